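"""Effective bulk concentration of a single restrained ion.

A tagged ion confined to a restrained bulk volume behaves like a solution
whose concentration is one particle per that volume.  This number converts
crossing rates into permeabilities, so the restraint geometry matters.
"""

from permeakit import BulkGeometry, single_particle_molarity

cylinder = BulkGeometry("cylinder", radius=6.0, length=28.0)
short_cyl = BulkGeometry("cylinder", radius=6.0, length=10.0)
hemisphere = BulkGeometry("hemisphere", radius=10.0)

print(f"cylinder r=6 Å, L=28 Å : {single_particle_molarity(cylinder):.3f} M")
print(f"cylinder r=6 Å, L=10 Å : {single_particle_molarity(short_cyl):.3f} M")
print(f"hemisphere r=10 Å      : {single_particle_molarity(hemisphere):.3f} M")
ratio = single_particle_molarity(short_cyl) / single_particle_molarity(hemisphere)
print(f"cylinder/hemisphere    : {ratio:.2f}")
# The first value (~0.52 M) is the concentration seen by voltage runs with
# one ion in the bulk cylinder; the ~1.9 ratio is what reconciles MFPTs
# measured under cylindrical versus spherical bulk boundaries.
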