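"""Permeability from profiles: the ISD equation and its MFPT counterpart.

Given w(z) and D(z), the inhomogeneous solubility-diffusion equation gives
P = πr²/∫e^{βw}/D dz; the Smoluchowski double integral gives the mean
first-passage time, and P = πr²∫e^{−βw}dz/(2⟨t⟩) closes the loop.
"""

import numpy as np

import permeakit as pk
from permeakit.isd import (ChannelBounds, isd_permeability, mfpt_permeability,
                           resistance_profile, smoluchowski_mfpt)
from permeakit.pmf import DiffusionProfile, PMFProfile

barrier = pk.GaussianBarrier(4.0, 0.0, 2.5)
zg = np.linspace(-12, 12, 2401)
pmf = PMFProfile(zg, barrier.energy(zg), bulk_region=(-12, -11))
d = DiffusionProfile(zg, np.full_like(zg, 0.02))
bounds = ChannelBounds(-10.0, 10.0)

p_isd = isd_permeability(pmf, d, radius=6.0, bounds=bounds)
mfpt = smoluchowski_mfpt(pmf, d, bounds)
p_mfpt = mfpt_permeability(pmf, mfpt, 6.0, bounds)

print(f"P (ISD)  : {p_isd.P:.3e} cm³/s")
print(f"MFPT     : {mfpt / 1e6:.3f} µs")
print(f"P (MFPT) : {p_mfpt.P:.3e} cm³/s")
print(f"ratio    : {p_isd.P / p_mfpt.P:.2f}")

table = resistance_profile(pmf, d, 6.0, bounds)
peak = table.loc[table.local_resistance_ps_per_A2.idxmax()]
print(f"resistance peaks at z = {peak.z_A:+.1f} Å "
      f"(the barrier top dominates 1/P)")
# For a single dominant symmetric barrier the two routes agree within
# ~10–25%; the resistance profile shows where the permeation bottleneck is.
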