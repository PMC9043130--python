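"""Physical constants, unit conversions, and bulk-boundary geometry.

The internal unit base is Å (length), ps (time), kcal/mol (energy) and the
elementary charge; conversions to SI, eV, pS, pA, mol/L and cm³/s happen only
at API boundaries.  Working in these units keeps Boltzmann exponentials of
free-energy profiles (a few kcal/mol at ~0.6 kcal/mol thermal energy) far
from float overflow.

All constants follow CODATA 2018, where ``k_B``, ``N_A`` and ``e`` are exact
defined values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

# --- CODATA 2018 exact defined constants -------------------------------------
BOLTZMANN_J_PER_K: float = 1.380649e-23       # J/K (exact)
AVOGADRO: float = 6.02214076e23               # 1/mol (exact)
ELEMENTARY_CHARGE_C: float = 1.602176634e-19  # C (exact)

JOULE_PER_KCAL: float = 4184.0                # thermochemical calorie (exact)

#: Boltzmann constant in kcal/mol/K — the molar gas constant over 4184 J/kcal.
KB_KCAL_PER_MOL_K: float = BOLTZMANN_J_PER_K * AVOGADRO / JOULE_PER_KCAL
#: Boltzmann constant in eV/K.
KB_EV_PER_K: float = BOLTZMANN_J_PER_K / ELEMENTARY_CHARGE_C
#: Molar gas constant R in J/(mol K).
GAS_CONSTANT_J_PER_MOL_K: float = BOLTZMANN_J_PER_K * AVOGADRO
#: Faraday constant in C/mol.
FARADAY_C_PER_MOL: float = ELEMENTARY_CHARGE_C * AVOGADRO

# --- derived conversion factors ----------------------------------------------
#: 1 Å³/ps in cm³/s: (1e-8 cm)³ / (1e-12 s) = 1e-12 (exact).
A3_PER_PS_TO_CM3_PER_S: float = 1e-12
#: 1 kcal/mol in eV.
KCAL_PER_MOL_TO_EV: float = JOULE_PER_KCAL / AVOGADRO / ELEMENTARY_CHARGE_C
#: 1 kcal/mol in J (per molecule).
KCAL_PER_MOL_TO_J: float = JOULE_PER_KCAL / AVOGADRO
#: mol/L to molecules/cm³.
MOLAR_TO_PER_CM3: float = AVOGADRO / 1000.0
#: mol/L to molecules/Å³ (1 L = 1e27 Å³).
MOLAR_TO_PER_A3: float = AVOGADRO / 1e27
#: molarity of a single particle confined to 1 Å³, in mol·Å³/L.
SINGLE_PARTICLE_MOLAR_A3: float = 1e27 / AVOGADRO  # ≈ 1660.54


def thermal_energy(temperature: float, unit: str = "kcal/mol") -> float:
    """k_B·T in the requested unit (``kcal/mol``, ``eV`` or ``J``).

    Raises ``ValueError`` for non-positive temperature or an unknown unit.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature} K")
    if unit == "kcal/mol":
        return KB_KCAL_PER_MOL_K * temperature
    if unit == "eV":
        return KB_EV_PER_K * temperature
    if unit == "J":
        return BOLTZMANN_J_PER_K * temperature
    raise ValueError(f"unknown energy unit {unit!r}")


def beta(temperature: float) -> float:
    """Inverse thermal energy 1/(k_B T) in mol/kcal."""
    return 1.0 / thermal_energy(temperature, "kcal/mol")


@dataclass(frozen=True)
class BulkGeometry:
    """Restrained bulk region confining the tagged particle outside the pore.

    ``cylinder`` is the lateral flat-bottom restraint of radius ``radius``
    over an axial span ``length``; ``hemisphere`` and ``spherical_shell``
    describe radial restraints around a channel mouth.
    """

    kind: Literal["cylinder", "hemisphere", "spherical_shell"]
    radius: float = 0.0          # Å; outer radius for shells
    length: float = 0.0          # Å; cylinder only
    inner_radius: float = 0.0    # Å; shell only

    def __post_init__(self) -> None:
        if self.kind == "cylinder":
            if self.radius <= 0 or self.length <= 0:
                raise ValueError("cylinder needs positive radius and length")
        elif self.kind == "hemisphere":
            if self.radius <= 0:
                raise ValueError("hemisphere needs positive radius")
        elif self.kind == "spherical_shell":
            if self.inner_radius <= 0 or self.radius <= self.inner_radius:
                raise ValueError(
                    "shell needs 0 < inner_radius < radius "
                    f"(got inner={self.inner_radius}, outer={self.radius})"
                )
        else:
            raise ValueError(f"unknown geometry kind {self.kind!r}")


def volume(g: BulkGeometry) -> float:
    """Volume of the bulk region in Å³."""
    if g.kind == "cylinder":
        return math.pi * g.radius**2 * g.length
    if g.kind == "hemisphere":
        return (2.0 / 3.0) * math.pi * g.radius**3
    # spherical_shell: half-shell on one side of the membrane
    return (2.0 / 3.0) * math.pi * (g.radius**3 - g.inner_radius**3)


def single_particle_molarity(g: BulkGeometry) -> float:
    """Effective concentration (mol/L) of one particle confined to ``g``.

    A single tagged ion restrained to a bulk volume V defines an effective
    bulk concentration 1/(N_A·V); for V in Å³ this is ≈1660.54/V[Å³] mol/L.
    """
    return SINGLE_PARTICLE_MOLAR_A3 / volume(g)


def constants_table() -> str:
    """Machine-readable TSV of the constant set (name, value, unit)."""
    rows = [
        ("boltzmann", repr(BOLTZMANN_J_PER_K), "J/K"),
        ("boltzmann_kcal_mol", repr(KB_KCAL_PER_MOL_K), "kcal/mol/K"),
        ("boltzmann_ev", repr(KB_EV_PER_K), "eV/K"),
        ("avogadro", repr(AVOGADRO), "1/mol"),
        ("elementary_charge", repr(ELEMENTARY_CHARGE_C), "C"),
        ("gas_constant", repr(GAS_CONSTANT_J_PER_MOL_K), "J/mol/K"),
        ("faraday", repr(FARADAY_C_PER_MOL), "C/mol"),
        ("kcal_per_mol_to_ev", repr(KCAL_PER_MOL_TO_EV), "eV"),
        ("a3_per_ps_to_cm3_per_s", repr(A3_PER_PS_TO_CM3_PER_S), "cm³·s⁻¹ per Å³·ps⁻¹"),
    ]
    lines = ["name\tvalue\tunit"]
    lines += ["\t".join(r) for r in rows]
    return "\n".join(lines) + "\n"
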