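"""Permeability from free-energy and diffusion profiles.

Implements the PMF/D(z)-based kinetics of a single permeant crossing a
channel pore [z1, z2] with a lateral cylindrical bulk restraint of radius r:

* the (modified) inhomogeneous solubility-diffusion permeability
      P = πr² / ∫ e^{βw(z)}/D(z) dz,
* the local/cumulative resistance profile 1/P(z),
* the Smoluchowski mean first-passage time
      ⟨t⟩ = ∫ dz e^{βw(z)}/D(z) ∫_{z1}^{z} dz' e^{−βw(z')},
* the MFPT-route permeability  P = πr² ∫ e^{−βw} dz / (2⟨t⟩),
* the elementary relation  P = k/c = 1/(c⟨t⟩).

All quadratures are trapezoidal on the PMF grid, with D interpolated
linearly onto it; Boltzmann exponentials are computed with the grid
maximum shifted out so multi-kcal/mol barriers never overflow.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .pmf import DiffusionProfile, PMFProfile
from .units import A3_PER_PS_TO_CM3_PER_S, MOLAR_TO_PER_CM3, beta as beta_of_T


@dataclass(frozen=True)
class ChannelBounds:
    """Pore interval [z1, z2] beyond which the PMF is at its bulk value."""

    z1: float
    z2: float

    def __post_init__(self) -> None:
        if self.z1 >= self.z2:
            raise ValueError("channel bounds need z1 < z2")


@dataclass
class PermeabilityResult:
    """Single-channel permeability in cm³/s, tagged with its route."""

    P: float                       # cm³/s
    method: str                    # "ISD" | "MFPT" | "GHK" | "rate"
    uncertainty: Optional[float] = None
    inputs_digest: str = ""
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.P > 0:
            raise ValueError("permeability must be positive")

    def to_record(self) -> dict:
        rec = {"method": self.method, "P_cm3_per_s": self.P,
               "inputs_digest": self.inputs_digest, **self.details}
        if self.uncertainty is not None:
            rec["uncertainty_cm3_per_s"] = self.uncertainty
        return rec


def _digest(*arrays) -> str:
    h = hashlib.sha1()
    for a in arrays:
        h.update(np.ascontiguousarray(a, dtype=float).tobytes())
    return h.hexdigest()[:12]


def _common_grid(pmf: PMFProfile, d: DiffusionProfile, b: ChannelBounds):
    """PMF grid restricted to [z1, z2] with the bounds inserted exactly."""
    zg = pmf.z_grid
    if b.z1 < zg[0] - 1e-9 or b.z2 > zg[-1] + 1e-9:
        raise ValueError(
            f"channel bounds [{b.z1}, {b.z2}] outside PMF grid "
            f"[{zg[0]:.3g}, {zg[-1]:.3g}]")
    inner = zg[(zg > b.z1) & (zg < b.z2)]
    zs = np.concatenate(([b.z1], inner, [b.z2]))
    w = np.interp(zs, zg, pmf.w)
    D = np.interp(zs, d.z_grid, d.D)
    if np.any(D <= 0):
        raise ValueError("diffusion profile must be positive on the pore interval")
    return zs, w, D


def _exp_beta_w(w: np.ndarray, beta: float) -> tuple[np.ndarray, float]:
    """e^{βw} split as e^{β(w−wmax)} and the restored scale e^{βwmax}."""
    wmax = float(np.max(w))
    return np.exp(beta * (w - wmax)), float(np.exp(beta * wmax))


def isd_permeability(pmf: PMFProfile, d: DiffusionProfile, radius: float,
                     bounds: ChannelBounds, temperature: float = 300.0) -> PermeabilityResult:
    """Inhomogeneous solubility-diffusion permeability, in cm³/s.

    ``radius`` is the cylindrical bulk restraint radius (Å); it must exceed
    the pore radius so the restraint has no energetic contribution inside
    the pore (the caller asserts this).
    """
    if radius <= 0:
        raise ValueError("restraint radius must be positive")
    zs, w, D = _common_grid(pmf, d, bounds)
    bexp, scale = _exp_beta_w(w, beta_of_T(temperature))
    integral = np.trapezoid(bexp / D, zs) * scale    # ps/Å²
    P_a3_ps = np.pi * radius**2 / integral           # Å³/ps
    return PermeabilityResult(
        P=P_a3_ps * A3_PER_PS_TO_CM3_PER_S, method="ISD",
        inputs_digest=_digest(zs, w, D, [radius]),
        details={"radius_A": radius, "z1": bounds.z1, "z2": bounds.z2,
                 "temperature_K": temperature, "P_A3_per_ps": P_a3_ps})


def resistance_profile(pmf: PMFProfile, d: DiffusionProfile, radius: float,
                       bounds: ChannelBounds, temperature: float = 300.0) -> pd.DataFrame:
    """Local resistance e^{βw}/D and its running integral 1/P(z).

    The cumulative column is scaled by 1/(πr²) and converted to s/cm³, so
    its final value is exactly 1/P from :func:`isd_permeability`.
    """
    zs, w, D = _common_grid(pmf, d, bounds)
    bexp, scale = _exp_beta_w(w, beta_of_T(temperature))
    local = bexp / D * scale                          # ps/Å²
    cum = cumulative_trapezoid(local, zs, initial=0.0) / (np.pi * radius**2)
    return pd.DataFrame({
        "z_A": zs,
        "local_resistance_ps_per_A2": local,
        "cumulative_inverse_P_s_per_cm3": cum / A3_PER_PS_TO_CM3_PER_S,
    })


def smoluchowski_mfpt(pmf: PMFProfile, d: DiffusionProfile, bounds: ChannelBounds,
                      temperature: float = 300.0,
                      reflecting_at: Optional[float] = None) -> float:
    """Mean first-passage time (ps) from z1 to z2 for Smoluchowski diffusion.

    Reflecting at z1, absorbing at z2 (the outward construction); the inward
    time follows by mirroring the profile or swapping bounds.  When the
    reflecting wall sits below the starting point (a bulk region behind the
    source), pass it as ``reflecting_at``: the inner integral then starts
    there while the outer integral still runs from z1.
    """
    b = beta_of_T(temperature)
    if reflecting_at is None:
        zs, w, D = _common_grid(pmf, d, bounds)
        inner0 = 0.0
    else:
        if reflecting_at > bounds.z1:
            raise ValueError("reflecting wall must lie at or below the start z1")
        zpre, wpre, _ = _common_grid(pmf, d, ChannelBounds(reflecting_at, bounds.z1))
        inner0 = float(np.trapezoid(np.exp(-b * wpre), zpre))
        zs, w, D = _common_grid(pmf, d, bounds)
    bexp, scale = _exp_beta_w(w, b)
    inner = inner0 + cumulative_trapezoid(np.exp(-b * w), zs, initial=0.0)
    return float(np.trapezoid(bexp / D * inner, zs) * scale)


def mfpt_permeability(pmf: PMFProfile, mfpt_ps: float, radius: float,
                      bounds: ChannelBounds, temperature: float = 300.0,
                      mfpt_err_ps: Optional[float] = None) -> PermeabilityResult:
    """Permeability from a measured MFPT:  P = πr² ∫ e^{−βw} dz / (2⟨t⟩)."""
    if mfpt_ps <= 0:
        raise ValueError("MFPT must be positive")
    zg = pmf.z_grid
    mask = (zg >= bounds.z1 - 1e-9) & (zg <= bounds.z2 + 1e-9)
    if not np.any(mask):
        raise ValueError("channel bounds outside PMF grid")
    zs = zg[mask]
    w = pmf.w[mask]
    partition = np.trapezoid(np.exp(-beta_of_T(temperature) * w), zs)  # Å
    P_a3_ps = np.pi * radius**2 * partition / (2.0 * mfpt_ps)
    unc = None
    if mfpt_err_ps is not None:
        unc = P_a3_ps * mfpt_err_ps / mfpt_ps * A3_PER_PS_TO_CM3_PER_S
    return PermeabilityResult(
        P=P_a3_ps * A3_PER_PS_TO_CM3_PER_S, method="MFPT", uncertainty=unc,
        inputs_digest=_digest(zs, w, [radius, mfpt_ps]),
        details={"radius_A": radius, "mfpt_ps": mfpt_ps, "z1": bounds.z1,
                 "z2": bounds.z2, "temperature_K": temperature})


def permeability_from_rate(concentration_M: float, *, mfpt_ps: Optional[float] = None,
                           rate_per_s: Optional[float] = None) -> PermeabilityResult:
    """Elementary relation P = k/c = 1/(c⟨t⟩) at a symmetric concentration.

    Exactly one of ``mfpt_ps`` (ps) or ``rate_per_s`` (crossings/s) must be
    given; the concentration is in mol/L and is converted to molecules/cm³.
    """
    if concentration_M <= 0:
        raise ValueError("concentration must be positive")
    if (mfpt_ps is None) == (rate_per_s is None):
        raise ValueError("give exactly one of mfpt_ps or rate_per_s")
    if mfpt_ps is not None:
        if mfpt_ps <= 0:
            raise ValueError("MFPT must be positive")
        rate_per_s = 1.0 / (mfpt_ps * 1e-12)
    if rate_per_s <= 0:
        raise ValueError("rate must be positive")
    c_cm3 = concentration_M * MOLAR_TO_PER_CM3
    return PermeabilityResult(
        P=rate_per_s / c_cm3, method="rate",
        details={"concentration_M": concentration_M, "rate_per_s": rate_per_s})
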