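"""Steady-state flux analysis under applied voltage.

Two independent current estimators over ion trajectories — permeation-event
counting through a lower/inner/upper state machine, and the
charge-displacement current Σ_i q_i Δz_i/(Δt·L) — an ordinary least-squares
current–voltage fit whose slope is the unitary conductance γ, and the GHK
conversion P = γ·k_BT/(q²C) from conductance to permeability at symmetric
concentration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .isd import PermeabilityResult
from .trajectory import TimeSeries
from .units import (BOLTZMANN_J_PER_K, ELEMENTARY_CHARGE_C, MOLAR_TO_PER_CM3)

#: pA carried by one elementary charge per ps.
PA_PER_E_PER_PS = ELEMENTARY_CHARGE_C * 1e24


@dataclass(frozen=True)
class CrossingRegions:
    """Axial split of the channel into lower / inner / upper regions.

    The inner region is the closed interval [z_lower, z_upper] (samples on
    a boundary are assigned inner, keeping the state machine deterministic);
    ``pore_length`` is the L used by the displacement current.
    """

    z_lower: float
    z_upper: float
    pore_length: float

    def __post_init__(self) -> None:
        if self.z_lower >= self.z_upper:
            raise ValueError("regions need z_lower < z_upper")
        if self.pore_length <= 0:
            raise ValueError("pore length must be positive")

    def label(self, z: np.ndarray) -> np.ndarray:
        """-1 (lower), 0 (inner), +1 (upper) per sample."""
        z = np.asarray(z, dtype=float)
        return np.where(z < self.z_lower, -1, np.where(z > self.z_upper, 1, 0))


@dataclass
class CrossingCount:
    """Completed permeation events and the resulting counting current."""

    positive: int       # lower→inner→upper completions
    negative: int       # upper→inner→lower completions
    duration_ps: float
    current_pA: float

    @property
    def net(self) -> int:
        return self.positive - self.negative


def count_crossings(series_set: Sequence[TimeSeries], regions: CrossingRegions,
                    charge: float = 1.0) -> CrossingCount:
    """Count completed crossings over all ions; I = (net events)·q/τ in pA.

    A +1 event is a completed lower→inner→upper region sequence of one
    ion's samples; −1 the reverse.  Excursions that return to the starting
    side emit nothing.  Ions that never change region contribute zero.
    """
    if not series_set:
        raise ValueError("need at least one trajectory")
    pos = neg = 0
    duration = max(ts.times[-1] - ts.times[0] for ts in series_set)
    for ts in series_set:
        labels = regions.label(ts.values)
        origin = 0       # last bulk side visited: -1, +1, or 0 (none yet)
        via_inner = False  # inner region visited since leaving that side?
        for lab in labels:
            if lab == 0:
                via_inner = True
                continue
            if via_inner and lab == 1 and origin == -1:
                pos += 1
            elif via_inner and lab == -1 and origin == 1:
                neg += 1
            # a direct side-to-side jump (e.g. a periodic wrap) is not a
            # completed lower-inner-upper sequence and emits nothing
            origin = lab
            via_inner = False
    current = (pos - neg) * charge * PA_PER_E_PER_PS / duration
    return CrossingCount(pos, neg, float(duration), float(current))


def _unwrapped(ts: TimeSeries) -> np.ndarray:
    """Unwrap a periodic trajectory using the recorded wrap counts."""
    wraps = ts.meta.get("wraps")
    if wraps is None:
        return ts.values
    L = ts.meta["box_length"]
    return ts.values + np.asarray(wraps, dtype=float) * L


def displacement_current(series_set: Sequence[TimeSeries], regions: CrossingRegions,
                         charges: Optional[Sequence[float]] = None) -> float:
    """Charge-displacement current I = Σ_i q_i Σ_t Δz_i(t)/(Δt·L), in pA.

    Displacements are unwrapped via simulator wrap metadata.  Frames whose
    wrapped midpoint lies outside [z_lower, z_upper] are excluded, clipping
    the sum to the pore; when the pore spans the whole box this is a no-op.
    """
    if charges is None:
        charges = [ts.meta.get("charge", 1.0) for ts in series_set]
    total = 0.0  # e·Å
    duration = 0.0
    for ts, q in zip(series_set, charges):
        zu = _unwrapped(ts)
        dz = np.diff(zu)
        mid = 0.5 * (ts.values[:-1] + ts.values[1:])
        inside = (mid >= regions.z_lower) & (mid <= regions.z_upper)
        total += q * float(np.sum(dz[inside]))
        duration = max(duration, ts.times[-1] - ts.times[0])
    return total / (duration * regions.pore_length) * PA_PER_E_PER_PS


@dataclass(frozen=True)
class IVPoint:
    """One point of the current–voltage relation."""

    voltage: float               # V
    current: float               # pA
    uncertainty: float = 0.0     # pA
    method: str = "counting"

    def __post_init__(self) -> None:
        if self.uncertainty < 0:
            raise ValueError("uncertainty must be non-negative")


@dataclass
class ConductanceFit:
    """OLS slope of I on V: conductance in pS plus fit diagnostics."""

    conductance_pS: float
    stderr_pS: float
    intercept_pA: float          # expected ≈0 for a symmetric system
    intercept_stderr_pA: float
    n_points: int


def conductance_fit(points: Sequence[IVPoint]) -> ConductanceFit:
    """Least-squares I–V slope; pA/V is numerically pS.

    The intercept is fitted (not forced through the origin) and reported as
    a symmetry diagnostic.  Requires at least two distinct voltages.
    """
    V = np.array([p.voltage for p in points])
    I = np.array([p.current for p in points])
    if len(np.unique(V)) < 2:
        raise ValueError("conductance fit needs at least two distinct voltages")
    res = sstats.linregress(V, I)
    return ConductanceFit(float(res.slope), float(res.stderr),
                          float(res.intercept), float(res.intercept_stderr),
                          len(points))


def ghk_permeability(conductance_pS: float, concentration_M: float,
                     temperature: float = 300.0, z_charge: int = 1,
                     conductance_err_pS: Optional[float] = None) -> PermeabilityResult:
    """GHK conversion P = γ·k_BT/(q²·C) at symmetric concentration, in cm³/s.

    ``z_charge`` is the permeant valence; the GHK flux form is undefined
    for neutral species.
    """
    if conductance_pS <= 0 or concentration_M <= 0 or temperature <= 0:
        raise ValueError("conductance, concentration and temperature must be positive")
    if z_charge == 0:
        raise ValueError("GHK conversion undefined for a neutral permeant")
    q = z_charge * ELEMENTARY_CHARGE_C
    kT = BOLTZMANN_J_PER_K * temperature
    c_cm3 = concentration_M * MOLAR_TO_PER_CM3
    # γkT/q² is a frequency (1/s); dividing by C in cm⁻³ yields cm³/s directly
    P = (conductance_pS * 1e-12) * kT / (q**2 * c_cm3)
    unc = None
    if conductance_err_pS is not None:
        unc = P * conductance_err_pS / conductance_pS
    return PermeabilityResult(
        P=P, method="GHK", uncertainty=unc,
        details={"conductance_pS": conductance_pS, "concentration_M": concentration_M,
                 "temperature_K": temperature, "z_charge": z_charge})


def write_ion_table(series_set: Sequence[TimeSeries], path) -> None:
    """Write a multi-ion trajectory table: time, ion-id, z, wrap-count."""
    with open(path, "w") as fh:
        fh.write("# time_ps ion z_A wraps\n")
        for ion, ts in enumerate(series_set):
            wraps = ts.meta.get("wraps")
            if wraps is None:
                wraps = np.zeros(len(ts), dtype=int)
            if "box_length" in ts.meta:
                fh.write(f"# box_length {ts.meta['box_length']:.10g}\n")
            if "charge" in ts.meta:
                fh.write(f"# charge {ion} {ts.meta['charge']:.10g}\n")
            for t, z, w in zip(ts.times, ts.values, wraps):
                fh.write(f"{t:.10g} {ion} {z:.10g} {int(w)}\n")


def read_ion_table(path, box_length: Optional[float] = None) -> list[TimeSeries]:
    """Read a multi-ion table (time, ion-id, z, wrap-count) into per-ion series."""
    charges: dict[int, float] = {}
    rows: dict[int, list[tuple[float, float, int]]] = {}
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if not s:
                continue
            if s.startswith("#"):
                parts = s[1:].split()
                if parts and parts[0] == "box_length":
                    box_length = float(parts[1])
                elif parts and parts[0] == "charge":
                    charges[int(parts[1])] = float(parts[2])
                continue
            t, ion, z, w = s.split()[:4]
            rows.setdefault(int(ion), []).append((float(t), float(z), int(w)))
    out = []
    for ion in sorted(rows):
        data = rows[ion]
        times = np.array([r[0] for r in data])
        values = np.array([r[1] for r in data])
        wraps = np.array([r[2] for r in data])
        meta = {"wraps": wraps, "charge": charges.get(ion, 1.0)}
        if box_length is not None:
            meta["box_length"] = box_length
        out.append(TimeSeries(f"ion{ion}", times, values, meta))
    return out


def iv_table(points: Sequence[IVPoint]) -> pd.DataFrame:
    return pd.DataFrame([{"voltage_V": p.voltage, "current_pA": p.current,
                          "uncertainty_pA": p.uncertainty, "method": p.method}
                         for p in points])
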