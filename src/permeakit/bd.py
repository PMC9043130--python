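"""1-D overdamped Langevin (Brownian dynamics) trajectory generator.

Generates the ground truth the estimators are tested against: a single
tagged particle diffusing on a potential w(z) with position-dependent
diffusion D(z), optionally under harmonic / flat-bottom / constant-force
biases or a constant electric field.  The statistical structure of the
output — a scalar collective variable recorded at a fixed stride — matches
restrained MD output, so every downstream estimator sees realistic input.

The integrator uses the Itô convention with the explicit spurious-drift
term D'(z), which is required for the stationary law to be the Boltzmann
distribution exp(−βw) when D varies with position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from . import _kernels
from .trajectory import TimeSeries
from .units import KCAL_PER_MOL_TO_EV, beta as beta_of_T

_CHUNK = 1 << 21  # steps of pre-generated noise per kernel call (~16 MB)


class DomainEscapeError(RuntimeError):
    """A step left the simulation domain irrecoverably."""


# --------------------------------------------------------------------------
# potential / diffusion / bias specifications
# --------------------------------------------------------------------------

class FlatPotential:
    """w(z) = 0 everywhere."""

    def energy(self, z: np.ndarray) -> np.ndarray:
        return np.zeros_like(np.asarray(z, dtype=float))


@dataclass(frozen=True)
class GaussianBarrier:
    """Single symmetric barrier w(z) = height·exp(−(z−center)²/2·width²)."""

    height: float          # kcal/mol
    center: float = 0.0    # Å
    width: float = 2.5     # Å (Gaussian sigma)

    def energy(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        return self.height * np.exp(-((z - self.center) ** 2) / (2.0 * self.width**2))


class TabulatedPotential:
    """Cubic-spline interpolant through (z_grid, w) knots in kcal/mol."""

    def __init__(self, z_grid: Sequence[float], w: Sequence[float]):
        z_grid = np.asarray(z_grid, dtype=float)
        w = np.asarray(w, dtype=float)
        if np.any(np.diff(z_grid) <= 0):
            raise ValueError("tabulated grid must be strictly increasing")
        self.z_grid = z_grid
        self.w = w
        self._spline = CubicSpline(z_grid, w)

    def energy(self, z: np.ndarray) -> np.ndarray:
        return self._spline(np.asarray(z, dtype=float))


@dataclass(frozen=True)
class ConstantDiffusion:
    D: float  # Å²/ps

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError("diffusion coefficient must be positive")

    def diffusivity(self, z: np.ndarray) -> np.ndarray:
        return np.full_like(np.asarray(z, dtype=float), self.D)


class TabulatedDiffusion:
    """Cubic-spline D(z) profile in Å²/ps; must stay positive on its grid."""

    def __init__(self, z_grid: Sequence[float], D: Sequence[float]):
        z_grid = np.asarray(z_grid, dtype=float)
        D = np.asarray(D, dtype=float)
        if np.any(np.diff(z_grid) <= 0):
            raise ValueError("tabulated grid must be strictly increasing")
        if np.any(D <= 0):
            raise ValueError("diffusion coefficient must be positive everywhere")
        self.z_grid = z_grid
        self.D = D
        self._spline = CubicSpline(z_grid, D)

    def diffusivity(self, z: np.ndarray) -> np.ndarray:
        return self._spline(np.asarray(z, dtype=float))


@dataclass(frozen=True)
class HarmonicBias:
    """u(z) = ½ k (z − center)², the umbrella-sampling restraint."""

    k: float       # kcal/mol/Å²
    center: float  # Å

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("force constant must be non-negative")

    def energy(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        return 0.5 * self.k * (z - self.center) ** 2


@dataclass(frozen=True)
class FlatBottomBias:
    """Zero inside [lower, upper], half-harmonic walls outside (soft walls)."""

    k: float      # kcal/mol/Å²
    lower: float  # Å
    upper: float  # Å

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("force constant must be non-negative")
        if self.lower >= self.upper:
            raise ValueError("flat-bottom bias needs lower < upper")

    def energy(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        out = np.zeros_like(z)
        lo = z < self.lower
        hi = z > self.upper
        out[lo] = 0.5 * self.k * (z[lo] - self.lower) ** 2
        out[hi] = 0.5 * self.k * (z[hi] - self.upper) ** 2
        return out


@dataclass(frozen=True)
class ConstantForceBias:
    """Constant force f along +z, i.e. bias energy −f·z."""

    f: float  # kcal/mol/Å

    def energy(self, z: np.ndarray) -> np.ndarray:
        return -self.f * np.asarray(z, dtype=float)


@dataclass
class SimConfig:
    """Integrator settings.

    ``domain`` is the simulated interval (reflecting walls unless overridden
    by absorbing bounds or a periodic wrap).  ``output_stride`` records every
    n-th step; the recorded sampling interval is dt·output_stride, emulating
    a collective-variable output frequency.
    """

    dt: float = 0.01                 # ps
    n_steps: int = 100_000
    temperature: float = 300.0       # K
    seed: int = 0
    output_stride: int = 1
    initial_z: float = 0.0           # Å
    domain: tuple[float, float] = (-30.0, 30.0)
    absorbing_bounds: Optional[tuple[Optional[float], Optional[float]]] = None
    max_steps: int = 200_000_000     # first-passage step budget per replica

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.output_stride < 1:
            raise ValueError("output_stride must be >= 1")
        if self.domain[0] >= self.domain[1]:
            raise ValueError("domain must satisfy zmin < zmax")
        if self.absorbing_bounds is not None:
            lo, hi = self.absorbing_bounds
            if lo is not None and not self.initial_z > lo:
                raise ValueError("initial_z must lie strictly above the lower absorbing bound")
            if hi is not None and not self.initial_z < hi:
                raise ValueError("initial_z must lie strictly below the upper absorbing bound")


# --------------------------------------------------------------------------
# force-grid construction
# --------------------------------------------------------------------------

_GRID_DX = 0.005  # Å; fine enough that O(dx²) interpolation bias is negligible


def _build_grids(potential, diffusion, biases, zmin, zmax, extra_force=0.0):
    """Tabulate total force, D and D' on a uniform grid spanning the domain."""
    n = max(int(math.ceil((zmax - zmin) / _GRID_DX)) + 1, 8)
    grid = np.linspace(zmin, zmax, n)
    dx = grid[1] - grid[0]
    w = np.asarray(potential.energy(grid), dtype=float).copy()
    for b in biases:
        w += b.energy(grid)
    F = -np.gradient(w, dx) + extra_force
    D = np.asarray(diffusion.diffusivity(grid), dtype=float)
    if np.any(D <= 0):
        raise ValueError("diffusion profile must be positive over the domain")
    dD = np.gradient(D, dx)
    return grid, F, D, dD


def _replica_rng(seed: int, replica: int) -> np.random.Generator:
    """Per-replica stream: Generator(PCG64(SeedSequence([seed, replica])))."""
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, replica])))


# --------------------------------------------------------------------------
# simulation drivers
# --------------------------------------------------------------------------

def simulate(potential, diffusion, biases: Sequence = (), cfg: SimConfig = SimConfig(),
             label: str = "bd") -> TimeSeries:
    """Run a confined trajectory and return the recorded series.

    Deterministic for a fixed ``cfg.seed``.  Records the initial position at
    t=0 and then every ``output_stride`` steps.
    """
    zmin, zmax = cfg.domain
    grid, F, D, dD = _build_grids(potential, diffusion, biases, zmin, zmax)
    inv_dx = 1.0 / (grid[1] - grid[0])
    b = beta_of_T(cfg.temperature)
    rng = _replica_rng(cfg.seed, 0)

    n_rec = cfg.n_steps // cfg.output_stride
    out = np.empty(n_rec, dtype=float)
    z = float(cfg.initial_z)
    if not (zmin <= z <= zmax):
        raise ValueError("initial_z outside the simulation domain")
    phase = 0
    out_pos = 0
    done = 0
    while done < cfg.n_steps:
        m = min(_CHUNK, cfg.n_steps - done)
        noise = rng.standard_normal(m)
        z, out_pos, phase, esc = _kernels.run_reflecting(
            z, phase, noise, grid[0], inv_dx, F, D, dD, b, cfg.dt,
            zmin, zmax, out, out_pos, cfg.output_stride)
        if esc >= 0:
            raise DomainEscapeError(f"step {done + esc} left the domain [{zmin}, {zmax}]")
        done += m

    values = np.concatenate(([cfg.initial_z], out[:out_pos]))
    stride = cfg.dt * cfg.output_stride
    times = stride * np.arange(len(values))
    meta = {"seed": cfg.seed, "dt": cfg.dt, "output_stride": cfg.output_stride,
            "temperature": cfg.temperature}
    return TimeSeries(label, times, values, meta)


@dataclass
class FirstPassageResult:
    """Exit times (ps), exit sides (−1 lower / +1 upper) and censoring flags."""

    times: np.ndarray
    sides: np.ndarray
    censored: np.ndarray

    @property
    def mean(self) -> float:
        """Mean first-passage time over uncensored replicas, in ps."""
        ok = ~self.censored
        if not np.any(ok):
            raise ValueError("all replicas censored")
        return float(np.mean(self.times[ok]))


def first_passage_times(potential, diffusion, cfg: SimConfig, n_replicas: int,
                        biases: Sequence = ()) -> FirstPassageResult:
    """First exit times through the configured absorbing bounds.

    A bound given as None reflects instead of absorbing (e.g. reflecting at
    z1, absorbing at z2 for the outward passage).  Replicas exceeding
    ``cfg.max_steps`` are flagged censored, never silently truncated.
    """
    if cfg.absorbing_bounds is None:
        raise ValueError("first_passage_times requires cfg.absorbing_bounds")
    if n_replicas < 1:
        raise ValueError("need at least one replica")
    lo, hi = cfg.absorbing_bounds
    absorb_lo = lo is not None
    absorb_hi = hi is not None
    zmin = lo if absorb_lo else cfg.domain[0]
    zmax = hi if absorb_hi else cfg.domain[1]
    grid, F, D, dD = _build_grids(potential, diffusion, biases, zmin, zmax)
    inv_dx = 1.0 / (grid[1] - grid[0])
    b = beta_of_T(cfg.temperature)

    times = np.empty(n_replicas)
    sides = np.zeros(n_replicas, dtype=np.int64)
    censored = np.zeros(n_replicas, dtype=bool)
    for rep in range(n_replicas):
        rng = _replica_rng(cfg.seed, rep)
        z = float(cfg.initial_z)
        steps = 0
        side = 0
        while steps < cfg.max_steps:
            m = min(_CHUNK, cfg.max_steps - steps)
            noise = rng.standard_normal(m)
            z, used, side = _kernels.run_absorbing(
                z, noise, grid[0], inv_dx, F, D, dD, b, cfg.dt,
                zmin, zmax, absorb_lo, absorb_hi)
            steps += used
            if side != 0:
                break
        times[rep] = steps * cfg.dt
        sides[rep] = side
        censored[rep] = side == 0
    return FirstPassageResult(times, sides, censored)


def simulate_field(potential, diffusion, charge: float, voltage: float,
                   cfg: SimConfig, n_particles: int = 1,
                   biases: Sequence = ()) -> list[TimeSeries]:
    """Constant-field simulation on a periodic interval (voltage protocol).

    The transmembrane potential ``voltage`` (V) drops uniformly over the
    periodic box ``cfg.domain``; a particle of ``charge`` (in units of e)
    feels the constant force qV/L, positive voltage driving positive charge
    toward +z.  Wrap counts are recorded alongside positions (meta['wraps'])
    so displacements can be unwrapped for charge-displacement currents.
    """
    zmin, zmax = cfg.domain
    L = zmax - zmin
    if L <= 0:
        raise ValueError("periodic wrap interval must have positive length")
    # charge[e] · V/L [V/Å] is a force in eV/Å; convert to kcal/mol/Å
    force = charge * (voltage / L) / KCAL_PER_MOL_TO_EV
    grid, F, D, dD = _build_grids(potential, diffusion, biases, zmin, zmax,
                                  extra_force=force)
    inv_dx = 1.0 / (grid[1] - grid[0])
    b = beta_of_T(cfg.temperature)

    out_series = []
    n_rec = cfg.n_steps // cfg.output_stride
    for part in range(n_particles):
        rng = _replica_rng(cfg.seed, part)
        out_z = np.empty(n_rec)
        out_w = np.empty(n_rec, dtype=np.int64)
        z = float(cfg.initial_z)
        wraps = 0
        phase = 0
        out_pos = 0
        done = 0
        while done < cfg.n_steps:
            m = min(_CHUNK, cfg.n_steps - done)
            noise = rng.standard_normal(m)
            z, wraps, out_pos, phase = _kernels.run_periodic(
                z, wraps, phase, noise, grid[0], inv_dx, F, D, dD, b, cfg.dt,
                zmin, zmax, out_z, out_w, out_pos, cfg.output_stride)
            done += m
        values = np.concatenate(([cfg.initial_z], out_z[:out_pos]))
        wrap_track = np.concatenate(([0], out_w[:out_pos]))
        stride = cfg.dt * cfg.output_stride
        times = stride * np.arange(len(values))
        meta = {"seed": cfg.seed, "particle": part, "charge": charge,
                "voltage": voltage, "box_length": L, "wraps": wrap_track}
        out_series.append(TimeSeries(f"ion{part}", times, values, meta))
    return out_series
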