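"""PMF and position-dependent diffusion from biased windows.

The free-energy profile w(z) is recovered from harmonically restrained
umbrella windows by self-consistent reweighting (binned WHAM): window free
energies f_i and the unbiased bin probabilities are iterated to joint
self-consistency.  The diffusion profile D(z) follows the restrained-window
estimator D(z_i) = ⟨δz²⟩_i / τ_i, where τ_i is the integral of the
normalized positional autocovariance in window i.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .trajectory import TimeSeries
from .units import beta as beta_of_T, thermal_energy


class CoverageError(ValueError):
    """Sampled windows leave an unsampled gap along the coordinate."""


class ConvergenceError(RuntimeError):
    """Self-consistent iteration failed to reach tolerance."""


@dataclass
class UmbrellaWindow:
    """One biased window: harmonic restraint ½k(z−center)² and its samples."""

    center: float       # Å
    k: float            # kcal/mol/Å²; 0 means unbiased
    series: TimeSeries

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("force constant must be non-negative")


@dataclass
class PMFProfile:
    """Binned free-energy profile w(z) in kcal/mol on a uniform z-grid.

    The profile is offset so that the mean over ``bulk_region`` (or the
    global minimum, when no bulk region is declared) is zero.
    """

    z_grid: np.ndarray
    w: np.ndarray
    w_err: Optional[np.ndarray] = None
    bulk_region: Optional[tuple[float, float]] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z_grid = np.asarray(self.z_grid, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        dz = np.diff(self.z_grid)
        if len(self.z_grid) < 2 or np.any(dz <= 0) or np.ptp(dz) > 1e-8 * dz[0]:
            raise ValueError("z_grid must be uniform and increasing")
        self.apply_bulk_offset()

    def apply_bulk_offset(self) -> None:
        """Re-zero the profile over the bulk region (idempotent)."""
        if self.bulk_region is not None:
            lo, hi = self.bulk_region
            mask = (self.z_grid >= lo) & (self.z_grid <= hi)
            if not np.any(mask):
                raise ValueError("bulk region contains no grid points")
            self.w = self.w - np.mean(self.w[mask])
        else:
            self.w = self.w - np.min(self.w)

    @property
    def barrier(self) -> float:
        """Maximum of w(z) relative to the bulk zero, kcal/mol."""
        return float(np.max(self.w))


@dataclass
class DiffusionProfile:
    """D(z) in Å²/ps at window centers, with per-window τ (ps) and variance (Å²)."""

    z_grid: np.ndarray
    D: np.ndarray
    tau: Optional[np.ndarray] = None
    variance: Optional[np.ndarray] = None
    symmetrized: bool = False

    def __post_init__(self) -> None:
        self.z_grid = np.asarray(self.z_grid, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        if np.any(self.D <= 0):
            raise ValueError("diffusion profile must be positive")


# --------------------------------------------------------------------------
# WHAM
# --------------------------------------------------------------------------

def _wham_solve(counts: np.ndarray, n_samples: np.ndarray, bias: np.ndarray,
                beta: float, tol: float, max_iter: int):
    """Self-consistent WHAM iteration on binned data.

    counts: (n_windows, n_bins) histograms; bias: (n_windows, n_bins) window
    bias energies at bin centers.  Returns (log unbiased bin weights,
    window free energies f, iterations).
    """
    total = counts.sum(axis=0)
    logN = np.log(n_samples.astype(float))
    f = np.zeros(len(n_samples))
    occupied = total > 0
    log_total = np.full(total.shape, -np.inf)
    log_total[occupied] = np.log(total[occupied])
    for it in range(1, max_iter + 1):
        # log denominator per bin: logsumexp_i [ logN_i + beta(f_i - u_i(b)) ]
        a = logN[:, None] + beta * (f[:, None] - bias)
        amax = a.max(axis=0)
        log_denom = amax + np.log(np.exp(a - amax).sum(axis=0))
        log_p = np.where(occupied, log_total - log_denom, -np.inf)
        # new window free energies: f_i = -kT ln sum_b p_b exp(-beta u_i(b))
        g = log_p[None, :] - beta * bias
        gmax = g.max(axis=1)
        f_new = -(gmax + np.log(np.exp(g - gmax[:, None]).sum(axis=1))) / beta
        f_new -= f_new[0]
        delta = float(np.max(np.abs(f_new - f)))
        f = f_new
        if delta < tol:
            return log_p, f, it
    raise ConvergenceError(f"WHAM did not converge in {max_iter} iterations "
                           f"(last offset change {delta:.3g} kcal/mol)")


def estimate_pmf(windows: Sequence[UmbrellaWindow], bin_width: float = 0.2,
                 tol: float = 1e-7, max_iter: int = 100_000,
                 temperature: float = 300.0,
                 bulk_region: Optional[tuple[float, float]] = None,
                 error_blocks: int = 0) -> PMFProfile:
    """Estimate w(z) from umbrella windows by self-consistent reweighting.

    With ``error_blocks`` = 2 the windows are split into contiguous halves
    and the half-profile spread is reported as ``w_err`` (block analysis).
    Raises CoverageError when the sampled ranges leave an empty gap, and
    ConvergenceError when the iteration stalls.
    """
    if not windows:
        raise ValueError("need at least one window")
    kT = thermal_energy(temperature)
    b = 1.0 / kT

    zmin = min(w.series.values.min() for w in windows)
    zmax = max(w.series.values.max() for w in windows)
    n_bins = max(int(np.ceil((zmax - zmin) / bin_width)), 1)
    edges = zmin + bin_width * np.arange(n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    counts = np.stack([np.histogram(w.series.values, bins=edges)[0] for w in windows])
    n_samples = counts.sum(axis=1)
    total = counts.sum(axis=0)

    # coverage: no empty bin strictly inside the sampled span
    nz = np.nonzero(total)[0]
    inner = total[nz[0]: nz[-1] + 1]
    if np.any(inner == 0):
        gap = np.nonzero(inner == 0)[0] + nz[0]
        raise CoverageError(
            f"no samples in z ∈ [{edges[gap[0]]:.3g}, {edges[gap[-1] + 1]:.3g}] Å — "
            "neighboring windows do not overlap")

    bias = np.stack([0.5 * w.k * (centers - w.center) ** 2 for w in windows])
    log_p, f, iters = _wham_solve(counts, n_samples, bias, b, tol, max_iter)

    keep = np.isfinite(log_p)
    w_vals = -kT * log_p[keep]

    w_err = None
    if error_blocks >= 2:
        halves = []
        for part in range(error_blocks):
            sub = []
            for w in windows:
                n = len(w.series)
                lo, hi = part * n // error_blocks, (part + 1) * n // error_blocks
                if hi - lo < 2:
                    continue
                sub.append(UmbrellaWindow(w.center, w.k, TimeSeries(
                    w.series.label, w.series.times[lo:hi], w.series.values[lo:hi])))
            c = np.stack([np.histogram(s.series.values, bins=edges)[0] for s in sub])
            lp, _, _ = _wham_solve(c, c.sum(axis=1),
                                   np.stack([0.5 * s.k * (centers - s.center) ** 2 for s in sub]),
                                   b, tol, max_iter)
            prof = np.full(n_bins, np.nan)
            ok = np.isfinite(lp)
            prof[ok] = -kT * lp[ok]
            if bulk_region is not None:
                m = ok & (centers >= bulk_region[0]) & (centers <= bulk_region[1])
                prof -= np.nanmean(prof[m])
            else:
                prof -= np.nanmin(prof)
            halves.append(prof)
        with warnings.catch_warnings():
            # bins sampled in only one block legitimately yield NaN spread
            warnings.simplefilter("ignore", RuntimeWarning)
            spread = np.nanstd(np.stack(halves), axis=0, ddof=1)
        w_err = spread[keep]

    return PMFProfile(centers[keep], w_vals, w_err=w_err, bulk_region=bulk_region,
                      meta={"iterations": iters, "bin_width": bin_width,
                            "temperature": temperature, "n_windows": len(windows)})


# --------------------------------------------------------------------------
# correlation time and D(z)
# --------------------------------------------------------------------------

def correlation_time(series: TimeSeries, rho_floor: float = 0.01,
                     max_lag_fraction: float = 0.1) -> float:
    """Integrated positional correlation time τ in ps.

    τ = stride · Σ_l ρ(l), where ρ is the normalized autocovariance of
    δz(t) = z(t) − ⟨z⟩, summed from lag 0 and truncated at the first lag
    where ρ drops below ``rho_floor`` or crosses zero — integrating the
    noisy tail would not converge.
    """
    dz = series.values - series.values.mean()
    n = len(dz)
    var = float(np.dot(dz, dz) / n)
    if var <= 0 or not np.isfinite(var):
        raise ValueError("zero-variance series has no correlation time")
    max_lag = max(int(n * max_lag_fraction), 1)
    # lag sums via FFT (identical to direct summation, O(n log n))
    m = 1 << int(np.ceil(np.log2(2 * n)))
    fz = np.fft.rfft(dz, m)
    acov = np.fft.irfft(fz * np.conj(fz), m)[: max_lag + 1]
    acov /= n - np.arange(max_lag + 1)      # unbiased normalization
    rho = acov / acov[0]
    below = np.nonzero((rho < rho_floor) | (rho <= 0))[0]
    cut = int(below[0]) if len(below) else max_lag + 1
    if len(below) == 0:
        warnings.warn("autocovariance never decayed below the floor; "
                      "series may be too short for a reliable τ", stacklevel=2)
    return float(series.stride * rho[:cut].sum())


def window_diffusion(series: TimeSeries) -> tuple[float, float, float]:
    """Per-window (D, τ, variance): D = ⟨δz²⟩/τ in Å²/ps."""
    tau = correlation_time(series)
    var = float(np.var(series.values))
    return var / tau, tau, var


def estimate_diffusion(windows: Sequence[UmbrellaWindow],
                       symmetrize: bool = False) -> DiffusionProfile:
    """Assemble D(z) at window centers from restrained-window statistics.

    With ``symmetrize`` the profile is averaged with its mirror image
    D(−z) (linear interpolation), appropriate for symmetric channels.
    """
    order = np.argsort([w.center for w in windows])
    centers, Ds, taus, variances = [], [], [], []
    for i in order:
        w = windows[i]
        D, tau, var = window_diffusion(w.series)
        centers.append(w.center)
        Ds.append(D)
        taus.append(tau)
        variances.append(var)
    centers = np.array(centers)
    Ds = np.array(Ds)
    if symmetrize:
        mirrored = np.interp(centers, -centers[::-1], Ds[::-1])
        Ds = 0.5 * (Ds + mirrored)
    return DiffusionProfile(centers, Ds, np.array(taus), np.array(variances),
                            symmetrized=symmetrize)


# --------------------------------------------------------------------------
# profile TSV I/O (z, value[, error]) with '#' metadata
# --------------------------------------------------------------------------

def write_profile(path: str | Path, z: np.ndarray, value: np.ndarray,
                  err: Optional[np.ndarray] = None, **meta) -> None:
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k} {v}\n")
        for i in range(len(z)):
            row = f"{z[i]:.10g} {value[i]:.10g}"
            if err is not None:
                row += f" {err[i]:.10g}"
            fh.write(row + "\n")


def read_profile(path: str | Path) -> tuple[np.ndarray, np.ndarray, Optional[np.ndarray]]:
    data = np.loadtxt(path, comments="#", ndmin=2)
    err = data[:, 2] if data.shape[1] > 2 else None
    return data[:, 0], data[:, 1], err
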