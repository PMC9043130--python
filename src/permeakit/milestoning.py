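"""Voronoi-tessellated Markovian milestoning on a 1-D collective variable.

The coordinate axis is partitioned into M cells by M+1 edges; the M−1
interior edges shared by adjacent cells are the milestones.  Each cell is
sampled by a trajectory confined with soft walls (flat-bottom restraints),
and the milestone-hitting kinetics of those confined trajectories determine

* the cell equilibrium probabilities π from the attempted-escape balance
  Σ_j π_j k_{j→i} = Σ_j π_i k_{i→j},
* per-cell free energies −k_B T ln π_i,
* the milestone-to-milestone rate matrix
  q_{ij,ik} = π_i n_i(j→k) / (π_i r_i(j) + π_j r_j(j)),
* inward/outward mean first-passage-time profiles from the rate matrix.

Event detection is sample-based: a milestone is hit when consecutive
recorded samples straddle (or land exactly on) a cell edge.  Because the
recorded stride bounds the resolvable recrossing rate, a stride-sensitivity
scan over subsampled data is part of the toolkit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .pmf import correlation_time
from .trajectory import TimeSeries, split_blocks, subsample
from .units import thermal_energy


class IrreducibilityError(ValueError):
    """The cell graph (or milestone chain) is not connected."""


@dataclass(frozen=True)
class CellPartition:
    """Ordered cell edges; interior edges are the milestones.

    M cells need M+1 strictly increasing edges.  Milestone m (0-based) is
    the edge shared by cells m and m+1, at position ``edges[m+1]``.
    """

    edges: tuple[float, ...]
    labels: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if len(e) < 3:
            raise ValueError("need at least 2 cells (3 edges)")
        if np.any(np.diff(e) <= 0):
            raise ValueError("cell edges must be strictly increasing")

    @property
    def n_cells(self) -> int:
        return len(self.edges) - 1

    @property
    def milestones(self) -> np.ndarray:
        """Positions of the M−1 interior milestones."""
        return np.asarray(self.edges[1:-1], dtype=float)

    def cell_milestones(self, cell: int) -> tuple[Optional[int], Optional[int]]:
        """(left, right) milestone indices bounding a cell; None at the domain ends."""
        left = cell - 1 if cell > 0 else None
        right = cell if cell < self.n_cells - 1 else None
        return left, right


@dataclass
class CellSampling:
    """Confined trajectory assigned to one Voronoi cell."""

    cell: int
    series: TimeSeries

    def excursion_fraction(self, partition: CellPartition) -> float:
        lo, hi = partition.edges[self.cell], partition.edges[self.cell + 1]
        v = self.series.values
        return float(np.mean((v < lo) | (v > hi)))


@dataclass
class CellStats:
    """Milestone-hitting statistics harvested from one cell trajectory.

    Times are in ps.  ``residence[j]`` is time spent after last hitting
    milestone j; ``counts[(j, k)]`` the number of j→k transitions; both are
    accumulated after the burn-in (time before the first milestone hit is
    discarded).  ``escapes`` counts attempted escapes toward each
    neighboring cell: one per contiguous excursion past the shared edge.
    ``incell_time`` (time spent inside the cell proper) normalizes escape
    and transition rates; ``total_time`` is the full trajectory duration.
    """

    cell: int
    assigned_time: float = 0.0
    total_time: float = 0.0
    incell_time: float = 0.0
    residence: dict[int, float] = field(default_factory=dict)
    counts: dict[tuple[int, int], int] = field(default_factory=dict)
    escapes: dict[str, int] = field(default_factory=lambda: {"left": 0, "right": 0})
    waiting_times: list[float] = field(default_factory=list)
    n_samples: int = 0

    def residence_fraction(self, milestone: int) -> float:
        if self.assigned_time <= 0:
            return 0.0
        return self.residence.get(milestone, 0.0) / self.assigned_time

    def transition_rate(self, j: int, k: int) -> float:
        """n_i(j→k): transition count normalized by time spent in the cell, ps⁻¹."""
        if self.assigned_time <= 0:
            return 0.0
        return self.counts.get((j, k), 0) / self.assigned_time

    def escape_rate(self, side: str) -> float:
        """Attempted-escape rate toward the ``side`` neighbor, ps⁻¹.

        Normalized by in-cell time: soft-wall excursion time must not count
        as time available for escape attempts, or cells whose surroundings
        are energetically downhill would have their rates deflated.
        """
        if self.incell_time <= 0:
            return 0.0
        return self.escapes[side] / self.incell_time


def detect_events(sampling: CellSampling, partition: CellPartition) -> CellStats:
    """Scan one confined trajectory for milestone hits and escape attempts.

    A hit is registered when consecutive samples straddle a bounding edge or
    a sample lands exactly on it (closed boundary on the crossing side).  A
    frame that jumps across both edges registers hits in spatial order
    within that frame.  Warns and returns zero statistics when no milestone
    is ever hit.
    """
    cell = sampling.cell
    if not (0 <= cell < partition.n_cells):
        raise ValueError(f"cell index {cell} outside partition of {partition.n_cells} cells")
    v = sampling.series.values
    h = sampling.series.stride
    lo_edge = partition.edges[cell]
    hi_edge = partition.edges[cell + 1]
    left_m, right_m = partition.cell_milestones(cell)

    stats = CellStats(cell=cell, total_time=h * (len(v) - 1), n_samples=len(v))
    stats.incell_time = h * float(np.sum((v >= lo_edge) & (v <= hi_edge)))

    # attempted escapes: one per contiguous excursion past each edge
    for side, outside in (("left", v < lo_edge), ("right", v > hi_edge)):
        starts = int(outside[0]) + int(np.sum(outside[1:] & ~outside[:-1]))
        stats.escapes[side] = starts

    # milestone hit sequence: (sample index, milestone id), vectorized per edge
    boundaries = [(left_m, partition.edges[cell]), (right_m, partition.edges[cell + 1])]
    boundaries = [(m, pos) for m, pos in boundaries if m is not None]
    hit_idx: list[np.ndarray] = []
    hit_m: list[np.ndarray] = []
    hit_key: list[np.ndarray] = []
    prev, cur = v[:-1], v[1:]
    up = cur > prev
    for m, pos in boundaries:
        straddle = (np.minimum(prev, cur) < pos) & (pos < np.maximum(prev, cur))
        landed = (cur == pos) & (cur != prev)
        idx = np.nonzero(straddle | landed)[0] + 1
        if v[0] == pos:
            idx = np.concatenate(([0], idx))
        hit_idx.append(idx)
        hit_m.append(np.full(len(idx), m, dtype=np.int64))
        # secondary sort key orders double crossings along the motion direction
        key = np.where(up[np.maximum(idx - 1, 0)], pos, -pos)
        hit_key.append(key)
    hits: list[tuple[int, int]] = []
    if hit_idx:
        idx = np.concatenate(hit_idx)
        ms = np.concatenate(hit_m)
        key = np.concatenate(hit_key)
        order = np.lexsort((key, idx))
        hits = list(zip(idx[order].tolist(), ms[order].tolist()))

    if not hits:
        warnings.warn(f"cell {cell}: no milestone ever hit; zero contribution",
                      stacklevel=2)
        return stats

    # residence clock counts only in-cell samples: soft-wall excursion time
    # beyond an edge belongs to the neighboring cell's bookkeeping
    incell = (v >= lo_edge) & (v <= hi_edge)
    cs = np.concatenate(([0], np.cumsum(incell)))

    def cell_time(a: int, b: int) -> float:
        return h * float(cs[b] - cs[a])

    # burn-in: discard time before the first hit
    first_i, last_m = hits[0]
    last_event_i = first_i
    t_last = first_i
    for i, m in hits[1:]:
        if m == last_m:
            continue
        stats.residence[last_m] = stats.residence.get(last_m, 0.0) + cell_time(t_last, i)
        stats.counts[(last_m, m)] = stats.counts.get((last_m, m), 0) + 1
        stats.waiting_times.append(h * (i - last_event_i))
        last_m = m
        last_event_i = i
        t_last = i
    # tail residence up to the final sample
    stats.residence[last_m] = stats.residence.get(last_m, 0.0) + cell_time(t_last, len(v))
    stats.assigned_time = cell_time(first_i, len(v))
    return stats


def solve_equilibrium(stats: Sequence[CellStats], partition: CellPartition) -> np.ndarray:
    """Cell equilibrium probabilities π from the attempted-escape balance.

    Builds the escape-rate generator over cells and returns its stationary
    distribution (null space of the transpose), normalized to Σπ = 1.
    """
    M = partition.n_cells
    by_cell = {s.cell: s for s in stats}
    if set(by_cell) != set(range(M)):
        missing = sorted(set(range(M)) - set(by_cell))
        raise ValueError(f"missing statistics for cells {missing}")
    L = np.zeros((M, M))
    for i in range(M):
        s = by_cell[i]
        if i > 0:
            L[i, i - 1] = s.escape_rate("left")
        if i < M - 1:
            L[i, i + 1] = s.escape_rate("right")
    for i in range(M - 1):
        if L[i, i + 1] <= 0 or L[i + 1, i] <= 0:
            raise IrreducibilityError(
                f"cell graph disconnected between cells {i} and {i + 1} "
                "(no attempted escapes observed)")
    np.fill_diagonal(L, -L.sum(axis=1))
    # stationary: pi^T L = 0 with sum(pi) = 1
    A = np.vstack([L.T, np.ones(M)])
    rhs = np.zeros(M + 1)
    rhs[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def free_energy(pi: np.ndarray, reference_cells: Sequence[int],
                temperature: float = 300.0) -> np.ndarray:
    """Per-cell free energy −k_B T ln π_i (kcal/mol), zeroed over the bulk cells."""
    pi = np.asarray(pi, dtype=float)
    if np.any(pi <= 0):
        raise ValueError("free energy undefined for zero-probability cells")
    kT = thermal_energy(temperature)
    F = -kT * np.log(pi)
    return F - np.mean(F[list(reference_cells)])


@dataclass
class MilestoningModel:
    """Milestone-indexed rate matrix and the cell equilibrium behind it."""

    pi: np.ndarray                 # per-cell equilibrium probabilities
    Q: np.ndarray                  # (K, K) rate matrix, ps⁻¹
    milestones: np.ndarray         # positions (or index labels) of the K milestones
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.pi < 0) or abs(self.pi.sum() - 1.0) > 1e-9:
            raise ValueError("π must be non-negative and sum to 1")
        if self.Q.size == 0:
            return  # degenerate model: every milestone was dropped
        off = self.Q.copy()
        np.fill_diagonal(off, 0.0)
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be non-negative")
        if np.any(np.abs(self.Q.sum(axis=1)) > 1e-9 * max(np.abs(off).max(), 1e-300)):
            raise ValueError("rate-matrix rows must sum to zero")


def build_rate_matrix(stats: Sequence[CellStats], pi: np.ndarray,
                      partition: CellPartition, provenance: Optional[dict] = None
                      ) -> MilestoningModel:
    """Assemble the milestone rate matrix q_{ij,ik} from cell statistics.

    The numerator is the π-weighted transition rate observed in the shared
    cell; the denominator is the total stationary residence weight on the
    source milestone, summed over both cells adjacent to it.  Milestones
    that were never hit are dropped with a warning.
    """
    M = partition.n_cells
    by_cell = {s.cell: s for s in stats}
    K = M - 1
    Q = np.zeros((K, K))

    def milestone_weight(m: int) -> float:
        # milestone m is shared by cells m and m+1
        wgt = 0.0
        for c in (m, m + 1):
            if c in by_cell:
                wgt += pi[c] * by_cell[c].residence_fraction(m)
        return wgt

    for i in range(M):
        if i not in by_cell:
            continue
        s = by_cell[i]
        left_m, right_m = partition.cell_milestones(i)
        for j, k in ((left_m, right_m), (right_m, left_m)):
            if j is None or k is None:
                continue
            n = s.transition_rate(j, k)
            if n == 0.0:
                continue
            denom = milestone_weight(j)
            if denom <= 0:
                raise ValueError(
                    f"milestone {j}: transitions observed but zero residence weight")
            Q[j, k] += pi[i] * n / denom

    hit = np.array([milestone_weight(m) > 0 or Q[m].any() or Q[:, m].any()
                    for m in range(K)])
    if not np.all(hit):
        dropped = np.nonzero(~hit)[0]
        warnings.warn(f"dropping never-hit milestones {dropped.tolist()}", stacklevel=2)
        idx = np.nonzero(hit)[0]
        Q = Q[np.ix_(idx, idx)]
        milestones = partition.milestones[idx]
    else:
        milestones = partition.milestones
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return MilestoningModel(np.asarray(pi, dtype=float), Q, milestones,
                            provenance=dict(provenance or {}))


@dataclass
class MFPTProfile:
    """MFPT (ps) from the source milestone to every milestone, one direction."""

    milestones: np.ndarray
    mfpt: np.ndarray
    direction: Literal["outward", "inward"]

    @property
    def end_to_end(self) -> float:
        """MFPT between the first and last milestones, ps."""
        return float(self.mfpt[-1] if self.direction == "outward" else self.mfpt[0])


def mfpt_profile(model: MilestoningModel,
                 direction: Literal["outward", "inward"] = "outward") -> MFPTProfile:
    """MFPT from the first (outward) or last (inward) milestone to every other.

    For each target m*, the restricted system (Q without the absorbing row
    and column)·t = −1 is solved and t at the source reported.  Raises when
    the restricted system is singular (target unreachable).
    """
    K = model.Q.shape[0]
    source = 0 if direction == "outward" else K - 1
    out = np.zeros(K)
    for target in range(K):
        if target == source:
            continue
        keep = [m for m in range(K) if m != target]
        A = model.Q[np.ix_(keep, keep)]
        try:
            t = np.linalg.solve(A, -np.ones(K - 1))
        except np.linalg.LinAlgError:
            raise IrreducibilityError(
                f"milestone {target} unreachable from milestone {source}") from None
        if np.any(t < -1e-9):
            raise IrreducibilityError(
                f"milestone {target} unreachable from milestone {source}")
        out[target] = t[keep.index(source)]
    return MFPTProfile(model.milestones.copy(), out, direction)


def run_milestoning(samplings: Sequence[CellSampling], partition: CellPartition,
                    provenance: Optional[dict] = None
                    ) -> tuple[MilestoningModel, list[CellStats]]:
    """Full pipeline: events → π → rate matrix."""
    stats = [detect_events(s, partition) for s in samplings]
    pi = solve_equilibrium(stats, partition)
    model = build_rate_matrix(stats, pi, partition, provenance=provenance)
    return model, stats


def merge_stats(parts: Sequence[CellStats]) -> CellStats:
    """Pool statistics of several trajectory segments of the same cell."""
    if not parts:
        raise ValueError("nothing to merge")
    cells = {p.cell for p in parts}
    if len(cells) != 1:
        raise ValueError("can only merge statistics of a single cell")
    out = CellStats(cell=parts[0].cell)
    for p in parts:
        out.assigned_time += p.assigned_time
        out.total_time += p.total_time
        out.incell_time += p.incell_time
        out.n_samples += p.n_samples
        for m, t in p.residence.items():
            out.residence[m] = out.residence.get(m, 0.0) + t
        for jk, n in p.counts.items():
            out.counts[jk] = out.counts.get(jk, 0) + n
        for side in ("left", "right"):
            out.escapes[side] += p.escapes[side]
        out.waiting_times.extend(p.waiting_times)
    return out


def mfpt_uncertainty(samplings: Sequence[CellSampling], partition: CellPartition,
                     n_blocks: int = 5, n_boot: int = 50, seed: int = 0
                     ) -> dict[str, tuple[float, float]]:
    """Block-bootstrap mean and standard error of the end-to-end MFPT (ps).

    Each cell trajectory is cut into ``n_blocks`` contiguous segments whose
    milestone statistics are resampled with replacement and pooled, and the
    full π → Q → MFPT pipeline rebuilt per replicate.  Returns
    {"outward": (mean, se), "inward": (mean, se)}.
    """
    block_stats: list[list[CellStats]] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in samplings:
            blocks = split_blocks(s.series, n_blocks)
            block_stats.append([detect_events(CellSampling(s.cell, b), partition)
                                for b in blocks])
    rng = np.random.default_rng(seed)
    outs, ins = [], []
    for _ in range(n_boot):
        stats = []
        for per_cell in block_stats:
            pick = rng.integers(0, n_blocks, size=n_blocks)
            stats.append(merge_stats([per_cell[i] for i in pick]))
        try:
            pi = solve_equilibrium(stats, partition)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = build_rate_matrix(stats, pi, partition)
            outs.append(mfpt_profile(model, "outward").end_to_end)
            ins.append(mfpt_profile(model, "inward").end_to_end)
        except (IrreducibilityError, ValueError):
            continue  # unlucky resample lost connectivity; skip
    if len(outs) < max(n_boot // 2, 2):
        raise RuntimeError("too many bootstrap replicates lost connectivity")
    return {"outward": (float(np.mean(outs)), float(np.std(outs, ddof=1))),
            "inward": (float(np.mean(ins)), float(np.std(ins, ddof=1)))}


def diagnostics(stats: Sequence[CellStats],
                samplings: Optional[Sequence[CellSampling]] = None) -> pd.DataFrame:
    """Per-cell convergence diagnostics.

    Reports the extreme waiting times between successive milestone
    transitions and (when trajectories are supplied) the positional
    decorrelation time; Markovianity requires decorrelation faster than the
    minimum waiting time.
    """
    series_by_cell = {s.cell: s.series for s in samplings} if samplings else {}
    rows = []
    for s in sorted(stats, key=lambda s: s.cell):
        wt = np.asarray(s.waiting_times)
        row = {
            "cell": s.cell,
            "n_transitions": int(sum(s.counts.values())),
            "max_waiting_ps": float(wt.max()) if len(wt) else np.nan,
            "min_waiting_ps": float(wt.min()) if len(wt) else np.nan,
            "assigned_time_ps": s.assigned_time,
        }
        ser = series_by_cell.get(s.cell)
        if ser is not None:
            try:
                row["decorrelation_time_ps"] = correlation_time(ser)
            except ValueError:
                row["decorrelation_time_ps"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def convergence_trace(sampling: CellSampling, partition: CellPartition,
                      n_points: int = 20) -> pd.DataFrame:
    """Running transition rates and residence fractions versus sampling time."""
    v = sampling.series
    rows = []
    for frac in np.linspace(1.0 / n_points, 1.0, n_points):
        n = max(int(len(v) * frac), 2)
        truncated = CellSampling(sampling.cell, TimeSeries(
            v.label, v.times[:n], v.values[:n]))
        s = detect_events(truncated, partition)
        left_m, right_m = partition.cell_milestones(sampling.cell)
        row = {"time_ps": v.times[n - 1] - v.times[0]}
        if left_m is not None and right_m is not None:
            row["n_lr_per_ps"] = s.transition_rate(left_m, right_m)
            row["n_rl_per_ps"] = s.transition_rate(right_m, left_m)
        if left_m is not None:
            row["r_left"] = s.residence_fraction(left_m)
        if right_m is not None:
            row["r_right"] = s.residence_fraction(right_m)
        rows.append(row)
    return pd.DataFrame(rows)


def stride_sensitivity(samplings: Sequence[CellSampling], partition: CellPartition,
                       factors: Sequence[int]) -> pd.DataFrame:
    """Rerun the pipeline on subsampled trajectories for each stride factor.

    Coarser strides miss milestone recrossings, so transition counts drop
    and the end-to-end MFPT inflates; this table quantifies that bias.
    """
    rows = []
    for factor in factors:
        subs = [CellSampling(s.cell, subsample(s.series, factor)) for s in samplings]
        model, stats = run_milestoning(subs, partition)
        prof = mfpt_profile(model, "outward")
        rows.append({
            "factor": factor,
            "stride_ps": subs[0].series.stride,
            "mfpt_ps": prof.end_to_end,
            "total_transitions": int(sum(sum(s.counts.values()) for s in stats)),
        })
    return pd.DataFrame(rows)
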