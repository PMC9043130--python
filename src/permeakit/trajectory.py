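"""Collective-variable time series I/O.

Reads and writes whitespace-delimited trajectory tables in the style of MD
collective-variable (Colvars) output: a time column in ps followed by one or
more value columns in Å, with ``#`` comment/header lines.  Series are
strictly uniform in stride; subsampling and block splitting preserve that.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np

STRIDE_TOL = 1e-9  # ps, absolute; files are written at fixed print precision


class FormatError(ValueError):
    """Malformed trajectory file (bad number, non-uniform stride, ...)."""


@dataclass
class TimeSeries:
    """A uniformly sampled scalar collective-variable trace.

    times are in ps, values in Å.  ``stride`` is the (uniform) sampling
    interval; ``meta`` carries free-form provenance (seed, label, origin).
    """

    label: str
    times: np.ndarray
    values: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-D and equal length")
        if len(self.times) < 2:
            raise ValueError("a time series needs at least 2 records")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.abs(dt - dt[0]) > STRIDE_TOL):
            i = int(np.argmax(np.abs(dt - dt[0]) > STRIDE_TOL))
            raise FormatError(
                f"non-uniform stride at record {i + 1}: "
                f"{dt[i]:.6g} ps vs {dt[0]:.6g} ps"
            )

    @property
    def stride(self) -> float:
        """Sampling interval in ps."""
        return float(self.times[1] - self.times[0])

    def __len__(self) -> int:
        return len(self.times)


def read_timeseries(path: str | Path, column: int = 1, label: str | None = None) -> TimeSeries:
    """Read one value column (time is column 0) from a whitespace table.

    Lines starting with ``#`` and blank lines are skipped.  Malformed numeric
    fields and stride jumps are reported with their line number.
    """
    path = Path(path)
    times: list[float] = []
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split()
            if column >= len(parts):
                raise FormatError(f"{path}:{lineno}: expected at least {column + 1} columns")
            try:
                t = float(parts[0])
                v = float(parts[column])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric field: {exc}") from None
            if times and len(times) >= 2:
                stride = times[1] - times[0]
                if abs((t - times[-1]) - stride) > STRIDE_TOL:
                    raise FormatError(
                        f"{path}:{lineno}: stride jump "
                        f"{t - times[-1]:.6g} ps (expected {stride:.6g} ps)"
                    )
            times.append(t)
            values.append(v)
    if not times:
        raise FormatError(f"{path}: no data records")
    if len(times) < 2:
        raise FormatError(f"{path}: need at least 2 records")
    return TimeSeries(label or path.stem, np.array(times), np.array(values), {"source": str(path)})


def write_timeseries(ts: TimeSeries, path: str | Path) -> None:
    """Write a series with ``#`` metadata header lines at 10 significant digits."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# label {ts.label}\n")
        fh.write(f"# stride {ts.stride:.10g}\n")
        for k, v in ts.meta.items():
            fh.write(f"# {k} {v}\n")
        for t, v in zip(ts.times, ts.values):
            fh.write(f"{t:.10g} {v:.10g}\n")


def subsample(ts: TimeSeries, factor: int) -> TimeSeries:
    """Keep every ``factor``-th record from index 0; stride scales by ``factor``."""
    if factor < 1 or int(factor) != factor:
        raise ValueError(f"subsample factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return ts
    meta = dict(ts.meta)
    meta["subsample_factor"] = meta.get("subsample_factor", 1) * factor
    return TimeSeries(ts.label, ts.times[::factor], ts.values[::factor], meta)


def split_blocks(ts: TimeSeries, n_blocks: int) -> list[TimeSeries]:
    """Split into contiguous equal-length blocks, dropping the tail remainder."""
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    blen = len(ts) // n_blocks
    if blen < 2:
        raise ValueError(f"{n_blocks} blocks of a {len(ts)}-record series would be too short")
    out = []
    for b in range(n_blocks):
        sl = slice(b * blen, (b + 1) * blen)
        meta = dict(ts.meta, block=f"{b + 1}/{n_blocks}")
        out.append(TimeSeries(f"{ts.label}.block{b + 1}", ts.times[sl], ts.values[sl], meta))
    return out


def from_values(values: Sequence[float], stride: float, label: str = "series",
                t0: float = 0.0, **meta: Any) -> TimeSeries:
    """Build a TimeSeries from values at a uniform stride starting at ``t0``."""
    values = np.asarray(values, dtype=float)
    times = t0 + stride * np.arange(len(values))
    return TimeSeries(label, times, values, dict(meta))
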