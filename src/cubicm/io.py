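"""Plain-text readers and writers for traces, counts and rasters.

All formats are delimited text so reports and fixtures stay diffable: traces
are one sample per row with the sampling interval in a ``# dt=`` header (or a
two-column time/value layout), count series carry ``dt`` the same way, and
rasters are two columns (neuron id, spike time in s).
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Optional

import numpy as np

from .signals import Raster, SpikeCountSeries, Trace

_DT_RE = re.compile(r"dt\s*=\s*([0-9eE.+-]+)")


def _header_dt(path) -> Optional[float]:
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if not line.startswith("#"):
                break
            m = _DT_RE.search(line)
            if m:
                return float(m.group(1))
    return None


def write_trace(path, trace: Trace) -> None:
    """One sample per row, dt recorded in the header to full precision."""
    np.savetxt(path, trace.samples, fmt="%.17g", header=f"dt={trace.dt!r}")


def read_trace(path, dt: Optional[float] = None) -> Trace:
    """Read a uniformly sampled trace from delimited text.

    Accepts a single value column (dt from the header or the ``dt`` argument)
    or two columns (time, value) whose time stamps must be uniformly spaced to
    a relative tolerance of 1e-9 — non-uniform input is an error, never
    resampled.
    """
    path = Path(path)
    header_dt = _header_dt(path)
    data = np.loadtxt(path, ndmin=2)
    if data.shape[1] == 1:
        step = header_dt if header_dt is not None else dt
        if step is None:
            raise ValueError(
                f"{path}: single-column trace needs dt in the header or as an argument"
            )
        return Trace(samples=data[:, 0], dt=float(step))
    if data.shape[1] == 2:
        t = data[:, 0]
        diffs = np.diff(t)
        if diffs.size == 0:
            raise ValueError(f"{path}: need at least two samples to infer dt")
        step = float(diffs[0])
        if step <= 0 or np.max(np.abs(diffs - step)) > 1e-9 * abs(step):
            raise ValueError(f"{path}: time stamps are not uniformly spaced")
        return Trace(samples=data[:, 1], dt=step)
    raise ValueError(f"{path}: expected one or two numeric columns")


def write_counts(path, counts: SpikeCountSeries) -> None:
    fmt = "%d" if np.issubdtype(counts.counts.dtype, np.integer) else "%.17g"
    np.savetxt(
        path,
        counts.counts,
        fmt=fmt,
        header=f"dt={counts.dt!r} T={counts.duration!r}",
    )


def read_counts(path, dt: Optional[float] = None) -> SpikeCountSeries:
    step = _header_dt(path)
    if step is None:
        step = dt
    if step is None:
        raise ValueError(f"{path}: counts file needs dt in the header or as an argument")
    data = np.loadtxt(path)
    return SpikeCountSeries(counts=data, dt=float(step))


def write_raster(path, raster: Raster) -> None:
    np.savetxt(
        path,
        np.column_stack([raster.neuron_ids, raster.times]),
        fmt=("%d", "%.9f"),
        header=f"n_neurons={raster.n_neurons} duration={raster.duration!r}",
    )


def read_raster(path, n_neurons: int, duration: float) -> Raster:
    data = np.loadtxt(path, ndmin=2)
    if data.size == 0:
        return Raster(np.empty(0, np.int64), np.empty(0), n_neurons, duration)
    return Raster(data[:, 0].astype(np.int64), data[:, 1], n_neurons, duration)
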