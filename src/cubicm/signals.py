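"""Shared in-memory containers for spike counts, rasters and filtered traces."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class SpikeCountSeries:
    """Summed presynaptic spike counts on a uniform time grid.

    ``counts[i]`` is the number of input spikes falling into the i-th step of
    width ``dt`` (a float array when per-spike weights, e.g. heterogeneous
    synaptic amplitudes, are attached).
    """

    counts: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1 or self.counts.size == 0:
            raise ValueError("counts must be a non-empty 1-d array")
        if not self.dt > 0:
            raise ValueError("dt must be positive")

    @property
    def n_samples(self) -> int:
        return int(self.counts.size)

    @property
    def duration(self) -> float:
        return self.counts.size * self.dt


@dataclass
class Trace:
    """A uniformly sampled shot-noise / membrane-potential signal."""

    samples: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-d array")
        if not self.dt > 0:
            raise ValueError("dt must be positive")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        return self.samples.size * self.dt


@dataclass
class Raster:
    """Per-neuron spike times: parallel arrays of neuron ids and times (s)."""

    neuron_ids: np.ndarray
    times: np.ndarray
    n_neurons: int
    duration: float

    def __post_init__(self) -> None:
        self.neuron_ids = np.asarray(self.neuron_ids, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=float)
        if self.neuron_ids.shape != self.times.shape:
            raise ValueError("neuron_ids and times must have the same shape")
        if self.n_neurons < 1 or not self.duration > 0:
            raise ValueError("need n_neurons >= 1 and duration > 0")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    def spike_times(self, neuron: int) -> np.ndarray:
        return np.sort(self.times[self.neuron_ids == neuron])
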