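"""Synthetic correlated-population generator.

The summed spike activity of N presynaptic neurons is modeled as a compound
Poisson process Z(t) = sum_n n Y_n(t): the carrier processes Y_n are
independent Poisson processes with rate nu_n, and every carrier event of
order n stands for n neurons spiking synchronously.  The vector
(nu_1, ..., nu_N) is the correlation structure and xi = max{n | nu_n > 0} its
maximal order.

Besides the plain compound-Poisson count series this module generates the
robustness variants used to probe the inference: per-neuron rasters, uniform
spike-time jitter, lognormal-ISI (non-Poisson) single-neuron trains with the
same imposed coincidence structure, an added independent inhibitory
population, and per-neuron lognormal synaptic amplitudes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as _st

from .kernels import Kernel, filter_counts
from .signals import Raster, SpikeCountSeries, Trace


@dataclass
class CorrelationStructure:
    """Carrier rates nu[i] (events/s) of order i+1, i.e. nu[0] is nu_1."""

    nu: np.ndarray

    def __post_init__(self) -> None:
        self.nu = np.atleast_1d(np.asarray(self.nu, dtype=float))
        if self.nu.ndim != 1 or self.nu.size == 0:
            raise ValueError("nu must be a non-empty 1-d array")
        if np.any(self.nu < 0):
            raise ValueError("all rates must be non-negative")
        if not np.any(self.nu > 0):
            raise ValueError("at least one rate must be positive")

    @property
    def xi(self) -> int:
        """Maximal order of correlation: largest n with nu_n > 0."""
        return int(np.max(np.nonzero(self.nu)[0]) + 1)

    @property
    def spike_rate(self) -> float:
        """Total single-spike rate sum_n n nu_n (spikes/s)."""
        orders = np.arange(1, self.nu.size + 1, dtype=float)
        return float((orders * self.nu).sum())

    @property
    def sync_spike_rate(self) -> float:
        """Spike rate carried by events of order >= 2."""
        orders = np.arange(1, self.nu.size + 1, dtype=float)
        return float((orders[1:] * self.nu[1:]).sum())


@dataclass
class PopulationSpec:
    """Parameters of the simulated presynaptic population.

    A subpopulation of ``n_correlated`` of the ``n_neurons`` Poisson neurons
    (rate ``rate`` spikes/s each) shares synchronous events of the given
    ``order`` whose rate is set by the pairwise count-correlation coefficient
    ``c``.  ``jitter`` is the half-width (s) of uniform spike-time jitter;
    ``isi_model`` switches single-neuron backgrounds between Poisson and
    lognormal renewal with ISI coefficient of variation ``isi_cv``;
    ``amplitude_cv`` spreads per-neuron synaptic amplitudes; and
    ``inhibitory_rate`` > 0 adds an equally sized independent inhibitory
    population.
    """

    n_neurons: int
    n_correlated: int
    c: float
    order: int
    rate: float
    jitter: float = 0.0
    isi_model: str = "poisson"
    isi_cv: float = 1.0
    amplitude_cv: float = 0.0
    inhibitory_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.c < 1:
            raise ValueError("c must be in [0, 1)")
        if self.c > 0 and not 2 <= self.order <= self.n_correlated <= self.n_neurons:
            raise ValueError("need 2 <= order <= n_correlated <= n_neurons")
        if self.n_neurons < 1 or self.n_correlated < 0:
            raise ValueError("invalid population sizes")
        if not self.rate > 0:
            raise ValueError("rate must be positive")
        if self.jitter < 0 or self.amplitude_cv < 0 or self.inhibitory_rate < 0:
            raise ValueError("jitter, amplitude_cv, inhibitory_rate must be >= 0")
        if self.isi_model not in ("poisson", "lognormal"):
            raise ValueError("isi_model must be 'poisson' or 'lognormal'")
        if self.isi_model == "lognormal" and not self.isi_cv > 0:
            raise ValueError("isi_cv must be positive for lognormal ISIs")


def build_structure(spec: PopulationSpec) -> CorrelationStructure:
    """Single-order correlation structure matching (N, N_c, c, order, rate).

    Inverts the pairwise-correlation readout: the order-k carrier rate is
    nu_k = c * rate * N_c (N_c - 1) / (k (k - 1)), and nu_1 absorbs the rest
    of the population's spikes so that every neuron fires at ``rate``.
    """
    N, lam = spec.n_neurons, spec.rate
    if spec.c == 0:
        return CorrelationStructure(np.array([N * lam]))
    k, Nc = spec.order, spec.n_correlated
    nu = np.zeros(k)
    nu_k = spec.c * lam * Nc * (Nc - 1) / (k * (k - 1))
    nu_1 = N * lam - k * nu_k
    if nu_1 < 0:
        raise ValueError(
            "requested pairwise correlation too large for the per-neuron rate"
        )
    nu[0] = nu_1
    nu[k - 1] = nu_k
    return CorrelationStructure(nu)


def mip_structure(
    n_correlated: int, rate: float, c: float, n_total: Optional[int] = None
) -> CorrelationStructure:
    """Binomial-shaped ('multiple interaction process') structure.

    A mother Poisson process of rate ``rate / c`` is copied into each of the
    ``n_correlated`` neurons independently with probability p = c, so every
    pool neuron fires at ``rate`` and any pair has count correlation c.  The
    order-n carrier rate is the binomial term (rate/c) * B(n; N_c, c).  If
    ``n_total`` exceeds the pool size, the remaining neurons contribute
    independent spikes at ``rate`` to nu_1.
    """
    if not 0 < c < 1:
        raise ValueError("c must be in (0, 1) for a MIP structure")
    if n_correlated < 2:
        raise ValueError("need at least 2 correlated neurons")
    gamma = rate / c
    n = np.arange(1, n_correlated + 1)
    nu = gamma * _st.binom.pmf(n, n_correlated, c)
    if n_total is not None and n_total > n_correlated:
        nu[0] += (n_total - n_correlated) * rate
    return CorrelationStructure(nu)


def simulate_cpp(
    structure: CorrelationStructure,
    T: float,
    dt: float,
    rng=None,
    return_events: bool = False,
):
    """Simulate the compound-Poisson count series over [0, T).

    Each order-n carrier event adds n to the count in its time step (event
    times are floored onto the grid).  With ``return_events`` the raw carrier
    event times are returned as ``{order: sorted times}`` alongside.
    """
    if not T > 0 or not dt > 0:
        raise ValueError("T and dt must be positive")
    rng = np.random.default_rng(rng)
    L = int(round(T / dt))
    if L < 1:
        raise ValueError("T shorter than one time step")
    counts = np.zeros(L, dtype=np.int64)
    events: dict[int, np.ndarray] = {}
    for i, nu_n in enumerate(structure.nu):
        if nu_n <= 0:
            continue
        n = i + 1
        n_ev = rng.poisson(nu_n * T)
        if n_ev == 0:
            continue
        t = rng.uniform(0.0, T, n_ev)
        idx = np.minimum((t / dt).astype(np.int64), L - 1)
        counts += n * np.bincount(idx, minlength=L)
        if return_events:
            events[n] = np.sort(t)
    series = SpikeCountSeries(counts=counts, dt=dt)
    return (series, events) if return_events else series


def _poisson_train(rate: float, T: float, rng) -> np.ndarray:
    n = rng.poisson(rate * T)
    return np.sort(rng.uniform(0.0, T, n))


def _lognormal_train(rate: float, cv: float, T: float, rng) -> np.ndarray:
    """Lognormal renewal train with mean ISI 1/rate and ISI CV ``cv``."""
    mean_isi = 1.0 / rate
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean_isi) - sigma2 / 2.0
    sig = math.sqrt(sigma2)
    block = max(16, int(rate * T * 1.3) + 4 * int(math.sqrt(rate * T) + 1))
    times = np.cumsum(rng.lognormal(mu, sig, block))
    while times.size and times[-1] < T:
        times = np.concatenate(
            [times, times[-1] + np.cumsum(rng.lognormal(mu, sig, block))]
        )
    return times[times < T]


def _background_rates(
    structure: CorrelationStructure, spec: PopulationSpec
) -> tuple[float, float]:
    """Per-neuron independent rates (pool, outside) balancing marginals.

    Correlated neurons receive part of their rate through synchronous events
    (sync_spike_rate / N_c each), so their independent background is reduced
    such that every neuron's marginal rate equals spec.rate.
    """
    lam = spec.rate
    if spec.n_correlated == 0:
        return lam, lam
    r_sync = structure.sync_spike_rate / spec.n_correlated
    r_pool = lam - r_sync
    if r_pool < -1e-9 * lam:
        raise ValueError("synchronous rate exceeds the per-neuron rate")
    return max(r_pool, 0.0), lam


def simulate_population(
    spec: PopulationSpec,
    T: float,
    dt: float,
    rng=None,
    return_raster: bool = False,
    structure: Optional[CorrelationStructure] = None,
):
    """Simulate the population; counts by default, a Raster on request.

    For the raster, every order-n carrier event is assigned to n distinct
    neurons drawn uniformly from the correlated pool (membership re-drawn per
    event, making all pool pairs exchangeable), and independent background
    spikes are distributed so each neuron's marginal rate is spec.rate.
    """
    rng = np.random.default_rng(rng)
    if structure is None:
        structure = build_structure(spec)
    if not return_raster:
        return simulate_cpp(structure, T, dt, rng)
    raster = _raster_from_structure(structure, spec, T, rng, background="poisson")
    return raster


def simulate_nonpoisson(
    spec: PopulationSpec,
    T: float,
    dt: float,
    rng=None,
    return_raster: bool = False,
    structure: Optional[CorrelationStructure] = None,
):
    """Population with lognormal-ISI single-neuron background trains.

    The coincidence structure is imposed exactly as in the Poisson case by
    copying carrier-event times into the selected neurons' trains, so Poisson
    and non-Poisson surrogates share the same correlation structure; only the
    single-neuron inter-spike statistics differ.
    """
    if spec.isi_model != "lognormal":
        raise ValueError("spec.isi_model must be 'lognormal'")
    rng = np.random.default_rng(rng)
    if structure is None:
        structure = build_structure(spec)
    raster = _raster_from_structure(structure, spec, T, rng, background="lognormal")
    if return_raster:
        return raster
    return bin_raster(raster, dt)


def _raster_from_structure(
    structure: CorrelationStructure,
    spec: PopulationSpec,
    T: float,
    rng,
    background: str = "poisson",
) -> Raster:
    if not T > 0:
        raise ValueError("T must be positive")
    N, Nc = spec.n_neurons, spec.n_correlated
    r_pool, r_out = _background_rates(structure, spec)
    ids: list[np.ndarray] = []
    ts: list[np.ndarray] = []
    # synchronous carrier events, orders >= 2
    for i, nu_n in enumerate(structure.nu[1:], start=2):
        if nu_n <= 0:
            continue
        n_ev = rng.poisson(nu_n * T)
        for _ in range(n_ev):
            t = rng.uniform(0.0, T)
            members = rng.choice(Nc, size=i, replace=False)
            ids.append(members.astype(np.int64))
            ts.append(np.full(i, t))
    # independent background spikes
    for neuron in range(N):
        r = r_pool if neuron < Nc else r_out
        if r <= 0:
            continue
        if background == "poisson":
            t = _poisson_train(r, T, rng)
        else:
            t = _lognormal_train(r, spec.isi_cv, T, rng)
        if t.size:
            ids.append(np.full(t.size, neuron, dtype=np.int64))
            ts.append(t)
    neuron_ids = np.concatenate(ids) if ids else np.empty(0, dtype=np.int64)
    times = np.concatenate(ts) if ts else np.empty(0)
    return Raster(neuron_ids=neuron_ids, times=times, n_neurons=N, duration=T)


def apply_jitter(raster: Raster, j: float, rng=None) -> Raster:
    """Shift every spike independently by U(-j, +j), clipped into [0, T).

    Jitter is applied before binning; simulating with a leading warm-up
    window absorbs boundary effects, and no spike is ever dropped.
    """
    if j < 0:
        raise ValueError("jitter must be non-negative")
    rng = np.random.default_rng(rng)
    if j == 0:
        return Raster(
            raster.neuron_ids.copy(),
            raster.times.copy(),
            raster.n_neurons,
            raster.duration,
        )
    shifted = raster.times + rng.uniform(-j, j, raster.times.size)
    eps = raster.duration * 1e-12
    shifted = np.clip(shifted, 0.0, raster.duration - eps)
    return Raster(raster.neuron_ids.copy(), shifted, raster.n_neurons, raster.duration)


def bin_raster(
    raster: Raster, dt: float, weights: Optional[np.ndarray] = None
) -> SpikeCountSeries:
    """Bin raster spikes (optionally weighted per spike) onto a dt grid."""
    if not dt > 0:
        raise ValueError("dt must be positive")
    L = int(round(raster.duration / dt))
    idx = np.minimum((raster.times / dt).astype(np.int64), L - 1)
    counts = np.bincount(idx, weights=weights, minlength=L)
    if weights is None:
        counts = counts.astype(np.int64)
    return SpikeCountSeries(counts=counts, dt=dt)


def mix_inhibition(
    trace: Trace,
    kernel: Kernel,
    n_inhibitory: int,
    rate_inhibitory: float,
    rng=None,
    warmup: float = 1.0,
) -> Trace:
    """Add an independent inhibitory population filtered with -phi.

    ``n_inhibitory`` independent Poisson trains at ``rate_inhibitory`` each
    are summed, filtered with the sign-flipped kernel, and added onto the
    excitatory trace.
    """
    if rate_inhibitory < 0:
        raise ValueError("rate_inhibitory must be >= 0")
    if rate_inhibitory == 0 or n_inhibitory == 0:
        return Trace(trace.samples.copy(), trace.dt)
    rng = np.random.default_rng(rng)
    total_rate = n_inhibitory * rate_inhibitory
    n_warm = int(round(warmup / trace.dt))
    counts = rng.poisson(total_rate * trace.dt, trace.n_samples + n_warm)
    inh = filter_counts(
        SpikeCountSeries(counts, trace.dt),
        kernel.with_amplitude(-kernel.amplitude),
        warmup=warmup,
    )
    return Trace(trace.samples + inh.samples, trace.dt)


def heterogeneous_amplitude_filter(
    raster: Raster,
    kernel: Kernel,
    amplitude_cv: float,
    dt: float,
    rng=None,
    warmup: float = 1.0,
) -> Trace:
    """Filter each neuron's train with its own lognormal amplitude.

    Per-neuron amplitudes are lognormal with mean kernel.amplitude and the
    requested coefficient of variation; by linearity of convolution the trace
    is computed as one filtering pass over amplitude-weighted counts.
    """
    if amplitude_cv < 0:
        raise ValueError("amplitude_cv must be >= 0")
    rng = np.random.default_rng(rng)
    A = kernel.amplitude
    if amplitude_cv == 0:
        amps = np.full(raster.n_neurons, A)
    else:
        sigma2 = math.log(1.0 + amplitude_cv**2)
        mu = math.log(abs(A)) - sigma2 / 2.0
        amps = math.copysign(1.0, A) * rng.lognormal(
            mu, math.sqrt(sigma2), raster.n_neurons
        )
    weighted = bin_raster(raster, dt, weights=amps[raster.neuron_ids])
    return filter_counts(weighted, kernel.with_amplitude(1.0), warmup=warmup)
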