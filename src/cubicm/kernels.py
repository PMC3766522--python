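"""Postsynaptic filter kernels and shot-noise filtering of spike counts.

A kernel phi(t) maps one presynaptic spike onto a postsynaptic deflection.
Three families are supported:

``exponential``
    phi(t) = A exp(-t/tau), the impulse response of a leaky integrator with
    membrane time constant tau driven by pulse currents.
``rectangular``
    phi(t) = A for 0 <= t < tau; filtering with it and reading the result at
    multiples of tau is ordinary spike-count binning with bin width tau.
``alpha``
    the postsynaptic potential of an alpha-shaped synaptic current: a
    normalized difference of exponentials with decay tau and rise tau_alpha,
    scaled so that its *peak* equals A.  For tau_alpha -> 0 it converges to
    the exponential kernel; for tau_alpha == tau the canonical alpha function
    A * (t/tau) * e^(1 - t/tau) is used.  The time of the peak is
    t_peak = ln(tau/tau_alpha) * tau * tau_alpha / (tau - tau_alpha)
    (t_peak = tau in the degenerate case).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as _sig

from .signals import SpikeCountSeries, Trace

FAMILIES = ("exponential", "rectangular", "alpha")

#: Highest kernel power needed anywhere (sixth cumulant of the null).
M_MAX = 6


@dataclass(frozen=True)
class Kernel:
    """Parametric filter kernel phi(t).

    Parameters
    ----------
    family
        One of ``exponential``, ``rectangular``, ``alpha``.
    amplitude
        Signal units (e.g. mV) contributed by one spike: the initial value of
        the exponential, the plateau of the rectangle, or the peak of the
        alpha kernel.  Negative for inhibitory input.
    tau
        Decay time constant in seconds (window width for ``rectangular``).
    tau_alpha
        Rise time in seconds, ``alpha`` family only; must satisfy
        0 < tau_alpha <= tau.
    """

    family: str
    amplitude: float
    tau: float
    tau_alpha: float | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}")
        if not self.tau > 0:
            raise ValueError("tau must be positive")
        if self.amplitude == 0:
            raise ValueError("amplitude must be nonzero")
        if self.family == "alpha":
            if self.tau_alpha is None or not 0 < self.tau_alpha <= self.tau:
                raise ValueError("alpha family needs 0 < tau_alpha <= tau")

    def with_amplitude(self, amplitude: float) -> "Kernel":
        return replace(self, amplitude=amplitude)

    @property
    def time_to_peak(self) -> float:
        if self.family != "alpha":
            return 0.0
        ta, t = self.tau_alpha, self.tau
        if ta == t:
            return t
        return math.log(t / ta) * t * ta / (t - ta)


def _alpha_peak_unnormalized(tau: float, tau_alpha: float) -> float:
    """Peak of e^(-t/tau) - e^(-t/tau_alpha) for tau_alpha < tau."""
    tp = math.log(tau / tau_alpha) * tau * tau_alpha / (tau - tau_alpha)
    return math.exp(-tp / tau) - math.exp(-tp / tau_alpha)


def kernel_shape(kernel: Kernel, t: np.ndarray) -> np.ndarray:
    """Evaluate phi(t) on an array of times (phi = 0 for t < 0)."""
    t = np.asarray(t, dtype=float)
    A, tau = kernel.amplitude, kernel.tau
    if kernel.family == "exponential":
        y = np.where(t >= 0, np.exp(-np.clip(t, 0, None) / tau), 0.0)
    elif kernel.family == "rectangular":
        y = ((t >= 0) & (t < tau)).astype(float)
    else:
        ta = kernel.tau_alpha
        tc = np.clip(t, 0, None)
        if ta == tau:
            y = (tc / tau) * np.exp(1.0 - tc / tau)
        else:
            c = _alpha_peak_unnormalized(tau, ta)
            y = (np.exp(-tc / tau) - np.exp(-tc / ta)) / c
        y = np.where(t >= 0, y, 0.0)
    return A * y


def kernel_integral_power(kernel: Kernel, m: int) -> float:
    """Closed-form integral of phi(t)^m over the real line, m in 1..6.

    These constants link the rates of synchronous input events to the
    stationary cumulants of the filtered signal (Campbell's theorem for
    compound shot noise).
    """
    if not isinstance(m, (int, np.integer)) or not 1 <= m <= M_MAX:
        raise ValueError(f"m must be an integer in 1..{M_MAX}, got {m}")
    A, tau = kernel.amplitude, kernel.tau
    if kernel.family == "exponential":
        return A**m * tau / m
    if kernel.family == "rectangular":
        return A**m * tau
    ta = kernel.tau_alpha
    if ta == tau:
        # integral of ((t/tau) e^(1-t/tau))^m = e^m * tau * m! / m^(m+1)
        return A**m * math.exp(m) * tau * math.factorial(m) / m ** (m + 1)
    c = _alpha_peak_unnormalized(tau, ta)
    s = 0.0
    for j in range(m + 1):
        rate = (m - j) / tau + j / ta
        s += math.comb(m, j) * (-1.0) ** j / rate
    return (A / c) ** m * s


def filter_counts(
    counts: SpikeCountSeries, kernel: Kernel, warmup: float = 1.0
) -> Trace:
    """Convolve binned spike counts with the kernel.

    The exponential family uses the exact-integration recursion
    ``s[i] = s[i-1] * exp(-dt/tau) + A * n[i]`` (spikes act at the start of
    their bin); rectangular and alpha kernels are convolved with the kernel
    sampled on the same grid.  Samples within the leading ``warmup`` window
    are computed but dropped from the returned trace, so onset transients do
    not contaminate the stationary statistics.
    """
    n = np.asarray(counts.counts, dtype=float)
    dt = counts.dt
    n_warm = int(round(warmup / dt))
    if n_warm < 0:
        raise ValueError("warmup must be non-negative")
    if n_warm >= n.size:
        raise ValueError("warm-up window longer than the count series")
    A, tau = kernel.amplitude, kernel.tau
    if kernel.family == "exponential":
        s = _sig.lfilter([A], [1.0, -math.exp(-dt / tau)], n)
    else:
        if kernel.family == "rectangular":
            t_cut = tau
        else:
            # decay governed by tau; cut where the envelope is ~1e-15 * peak
            c = 1.0 if kernel.tau_alpha == tau else _alpha_peak_unnormalized(
                tau, kernel.tau_alpha
            )
            t_cut = kernel.time_to_peak + tau * (35.0 + max(0.0, -math.log(c)))
        n_k = max(1, int(math.ceil(t_cut / dt)) + 1)
        k_samp = kernel_shape(kernel, np.arange(n_k) * dt)
        s = _sig.fftconvolve(n, k_samp)[: n.size]
    return Trace(samples=s[n_warm:], dt=dt)
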