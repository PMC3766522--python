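"""Sample cumulants (k-statistics), theoretical shot-noise cumulants, and the
sampling variance of the third k-statistic.

The first three k-statistics are the unique symmetric unbiased estimators of
the cumulants of an iid sample.  On kernel-filtered traces consecutive samples
are *not* independent; the resulting underestimation of Var(k3) is compensated
downstream by the surrogate-based correction factor, not here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .kernels import Kernel, kernel_integral_power


@dataclass(frozen=True)
class CumulantSet:
    """First three sample cumulants of a trace of length L."""

    k1: float
    k2: float
    k3: float
    L: int


def sample_cumulants(trace) -> CumulantSet:
    """Unbiased k-statistics k1, k2, k3 of a trace (or plain array).

    k1 = mean, k2 = L/(L-1) m2, k3 = L^2 m3 / ((L-1)(L-2)) with m2, m3 the
    central sample moments.  Requires at least three samples.
    """
    x = np.asarray(getattr(trace, "samples", trace), dtype=float).ravel()
    L = x.size
    if L < 3:
        raise ValueError("need at least 3 samples for k1..k3")
    k1 = float(x.mean())
    d = x - k1
    d2 = d * d
    m2 = float(d2.mean())
    m3 = float((d2 * d).mean())
    k2 = m2 * L / (L - 1)
    k3 = m3 * L * L / ((L - 1) * (L - 2))
    return CumulantSet(k1=k1, k2=k2, k3=k3, L=L)


def theoretical_cumulant(structure, kernel: Kernel, m: int) -> float:
    """m-th stationary cumulant of the filtered compound-Poisson signal.

    kappa_m = sum_n n^m nu_n * integral(phi^m): each synchronous event of
    order n contributes with weight n^m, which is what makes the third
    cumulant sensitive to higher-order correlation.
    """
    nu = np.asarray(structure.nu, dtype=float)
    orders = np.arange(1, nu.size + 1, dtype=float)
    return float((orders**m * nu).sum() * kernel_integral_power(kernel, m))


def var_k3(kappa: Sequence[float], L: int) -> float:
    """Sampling variance of the third k-statistic for an iid sample.

    Parameters
    ----------
    kappa
        The population cumulants (kappa2, kappa3, kappa4, kappa5, kappa6).
        kappa5 does not enter the classical formula but is carried so callers
        can pass the full null-cumulant vector.
    L
        Sample size (>= 3).

    Returns
    -------
    Var(k3) = kappa6/L + 9 (kappa2 kappa4 + kappa3^2)/(L-1)
              + 6 L kappa2^3 / ((L-1)(L-2))
    """
    if L < 3:
        raise ValueError("need L >= 3")
    k2, k3, k4, _k5, k6 = (float(k) for k in kappa)
    return (
        k6 / L
        + 9.0 * (k2 * k4 + k3 * k3) / (L - 1)
        + 6.0 * L * k2**3 / ((L - 1) * (L - 2))
    )
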