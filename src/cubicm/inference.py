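"""The CuBICm hypothesis-test chain.

For each candidate order k the null H0^k states that the first three cumulants
of the trace are consistent with input correlations of order at most k.  Given
the measured k1, k2 the largest third cumulant attainable under H0^k,
kappa*_{3,k}, is found in closed form (the maximizing structure has carrier
rates only at orders 1 and k); the third sample cumulant k3 is compared to it
with a normal approximation whose standard deviation sigma*_k derives from the
null cumulants up to order six.  Because kernel filtering correlates
consecutive samples, sigma*_k is inflated by a surrogate-estimated correction
factor f_c.  The lower confidence bound on the maximal order of correlation is
the first k at which H0^k survives.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import norm as _norm

from .cumstats import sample_cumulants, var_k3
from .kernels import Kernel, filter_counts, kernel_integral_power
from .signals import SpikeCountSeries, Trace

logger = logging.getLogger("cubicm")


@dataclass(frozen=True)
class H0Bound:
    """Null bound for order k: maximizing rates, cumulants and test SD."""

    k: int
    nu1_star: float
    nuk_star: float
    kappa3_star: float
    kappa_m_star: tuple  # (kappa*_2, ..., kappa*_6)
    sigma_star: float
    clamped: bool


@dataclass
class InferenceResult:
    """Outcome of the sequential test: bound, p-values and settings."""

    xi_hat: int
    p_values: tuple
    alpha: float
    f_c: float
    censored: bool
    k1: float
    k2: float
    k3: float
    L: int
    dt: float
    kernel: Kernel
    resting_offset: float
    kappa3_star: tuple = ()
    sigma_star: tuple = ()

    def to_dict(self) -> dict:
        return {
            "xi_hat": int(self.xi_hat),
            "p_values": [float(p) for p in self.p_values],
            "alpha": self.alpha,
            "f_c": self.f_c,
            "censored": self.censored,
            "k1": self.k1,
            "k2": self.k2,
            "k3": self.k3,
            "L": self.L,
            "dt": self.dt,
            "kernel": {
                "family": self.kernel.family,
                "amplitude": self.kernel.amplitude,
                "tau": self.kernel.tau,
                "tau_alpha": self.kernel.tau_alpha,
            },
            "resting_offset": self.resting_offset,
            "kappa3_star": [float(v) for v in self.kappa3_star],
            "sigma_star": [float(v) for v in self.sigma_star],
        }


def h0_bound(k1: float, k2: float, k: int, kernel: Kernel, L: int) -> H0Bound:
    """Maximal null cumulants under H0^k given measured k1, k2.

    With a_m = integral(phi^m), the constrained maximum of the third cumulant
    over non-negative rate vectors supported on orders <= k is attained with
    mass at orders 1 and k only:

        nu_k* = (k2/a2 - k1/a1) / (k (k - 1)),   nu_1* = k1/a1 - k nu_k*,

    giving kappa*_{m,k} = a_m (nu_1* + k^m nu_k*).  The k = 1 case is the
    continuous extension kappa*_{m,1} = a_m (k1/a1 + (m-1)(k2/a2 - k1/a1)).
    Infeasible corners are clamped conservatively (flag ``clamped``): a
    sub-Poisson signal (nu_k* < 0) collapses onto pure order-1 input, and
    nu_1* < 0 collapses onto pure order-k input.  Requires integral(phi^3) > 0;
    inhibitory kernels are handled upstream by sign-flipping trace and kernel.
    """
    if not isinstance(k, (int, np.integer)) or k < 1:
        raise ValueError("k must be a positive integer")
    a = [kernel_integral_power(kernel, m) for m in range(1, 7)]
    a1, a2, a3 = a[0], a[1], a[2]
    if a1 == 0 or a2 == 0:
        raise ValueError("degenerate kernel: integral(phi) and integral(phi^2) must be nonzero")
    if a3 <= 0:
        raise ValueError(
            "integral(phi^3) must be positive; for inhibitory kernels flip the "
            "sign of trace and kernel first"
        )
    r1 = k1 / a1
    D = k2 / a2 - r1
    clamped = False
    if k == 1:
        if D < 0:
            D = 0.0
            clamped = True
        kappa = tuple(a[m - 1] * (r1 + (m - 1) * D) for m in range(2, 7))
        nu1, nuk = r1, 0.0
    else:
        nuk = D / (k * (k - 1))
        if nuk < 0:
            nuk, nu1 = 0.0, r1
            clamped = True
        else:
            nu1 = r1 - k * nuk
            if nu1 < 0:
                nu1, nuk = 0.0, k2 / (k * k * a2)
                clamped = True
        kappa = tuple(a[m - 1] * (nu1 + float(k) ** m * nuk) for m in range(2, 7))
    sigma = math.sqrt(max(var_k3(kappa, L), 0.0))
    return H0Bound(
        k=int(k),
        nu1_star=float(nu1),
        nuk_star=float(nuk),
        kappa3_star=float(kappa[1]),
        kappa_m_star=kappa,
        sigma_star=sigma,
        clamped=clamped,
    )


def p_value(k3: float, kappa3_star: float, sigma: float) -> float:
    """p = 1 - Phi((k3 - kappa*_{3,k}) / sigma), the upper-tail normal test."""
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    return float(_norm.sf((k3 - kappa3_star) / sigma))


def correction_factor(
    k1: float,
    kernel: Kernel,
    dt: float,
    L: int,
    n_surrogates: int = 20,
    rng=None,
    warmup: float = 1.0,
    k2: Optional[float] = None,
    sigma_basis: str = "surrogate",
) -> float:
    """Correlated-sample correction f_c = std(k3 surrogates) / sigma*_1.

    The rate of equivalent independent input is lambda = k1 / integral(phi);
    ``n_surrogates`` independent-Poisson shot-noise traces with the same
    kernel, dt, warm-up and length as the data are simulated, and the
    empirical SD of their third k-statistics is divided by the theoretical
    iid sigma*_1.  By default sigma*_1 is evaluated from the surrogates' own
    averaged H0^1 cumulants, isolating the pure sample-correlation effect;
    ``sigma_basis='data'`` uses the data's (k1, k2) instead.  The same f_c is
    reused for every k: the relative bias of sigma*_k is order-independent.
    """
    if n_surrogates < 2:
        raise ValueError("need at least 2 surrogates")
    if sigma_basis not in ("surrogate", "data"):
        raise ValueError("sigma_basis must be 'surrogate' or 'data'")
    a1 = kernel_integral_power(kernel, 1)
    lam = k1 / a1
    if not lam > 0:
        raise ValueError("implied input rate k1/integral(phi) must be positive")
    rng = np.random.default_rng(rng)
    n_warm = int(round(warmup / dt))
    k3s = np.empty(n_surrogates)
    kappa_acc = np.zeros(5)
    for i in range(n_surrogates):
        counts = rng.poisson(lam * dt, L + n_warm)
        tr = filter_counts(SpikeCountSeries(counts, dt), kernel, warmup=warmup)
        cs = sample_cumulants(tr)
        k3s[i] = cs.k3
        kappa_acc += h0_bound(cs.k1, cs.k2, 1, kernel, cs.L).kappa_m_star
    sd = float(np.std(k3s, ddof=1))
    if sigma_basis == "surrogate":
        sigma1 = math.sqrt(max(var_k3(kappa_acc / n_surrogates, L), 0.0))
    else:
        if k2 is None:
            raise ValueError("sigma_basis='data' requires k2")
        sigma1 = h0_bound(k1, k2, 1, kernel, L).sigma_star
    if not sigma1 > 0:
        raise ValueError("sigma*_1 is not positive; degenerate signal")
    return sd / sigma1


def infer_xi(
    trace: Trace,
    kernel: Kernel,
    alpha: float = 0.05,
    use_correction: bool = True,
    resting_offset: float = 0.0,
    k_max: int = 1000,
    n_surrogates: int = 20,
    rng=None,
    warmup: float = 1.0,
    sigma_basis: str = "surrogate",
) -> InferenceResult:
    """Sequential CuBICm test: lower confidence bound on the maximal order.

    Subtracts the resting offset, measures k1..k3, estimates f_c once (when
    enabled), then tests H0^1, H0^2, ... and returns the first k whose null
    survives (p_k > alpha).  If every k up to ``k_max`` is rejected the result
    carries ``censored=True`` and must not be read as a valid bound.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    x = np.asarray(trace.samples, dtype=float) - resting_offset
    if x.size < 3:
        raise ValueError("trace too short")
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) trace")
    kern = kernel
    if kernel_integral_power(kern, 3) < 0:
        # inhibitory kernel: the bound becomes a minimum; mirror both signal
        # and kernel so the standard maximization applies
        x = -x
        kern = kern.with_amplitude(-kern.amplitude)
    cs = sample_cumulants(x)
    rng = np.random.default_rng(rng)
    if use_correction:
        # surrogate seed split off the experiment stream
        child = rng.spawn(1)[0]
        f_c = correction_factor(
            cs.k1,
            kern,
            trace.dt,
            cs.L,
            n_surrogates=n_surrogates,
            rng=child,
            warmup=warmup,
            k2=cs.k2,
            sigma_basis=sigma_basis,
        )
    else:
        f_c = 1.0
    p_values: list[float] = []
    kappa3s: list[float] = []
    sigmas: list[float] = []
    xi_hat = k_max
    censored = True
    for k in range(1, k_max + 1):
        b = h0_bound(cs.k1, cs.k2, k, kern, cs.L)
        sig = f_c * b.sigma_star
        p = p_value(cs.k3, b.kappa3_star, sig)
        p_values.append(p)
        kappa3s.append(b.kappa3_star)
        sigmas.append(b.sigma_star)
        logger.info(
            "k=%d kappa3*=%.6g f_c*sigma*=%.6g p=%.4g", k, b.kappa3_star, sig, p
        )
        if p > alpha:
            xi_hat = k
            censored = False
            break
    return InferenceResult(
        xi_hat=xi_hat,
        p_values=tuple(p_values),
        alpha=alpha,
        f_c=f_c,
        censored=censored,
        k1=cs.k1,
        k2=cs.k2,
        k3=cs.k3,
        L=cs.L,
        dt=trace.dt,
        kernel=kernel,
        resting_offset=resting_offset,
        kappa3_star=tuple(kappa3s),
        sigma_star=tuple(sigmas),
    )


def pairwise_c_from_cumulants(
    kappa1: float, kappa2: float, kernel: Kernel, N: int, N_c: int
) -> float:
    """Pairwise count-correlation coefficient implied by kappa1 and kappa2.

    c = (N kappa2 a1 / (kappa1 a2) - N) / (N_c^2 - N_c): the excess of the
    signal's variance-to-mean ratio over the independent-population value,
    attributed to an N_c-neuron correlated subpopulation.
    """
    if N_c < 2:
        raise ValueError("need N_c >= 2")
    if not kappa1 > 0:
        raise ValueError("kappa1 must be positive")
    a1 = kernel_integral_power(kernel, 1)
    a2 = kernel_integral_power(kernel, 2)
    return (N * kappa2 * a1 / (kappa1 * a2) - N) / (N_c**2 - N_c)
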