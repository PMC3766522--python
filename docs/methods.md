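# Methods

## The model

A neuron's subthreshold membrane potential is treated as linearly filtered
presynaptic spike activity.  The summed input of N presynaptic neurons is a
compound Poisson process (CPP)

    Z(t) = sum_n n * Y_n(t),

where the carrier processes Y_n are independent stationary Poisson processes
with rates nu_n; an event of Y_n stands for n neurons firing synchronously.
The vector (nu_1, ..., nu_N) is the *correlation structure* and
xi = max{n : nu_n > 0} the *maximal order of correlation*.  The observable
signal is the shot noise S = Z * phi, where phi is a fixed postsynaptic
kernel.  For CPP shot noise the stationary cumulants obey a Campbell-type
relation,

    kappa_m[S] = sum_n n^m nu_n * integral(phi^m),   m = 1, 2, ...

so a synchronous event of order n enters kappa_m with weight n^m — this
n-cubed leverage on the third cumulant is what the inference exploits.

## The sequential test

Given a trace of L samples, the first three k-statistics k1, k2, k3 (the
unbiased sample cumulants) are measured.  The null H0^k — "the cumulants are
consistent with correlation orders <= k" — caps the third cumulant: with
a_m = integral(phi^m) the maximum of sum n^3 nu_n a3 subject to the k1 and k2
constraints and nu >= 0 over orders 1..k is attained with mass at orders 1
and k only,

    nu_k* = (k2/a2 - k1/a1) / (k(k-1)),   nu_1* = k1/a1 - k nu_k*,
    kappa*_{m,k} = a_m (nu_1* + k^m nu_k*),

which for the exponential kernel is independent of tau (a3/a1 and a3/a2 carry
only amplitude factors).  At k = 1 the two constraints cannot both be met by
a one-parameter structure; the bound is the continuous extension
kappa*_{m,1} = a_m (k1/a1 + (m-1)(k2/a2 - k1/a1)), validated against a
linear-programming oracle alongside the k >= 2 formula.  Infeasible corners
are clamped conservatively: nu_k* < 0 (a sub-Poisson signal) collapses to
pure order-1 input, nu_1* < 0 to pure order-k input; both only lower the
bound.  Negative kernels (inhibitory input, integral(phi^3) < 0) are handled
by mirroring trace and kernel, which turns the minimum problem into the
standard maximum.

The p-value is p_k = 1 - Phi((k3 - kappa*_{3,k}) / sigma*_k), where
sigma*_k^2 is the iid sampling variance of the third k-statistic evaluated at
the null cumulants up to order six,

    Var(k3) = kappa6/L + 9(kappa2*kappa4 + kappa3^2)/(L-1)
              + 6 L kappa2^3 / ((L-1)(L-2)),

frozen after Monte-Carlo validation on iid samples (within 10% at L = 1000
over 10^4 replicates).  Testing k = 1, 2, ... in unit steps, the estimate is
xi_hat = first k whose null survives (p_k > alpha); if every k up to k_max
(default 1000) is rejected the result is flagged censored and is not a valid
bound.  xi_hat is a *lower confidence bound*: it is expected to sit at or
below the true order, the more so the weaker the pairwise correlation.

## Correction for correlated samples

Kernel filtering correlates consecutive samples, so the iid Var(k3) formula
underestimates the true sampling variance — strongly for tau much larger
than the sampling interval (at tau = 10 ms and 20 kHz the underestimation
factor is ~11) — which makes the uncorrected test anti-conservative.  The
correction simulates n_surrogates = 20 independent-Poisson shot-noise traces
at the rate lambda = k1/a1 implied by the data, with identical kernel,
sampling step, warm-up and length, and sets

    f_c = std(k3 over surrogates) / sigma*_1.

Every test then uses f_c * sigma*_k; the relative bias of sigma*_k is taken
to be order-independent.  By default sigma*_1 in the ratio is computed from
the surrogates' own averaged H0^1 cumulants, so the ratio isolates the pure
sample-correlation effect; `sigma_basis="data"` switches to the data's
(k1, k2), the other defensible reading.  The two coincide for independent
input; for correlated data the default is slightly more conservative (lower
xi_hat).  The surrogate random stream is split off the caller's generator, so
one seed reproduces an entire experiment.

An equivalent but data-hungry alternative is downsampling: keeping every
i-th sample with the sampling interval >= tau restores the iid calibration
at the price of correspondingly longer recordings.

## Pairwise correlation read-out

For a population in which a subpopulation of N_c neurons is correlated, the
signal's first two cumulants return the pairwise count-correlation
coefficient

    c = (N kappa2 a1 / (kappa1 a2) - N) / (N_c^2 - N_c),

the exact inverse of the structure builder, so build -> theoretical cumulants
-> read-out is an identity (checked to 1e-12).  Because kappa1 is not
shift-invariant, an error in the subtracted resting potential biases c and
hence xi_hat: under-subtraction inflates both.

## Kernels

* `exponential`: phi(t) = A e^(-t/tau) — a leaky integrator with pulse
  currents.  Filtering uses the exact-integration recursion
  s[i] = s[i-1] e^(-dt/tau) + A n[i] (spikes act at the start of their bin;
  sub-step spike times are floored onto the grid).
* `rectangular`: phi = A on [0, h); filtering plus reading at multiples of h
  is ordinary spike-count binning, which recovers the count-based form of the
  bound, k1 + (k+1)(k2 - k1).
* `alpha`: the postsynaptic potential of an alpha-shaped synaptic current,
  implemented as a normalized difference of exponentials with decay tau and
  rise tau_alpha (0 < tau_alpha <= tau), scaled so the *peak* equals A.  The
  peak time is t_peak = ln(tau/tau_alpha) tau tau_alpha/(tau - tau_alpha);
  the degenerate tau_alpha = tau case uses A (t/tau) e^(1 - t/tau) with
  t_peak = tau.  All power integrals are closed forms (binomial expansion of
  the difference).  Because of the peak normalization the alpha kernel
  converges to the exponential one as tau_alpha -> 0 at rate
  O(tau_alpha ln tau_alpha), i.e. ~0.7% per power at tau_alpha = tau/1000.
  Rectangular and alpha filtering use dense convolution with the sampled
  kernel, cut where the envelope falls below ~1e-15 of the peak; it agrees
  with the exponential recursion path to 1e-9 relative error.

Defaults follow the simulation convention throughout: dt = 0.05 ms (20 kHz),
1 s warm-up generated and discarded, amplitude A = 1, alpha = 0.05, 20
correction surrogates.  All are overridable.

## The synthetic-data generator

`build_structure` inverts the pairwise-correlation relation for a
single-order structure: nu_order = c lambda N_c (N_c - 1)/(order(order - 1)),
with nu_1 absorbing the remaining spikes so every neuron's marginal rate is
lambda.  `mip_structure` provides the binomial-shaped alternative (a mother
process of rate lambda/c copied into each pool neuron with probability
p = c), which also yields marginal rate lambda and pairwise correlation c.
Rasters assign each order-n event to n distinct neurons drawn uniformly from
the correlated pool, re-drawn per event, making all pool pairs exchangeable;
correlated neurons get correspondingly reduced independent background so the
marginal rate stays lambda.

Robustness variants: uniform spike-time jitter on [-j, +j] applied before
binning (clipped into the simulated window; the warm-up buffer absorbs edge
effects, and no spike is dropped); lognormal-ISI renewal backgrounds with
the same injected coincidences (identical correlation structure, non-Poisson
single-neuron statistics; trains start at t = 0 rather than in equilibrium,
which the warm-up masks); per-neuron lognormal synaptic amplitudes with mean
pinned at A (computed as one filtering pass over amplitude-weighted counts,
exact by linearity); and an equally sized independent inhibitory population
filtered with -phi.

What the generator does *not* emulate: conductance-based synapses, dendritic
filtering, active membrane currents, rate non-stationarity, and
excitatory-inhibitory correlations.  Passing tests therefore show the
statistics of the inference chain are right under the stated point-process
model, not that real intracellular recordings meet its assumptions.

## Problem sizes in the shipped tests

The test suite re-runs the simulation studies at the stated physical
conditions with these repetition counts, chosen as the package's own
trade-off between statistical resolution and suite runtime: 200 calibration
datasets (correction applied to the first 100), 50 runs of the N=1000
order-20 dataset, 20 runs of the N=10000 order-40 dataset, 50 downsampled
calibration runs at fixed L = 50,000 coarse samples (the sample-correlation
bias under test is L-independent), and 12 runs per point for the 3-point
directional-robustness sweeps.  The resting-potential sweep uses shifts of
+/-5 kernel amplitudes: a shift of 0.5 A perturbs k1 by only ~2.5% in these
populations, far below what such repetition counts can resolve.  The
robustness population is a single-order structure (N = 200, N_c = 200,
order 20, c = 0.01, lambda = 10/s, tau = 10 ms, T = 30 s).

## Known limitations

* The normal approximation for k3 and the order-independence assumption for
  f_c are approximations; the corrected test is slightly conservative, and
  xi_hat under-covers the true order for weak correlations (by design — it
  is a bound, not an estimator).
* At very low implied rates (k1/a1 <= 0, e.g. strong inhibition pulling the
  mean to zero) the correction factor is undefined and the corrected test
  refuses to run.
* The MIP structure builder ties the copy probability to c (p = c); other
  (gamma, p) combinations with the same marginal rate and c are possible but
  not exposed.
* Censored results (all k <= k_max rejected) are reported as such and must
  not be read as bounds.
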