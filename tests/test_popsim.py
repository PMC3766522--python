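import numpy as np
import pytest

from cubicm import (
    CorrelationStructure,
    Kernel,
    PopulationSpec,
    SpikeCountSeries,
    Trace,
    apply_jitter,
    bin_raster,
    build_structure,
    filter_counts,
    heterogeneous_amplitude_filter,
    mip_structure,
    mix_inhibition,
    pairwise_c_from_cumulants,
    sample_cumulants,
    simulate_cpp,
    simulate_nonpoisson,
    simulate_population,
    theoretical_cumulant,
)


class TestCorrelationStructure:
    def test_xi_is_highest_active_order(self):
        s = CorrelationStructure([1.0, 0.0, 2.0, 0.0])
        assert s.xi == 3
        assert s.spike_rate == pytest.approx(1.0 + 3 * 2.0)

    @pytest.mark.parametrize("nu", [[], [-1.0], [0.0, 0.0]])
    def test_invalid_rates(self, nu):
        with pytest.raises(ValueError):
            CorrelationStructure(np.array(nu))


class TestBuildStructure:
    def test_default_blue_dataset_rates(self):
        spec = PopulationSpec(n_neurons=1000, n_correlated=100, c=0.05, order=20, rate=5.0)
        s = build_structure(spec)
        assert s.nu[19] == pytest.approx(0.05 * 5 * 100 * 99 / (20 * 19))
        assert s.nu[0] == pytest.approx(1000 * 5 - 20 * s.nu[19])
        assert s.xi == 20

    def test_independent_population(self):
        spec = PopulationSpec(n_neurons=50, n_correlated=0, c=0.0, order=2, rate=3.0)
        s = build_structure(spec)
        assert s.nu.tolist() == [150.0]
        assert s.xi == 1

    def test_pairwise_order_two(self):
        spec = PopulationSpec(n_neurons=2, n_correlated=2, c=0.01, order=2, rate=10.0)
        s = build_structure(spec)
        assert s.nu[1] == pytest.approx(0.1)
        assert s.nu[0] == pytest.approx(19.8)

    def test_round_trip_through_pairwise_c(self):
        spec = PopulationSpec(n_neurons=1000, n_correlated=100, c=0.05, order=20, rate=5.0)
        s = build_structure(spec)
        kern = Kernel("exponential", 1.0, 0.02)
        c = pairwise_c_from_cumulants(
            theoretical_cumulant(s, kern, 1),
            theoretical_cumulant(s, kern, 2),
            kern,
            1000,
            100,
        )
        assert c == pytest.approx(0.05, rel=1e-12)

    def test_excessive_correlation_rejected(self):
        spec = PopulationSpec(n_neurons=10, n_correlated=10, c=0.9, order=2, rate=1.0)
        with pytest.raises(ValueError):
            build_structure(spec)


class TestMipStructure:
    def test_marginal_rate_and_pairwise_c(self):
        Nc, rate, c = 100, 10.0, 0.02
        s = mip_structure(Nc, rate, c)
        orders = np.arange(1, s.nu.size + 1)
        # every pool neuron fires at `rate`
        assert (orders * s.nu).sum() / Nc == pytest.approx(rate, rel=1e-9)
        # pair-coincidence rate / rate = c
        pair_rate = (orders * (orders - 1) * s.nu).sum() / (Nc * (Nc - 1))
        assert pair_rate / rate == pytest.approx(c, rel=1e-9)

    def test_independent_remainder_adds_to_nu1(self):
        s_pool = mip_structure(50, 5.0, 0.05)
        s_all = mip_structure(50, 5.0, 0.05, n_total=80)
        assert s_all.nu[0] - s_pool.nu[0] == pytest.approx(30 * 5.0)


class TestSimulateCpp:
    def test_total_count_poisson_mean(self, rng):
        nu1, T = 500.0, 40.0
        series = simulate_cpp(CorrelationStructure([nu1]), T, 1e-3, rng)
        total = series.counts.sum()
        assert abs(total - nu1 * T) < 4 * np.sqrt(nu1 * T)

    def test_count_mean_rate_general_structure(self, rng):
        s = CorrelationStructure([100.0, 20.0, 0.0, 5.0])
        dt, T = 1e-3, 200.0
        series = simulate_cpp(s, T, dt, rng)
        expected = s.spike_rate * dt
        se = np.sqrt(sum((n + 1) ** 2 * nu for n, nu in enumerate(s.nu)) * dt / (T / dt))
        assert abs(series.counts.mean() - expected) < 4 * se

    def test_fano_factor_of_pure_order_five(self, rng):
        s = CorrelationStructure([0, 0, 0, 0, 1.0])
        series = simulate_cpp(s, 2000.0, 0.01, rng)
        fano = series.counts.var() / series.counts.mean()
        assert fano == pytest.approx(5.0, abs=1.0)


class TestRaster:
    SPEC = PopulationSpec(n_neurons=30, n_correlated=20, c=0.1, order=5, rate=20.0)

    def test_marginal_rates(self, rng):
        T = 200.0
        raster = simulate_population(self.SPEC, T, 1e-3, rng, return_raster=True)
        rates = np.bincount(raster.neuron_ids, minlength=30) / T
        se = np.sqrt(self.SPEC.rate / T)
        assert np.all(np.abs(rates - self.SPEC.rate) < 4.5 * se)

    def test_pairwise_count_correlation(self, rng):
        T, dt = 200.0, 5e-3
        raster = simulate_population(self.SPEC, T, dt, rng, return_raster=True)
        L = int(T / dt)
        idx = np.minimum((raster.times / dt).astype(int), L - 1)
        mat = np.zeros((30, L))
        np.add.at(mat, (raster.neuron_ids, idx), 1.0)
        corr = np.corrcoef(mat)
        pool = corr[:20, :20][np.triu_indices(20, 1)]
        cross = corr[:20, 20:].ravel()
        assert pool.mean() == pytest.approx(0.1, abs=0.02)
        assert abs(cross.mean()) < 0.01

    def test_binned_counts_match_structure_cumulants(self, rng):
        """Sample cumulants of summed counts agree with the CPP prediction."""
        T, dt = 400.0, 1e-3
        raster = simulate_population(self.SPEC, T, dt, rng, return_raster=True)
        counts = bin_raster(raster, dt)
        cs = sample_cumulants(counts.counts.astype(float))
        s = build_structure(self.SPEC)
        kern = Kernel("rectangular", 1.0, dt)  # binning = rectangular filtering
        for m, est in [(1, cs.k1), (2, cs.k2), (3, cs.k3)]:
            assert est == pytest.approx(theoretical_cumulant(s, kern, m), rel=0.1)


class TestJitter:
    def test_zero_jitter_identity(self, rng):
        raster = simulate_population(self.spec(), 20.0, 1e-3, rng, return_raster=True)
        same = apply_jitter(raster, 0.0, rng)
        np.testing.assert_array_equal(same.times, raster.times)

    def test_jitter_moves_but_never_deletes(self, rng):
        raster = simulate_population(self.spec(), 20.0, 1e-3, rng, return_raster=True)
        jit = apply_jitter(raster, 0.005, rng)
        assert jit.n_spikes == raster.n_spikes
        assert np.all(jit.times >= 0) and np.all(jit.times < raster.duration)
        assert not np.allclose(jit.times, raster.times)

    @staticmethod
    def spec():
        return PopulationSpec(n_neurons=20, n_correlated=10, c=0.05, order=3, rate=10.0)


class TestNonPoisson:
    def test_isi_cv_of_single_train(self, rng):
        spec = PopulationSpec(
            n_neurons=1, n_correlated=0, c=0.0, order=2, rate=10.0,
            isi_model="lognormal", isi_cv=1.5,
        )
        raster = simulate_nonpoisson(spec, 1500.0, 1e-3, rng, return_raster=True)
        isi = np.diff(raster.spike_times(0))
        assert isi.size > 10_000
        assert isi.std(ddof=1) / isi.mean() == pytest.approx(1.5, rel=0.05)
        assert 1.0 / isi.mean() == pytest.approx(10.0, rel=0.05)

    def test_regular_trains_are_underdispersed(self, rng):
        spec = PopulationSpec(
            n_neurons=20, n_correlated=0, c=0.0, order=2, rate=10.0,
            isi_model="lognormal", isi_cv=0.1,
        )
        counts = simulate_nonpoisson(spec, 200.0, 0.1, rng)
        assert counts.counts.var() < 0.5 * counts.counts.mean()

    def test_correlation_structure_preserved(self, rng):
        """Coincidences imposed on renewal trains keep the CPP count cumulants."""
        spec = PopulationSpec(
            n_neurons=50, n_correlated=10, c=0.05, order=3, rate=10.0,
            isi_model="lognormal", isi_cv=2.0,
        )
        dt, T = 5e-4, 400.0
        counts = simulate_nonpoisson(spec, T, dt, rng)
        cs = sample_cumulants(counts.counts.astype(float))
        s = build_structure(spec)
        kern = Kernel("rectangular", 1.0, dt)
        assert cs.k1 == pytest.approx(theoretical_cumulant(s, kern, 1), rel=0.05)
        assert cs.k2 == pytest.approx(theoretical_cumulant(s, kern, 2), rel=0.10)


class TestMixInhibition:
    KERNEL = Kernel("exponential", 1.0, 0.01)

    def test_zero_rate_identity(self, rng):
        tr = Trace(np.ones(100), 1e-3)
        out = mix_inhibition(tr, self.KERNEL, 10, 0.0, rng)
        np.testing.assert_array_equal(out.samples, tr.samples)

    def test_mixed_mean_is_rate_difference(self, rng):
        dt, T = 5e-4, 100.0
        R_E, R_I = 1000.0, 400.0
        counts = rng.poisson(R_E * dt, int(T / dt))
        tr = filter_counts(SpikeCountSeries(counts, dt), self.KERNEL, warmup=1.0)
        mixed = mix_inhibition(tr, self.KERNEL, 40, 10.0, rng, warmup=1.0)
        expected = (R_E - R_I) * 1.0 * 0.01
        assert mixed.samples.mean() == pytest.approx(expected, abs=0.3)


class TestHeterogeneousAmplitudes:
    KERNEL = Kernel("exponential", 1.0, 0.01)
    SPEC = PopulationSpec(n_neurons=100, n_correlated=0, c=0.0, order=2, rate=10.0)

    def test_cv_zero_equals_plain_filtering(self, rng):
        raster = simulate_population(self.SPEC, 10.0, 1e-3, rng, return_raster=True)
        het = heterogeneous_amplitude_filter(raster, self.KERNEL, 0.0, 1e-3, rng, warmup=1.0)
        plain = filter_counts(bin_raster(raster, 1e-3), self.KERNEL, warmup=1.0)
        np.testing.assert_allclose(het.samples, plain.samples, rtol=1e-12)

    def test_mean_invariant_to_cv(self, rng):
        raster = simulate_population(self.SPEC, 60.0, 1e-3, rng, return_raster=True)
        means = [
            heterogeneous_amplitude_filter(raster, self.KERNEL, cv, 1e-3, rng, warmup=1.0).samples.mean()
            for cv in (0.0, 1.0)
        ]
        # mean amplitude is pinned at kernel.amplitude for every CV
        assert means[1] == pytest.approx(means[0], rel=0.1)
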