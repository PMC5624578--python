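"""MC and bootstrap replicate engines, percentile CIs, difference test."""

import numpy as np
import pytest

import arci
from arci.ar import ARFit


def _zero_uncertainty_fit(model, n=10_000):
    """A fit whose parameter uncertainty is exactly zero (N -> infinity fixture)."""
    p = model.order
    return ARFit(
        model=model,
        coeff_covariance=np.zeros((p, p)),
        innovation_variance_variance=0.0,
        residuals=np.zeros(n - p),
        n_samples=n,
        degenerate=False,
    )


class TestMonteCarlo:
    def test_zero_uncertainty_degenerates_to_point_estimate(self, benchmark):
        fit = _zero_uncertainty_fit(benchmark)
        rset = arci.mc_replicates(fit, m=50, seed=0)
        truth = arci.compute_indexes(benchmark)
        for params, idx in zip(rset.parameter_sets, rset.index_values):
            assert np.array_equal(params.coefficients, benchmark.coefficients)
            assert params.innovation_variance == benchmark.innovation_variance
            assert idx.s_x == pytest.approx(truth.s_x, rel=1e-12)
        assert rset.n_rejected == 0

    def test_replicate_mean_near_point_estimate(self, benchmark_fit):
        rset = arci.mc_replicates(benchmark_fit, m=1000, seed=3)
        coeffs = np.array([m.coefficients for m in rset.parameter_sets])
        se = np.sqrt(np.diag(benchmark_fit.coeff_covariance) / rset.m_replicates)
        assert np.all(
            np.abs(coeffs.mean(axis=0) - benchmark_fit.model.coefficients) < 4 * se
        )

    def test_all_replicates_stable_with_positive_variance(self, benchmark_fit):
        rset = arci.mc_replicates(benchmark_fit, m=500, seed=4)
        for m in rset.parameter_sets:
            assert m.is_stable()
            assert m.innovation_variance > 0

    def test_degenerate_fit_rejected(self):
        # exact zero-mean recursion -> Sigma_W = 0 -> resampling undefined
        ts = arci.TimeSeries(np.cos(2 * np.pi * 2 / 50 * np.arange(50)), 1.0)
        fit = arci.fit_ar(ts, 2)
        assert fit.degenerate
        with pytest.raises(arci.DegenerateFitError):
            arci.mc_replicates(fit, 10, 0)

    def test_near_unit_root_fit_errors_out(self):
        # A fit whose Gaussian approximation mostly lands outside the unit
        # circle must refuse rather than silently truncate.
        model = arci.ARModel([0.999], 1.0)
        fit = ARFit(
            model=model,
            coeff_covariance=np.array([[4.0]]),  # sd 2.0 around 0.999: ~2/3 of draws unstable
            innovation_variance_variance=2.0 / 300,
            residuals=np.zeros(299),
            n_samples=300,
        )
        with pytest.raises(arci.ResamplingError):
            arci.mc_replicates(fit, 1000, 0)


class TestBootstrap:
    def test_zero_residuals_reproduce_point_estimate(self, benchmark_series):
        fit = arci.fit_ar(benchmark_series, 5)
        frozen = ARFit(
            model=fit.model,
            coeff_covariance=fit.coeff_covariance,
            innovation_variance_variance=fit.innovation_variance_variance,
            residuals=np.zeros_like(fit.residuals),
            n_samples=fit.n_samples,
        )
        rset = arci.bs_replicates(frozen, benchmark_series, m=20, seed=0)
        # V = 0 makes the surrogate series deterministic; the re-estimated
        # coefficients must reproduce the point estimate up to solver rounding.
        for m in rset.parameter_sets:
            assert np.allclose(m.coefficients, fit.model.coefficients, atol=1e-10)

    def test_replicate_innovation_variance_consistent(self, benchmark):
        ts = arci.simulate_linear(benchmark, 1000, seed=21)
        fit = arci.fit_ar(ts, 5)
        rset = arci.bs_replicates(fit, ts, m=1000, seed=5)
        sw = np.array([m.innovation_variance for m in rset.parameter_sets])
        assert sw.mean() == pytest.approx(fit.model.innovation_variance, rel=0.05)

    def test_interquartile_width_agrees_with_mc(self, benchmark_fit, benchmark_series):
        mc = arci.mc_replicates(benchmark_fit, m=1000, seed=6)
        bs = arci.bs_replicates(benchmark_fit, benchmark_series, m=1000, seed=6)
        for name in ("s_x", "p_lfhf"):
            w = {}
            for label, rset in (("mc", mc), ("bs", bs)):
                s = arci.confidence_summary(rset.index_array(name), None)
                w[label] = s.percentiles[75] - s.percentiles[25]
            assert w["bs"] == pytest.approx(w["mc"], rel=0.25)

    def test_recursive_regeneration_variant_runs(self, benchmark_fit, benchmark_series):
        rset = arci.bs_replicates(benchmark_fit, benchmark_series, m=50, seed=7, regenerate=True)
        sw = np.array([m.innovation_variance for m in rset.parameter_sets])
        assert np.all(sw > 0)
        assert rset.m_replicates == 50


class TestConfidenceSummary:
    def test_uniform_grid_interpolated_percentiles(self):
        s = arci.confidence_summary(np.arange(1.0, 101.0), point_estimate=50.0)
        assert s.percentiles[25] == pytest.approx(25.75)
        assert s.percentiles[50] == pytest.approx(50.5)

    def test_constant_values(self):
        s = arci.confidence_summary(np.full(100, 3.2), point_estimate=3.2)
        assert all(v == pytest.approx(3.2) for v in s.percentiles.values())

    def test_gaussian_quantile_oracle(self):
        draws = np.random.default_rng(8).normal(size=100_000)
        s = arci.confidence_summary(draws, point_estimate=0.0)
        assert s.percentiles[5] == pytest.approx(-1.645, abs=0.02)
        assert s.percentiles[95] == pytest.approx(1.645, abs=0.02)

    def test_undefined_values_counted_not_summarized(self):
        s = arci.confidence_summary([1.0, None, 2.0, np.nan, 3.0], point_estimate=2.0)
        assert s.n_defined == 3 and s.n_total == 5
        assert not s.reliable
        assert s.percentiles[50] == pytest.approx(2.0)

    def test_no_defined_values_raises(self):
        with pytest.raises(arci.ResamplingError):
            arci.confidence_summary([None, np.nan], point_estimate=0.0)

    def test_percentiles_nondecreasing(self, benchmark_fit):
        rset = arci.mc_replicates(benchmark_fit, m=500, seed=9)
        s = arci.confidence_summary(rset.index_array("p_lfhf"), None)
        vals = [s.percentiles[q] for q in (5, 25, 50, 75, 95)]
        assert vals == sorted(vals)


class TestDifferenceTest:
    def test_separated_distributions_detected_as_increase(self):
        rng = np.random.default_rng(10)
        a = rng.normal(0.0, 0.1, 1000)
        res = arci.difference_test(a, a + 10.0, alpha=0.05, seed=1)
        assert res.significant and res.direction == "increase"

    def test_degenerate_null_not_significant(self):
        a = np.full(1000, 2.0)
        res = arci.difference_test(a, a, alpha=0.05, seed=1)
        assert res.interval == (0.0, 0.0)
        assert not res.significant and res.direction == "none"

    def test_swap_flips_direction(self):
        rng = np.random.default_rng(12)
        a = rng.normal(0.0, 0.1, 1000)
        b = a + 10.0
        fwd = arci.difference_test(a, b, seed=2)
        rev = arci.difference_test(b, a, seed=2)
        assert fwd.significant == rev.significant
        assert (fwd.direction, rev.direction) == ("increase", "decrease")

    def test_undefined_pairs_dropped_then_error_below_ten(self):
        a = np.r_[np.full(5, 1.0), np.full(995, np.nan)]
        b = np.full(1000, 2.0)
        with pytest.raises(arci.ResamplingError):
            arci.difference_test(a, b, seed=0)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            arci.difference_test(np.zeros(10), np.zeros(11))


class TestDeterminism:
    def test_same_seed_bit_identical_replicates(self, benchmark_fit, benchmark_series):
        for maker in (
            lambda s: arci.mc_replicates(benchmark_fit, 200, seed=s),
            lambda s: arci.bs_replicates(benchmark_fit, benchmark_series, 200, seed=s),
        ):
            r1, r2 = maker(99), maker(99)
            for m1, m2 in zip(r1.parameter_sets, r2.parameter_sets):
                assert np.array_equal(m1.coefficients, m2.coefficients)
                assert m1.innovation_variance == m2.innovation_variance
            assert r1.index_values == r2.index_values
            r3 = maker(100)
            assert any(
                not np.array_equal(m1.coefficients, m3.coefficients)
                for m1, m3 in zip(r1.parameter_sets, r3.parameter_sets)
            )
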