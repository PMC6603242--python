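"""Inhibition statistics, distribution fits, threshold estimation and
group comparison."""

import numpy as np
import pytest
from scipy import stats as sps

from startlekit import analysis as an


class TestFullCombinatorialRatios:
    def test_single_pair(self):
        r = an.full_combinatorial_ratios([1.0], [2.0])
        assert list(r.ratios) == [0.5]

    def test_cardinality_2x3(self):
        r = an.full_combinatorial_ratios([1.0, 2.0], [1.0, 2.0, 4.0])
        assert len(r) == 6 and r.n_pre == 2 and r.n_base == 3

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(0)
        pre, base = rng.uniform(0.1, 5, 10), rng.uniform(0.1, 5, 10)
        r = an.full_combinatorial_ratios(pre, base)
        oracle = sorted(p / b for p in pre for b in base)
        np.testing.assert_allclose(sorted(r.ratios), oracle, rtol=1e-15)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            an.full_combinatorial_ratios([1.0, -1.0], [2.0])
        with pytest.raises(ValueError):
            an.full_combinatorial_ratios([1.0], [])


class TestInhibitionStatistic:
    def test_identical_groups_zero(self):
        a = [1.0, 2.0, 3.0]
        assert an.inhibition_statistic(an.full_combinatorial_ratios(a, a)) == \
            pytest.approx(0.0)

    def test_constant_half_ratio(self):
        r = an.full_combinatorial_ratios([1.0, 1.0], [2.0, 2.0])
        assert an.inhibition_statistic(r) == pytest.approx(0.5)

    def test_even_count_median_is_central_midpoint(self):
        r = an.RatioSet(np.array([0.2, 0.4, 0.6, 0.8]), 2, 2)
        assert an.inhibition_statistic(r) == pytest.approx(1 - 0.5)

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(1)
        pre, base = rng.uniform(0.1, 3, 7), rng.uniform(0.1, 3, 9)
        r = an.full_combinatorial_ratios(pre, base)
        srt = np.sort(r.ratios)
        n = len(srt)
        med = srt[n // 2] if n % 2 else 0.5 * (srt[n // 2 - 1] + srt[n // 2])
        assert an.inhibition_statistic(r) == pytest.approx(1 - med, rel=1e-15)

    def test_invariant_to_common_scaling(self):
        rng = np.random.default_rng(2)
        pre, base = rng.uniform(0.5, 2, 8), rng.uniform(0.5, 2, 8)
        s1 = an.inhibition_statistic(an.full_combinatorial_ratios(pre, base))
        s2 = an.inhibition_statistic(an.full_combinatorial_ratios(7.3 * pre, 7.3 * base))
        assert s2 == pytest.approx(s1, rel=1e-12)


class TestBootstrapSE:
    def test_constant_amplitudes_zero_se(self):
        res = an.bootstrap_se([2.0, 2.0, 2.0], [4.0, 4.0, 4.0], 200, seed=0)
        assert res.se == 0.0 and res.statistic == pytest.approx(0.5)

    def test_seed_determinism(self):
        rng = np.random.default_rng(3)
        pre, base = rng.uniform(0.5, 2, 10), rng.uniform(0.5, 2, 10)
        a = an.bootstrap_se(pre, base, 500, seed=42)
        b = an.bootstrap_se(pre, base, 500, seed=42)
        assert a.se == b.se

    def test_single_trial_groups_rejected(self):
        with pytest.raises(ValueError):
            an.bootstrap_se([1.0], [1.0, 2.0], 100, seed=0)


class TestLogNormalFit:
    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            an.fit_lognormal([np.e] * 4)

    def test_parameter_recovery_large_n(self):
        rng = np.random.default_rng(4)
        a = np.exp(rng.normal(0.5, 0.2, 100_000))
        fit = an.fit_lognormal(a)
        assert fit.mu == pytest.approx(0.5, abs=0.003)
        assert fit.sigma == pytest.approx(0.2, abs=0.002)

    def test_scale_shifts_mu_only(self):
        rng = np.random.default_rng(5)
        a = np.exp(rng.normal(0.0, 0.3, 500))
        f1, f2 = an.fit_lognormal(a), an.fit_lognormal(10.0 * a)
        assert f2.mu == pytest.approx(f1.mu + np.log(10), rel=1e-9)
        assert f2.sigma == pytest.approx(f1.sigma, rel=1e-12)

    def test_loglik_matches_scipy(self):
        rng = np.random.default_rng(6)
        a = np.exp(rng.normal(1.0, 0.5, 200))
        fit = an.fit_lognormal(a)
        ref = np.sum(sps.lognorm.logpdf(a, s=fit.sigma, scale=np.exp(fit.mu)))
        assert fit.loglik == pytest.approx(ref, rel=1e-12)


class TestLognormalityCheck:
    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            an.lognormality_check([1.0, 2.0, 3.0, 4.0])

    def test_lognormal_ratios_rarely_rejected(self):
        rng = np.random.default_rng(7)
        rejections = sum(
            an.lognormality_check(np.exp(rng.normal(0, 0.4, 225))).pvalue < 0.01
            for _ in range(200))
        assert rejections <= 10  # >= 95% non-rejection at alpha = 0.01

    def test_uniform_ratios_deviate_in_qq_tails(self):
        rng = np.random.default_rng(8)
        uniform = rng.uniform(10.0, 11.0, 2000)
        lognorm = np.exp(rng.normal(0, 0.4, 2000))
        bad = an.lognormality_check(uniform)
        good = an.lognormality_check(lognorm)
        assert bad.pvalue < 1e-4
        assert bad.qq_max_deviation > good.qq_max_deviation


class TestHardSigmoid:
    LEVELS = np.arange(2.0, 26.1, 2.0)

    def test_below_threshold_exactly_zero(self):
        y = an.hard_sigmoid(np.array([2.0, 6.0, 9.99]), 10.0, 0.05, 0.8)
        assert np.all(y == 0.0)

    @pytest.mark.parametrize("true", [(10.0, 0.05, 0.8), (6.0, 0.08, 0.6),
                                      (14.0, 0.1, 0.9)])
    def test_noiseless_recovery_machine_precision(self, true):
        th, m, s = true
        y = an.hard_sigmoid(self.LEVELS, th, m, s)
        fit = an.fit_hard_sigmoid(self.LEVELS, y)
        assert fit.threshold_dbspl == pytest.approx(th, abs=1e-6)
        assert fit.slope == pytest.approx(m, abs=1e-6)
        assert fit.saturation == pytest.approx(s, abs=1e-6)
        assert fit.rss <= 1e-12

    def test_unreached_saturation_still_locates_threshold(self):
        # threshold near the top of the level range: the plateau is never
        # sampled, so saturation is unidentifiable but the breakpoint and
        # slope still are
        y = an.hard_sigmoid(self.LEVELS, 17.3, 0.05, 0.9)
        fit = an.fit_hard_sigmoid(self.LEVELS, y)
        assert fit.threshold_dbspl == pytest.approx(17.3, abs=1e-6)
        assert fit.slope == pytest.approx(0.05, abs=1e-6)
        assert fit.rss <= 1e-12

    def test_residual_never_exceeds_generator_truth(self):
        y = an.hard_sigmoid(self.LEVELS, 11.0, 0.06, 0.7)
        fit = an.fit_hard_sigmoid(self.LEVELS, y)
        rss_true = np.sum((an.hard_sigmoid(self.LEVELS, 11.0, 0.06, 0.7) - y) ** 2)
        assert fit.rss <= rss_true + 1e-12

    def test_noisy_threshold_within_1db_median(self):
        rng = np.random.default_rng(9)
        y = an.hard_sigmoid(self.LEVELS, 10.0, 0.05, 0.8)
        errs = [abs(an.fit_hard_sigmoid(
            self.LEVELS, y + rng.normal(0, 0.05, len(y))).threshold_dbspl - 10.0)
            for _ in range(30)]
        assert np.median(errs) <= 1.0

    def test_all_zero_ppi_flags_no_response(self):
        fit = an.fit_hard_sigmoid(self.LEVELS, np.zeros_like(self.LEVELS))
        assert fit.no_response

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            an.fit_hard_sigmoid([2.0, 4.0, 6.0], [0.0, 0.1, 0.2])

    def test_weighted_fit_downweights_noisy_points(self):
        y = an.hard_sigmoid(self.LEVELS, 10.0, 0.05, 0.8)
        y_bad = y.copy()
        y_bad[0] = 0.5  # wild outlier below threshold
        w = np.ones_like(y)
        w[0] = 1e-6
        fit = an.fit_hard_sigmoid(self.LEVELS, y_bad, weights=w)
        assert fit.threshold_dbspl == pytest.approx(10.0, abs=0.05)


class TestCompareGroups:
    def test_identical_groups_p_one(self):
        assert an.compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_disjoint_support_exact(self):
        p = an.compare_groups([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
        assert p == pytest.approx(2 / 252)

    def test_matches_exhaustive_oracle_4v4(self):
        rng = np.random.default_rng(10)
        a, b = rng.normal(0, 1, 4), rng.normal(0.5, 1, 4)
        # independent oracle: scipy exact Mann-Whitney (no ties here)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        assert an.compare_groups(a, b) == pytest.approx(ref, rel=1e-12)

    def test_large_samples_use_tie_corrected_normal(self):
        rng = np.random.default_rng(11)
        a = np.round(rng.normal(0, 1, 20), 1)
        b = np.round(rng.normal(0.8, 1, 20), 1)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic").pvalue
        assert an.compare_groups(a, b) == pytest.approx(ref, rel=1e-12)

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            an.compare_groups([1.0, 2.0], [3.0, 4.0, 5.0])


class TestModelObjects:
    def test_inhibition_model_matches_functions(self):
        rng = np.random.default_rng(12)
        pre = np.exp(rng.normal(-0.7, 0.4, 15))
        base = np.exp(rng.normal(0.0, 0.4, 15))
        res = an.InhibitionModel(pre, base).fit(n_bootstrap=1000, seed=5)
        direct = an.bootstrap_se(pre, base, 1000, seed=5)
        assert res.statistic == direct.statistic and res.se == direct.se
        assert "bootstrap SE" in res.summary()
        lo, hi = res.conf_int()
        assert lo < res.statistic < hi

    def test_inhibition_model_from_dataframe(self):
        import pandas as pd

        df = pd.DataFrame({
            "kind": ["gap"] * 3 + ["nogap"] * 3,
            "amplitude": [0.5, 0.6, 0.4, 1.0, 1.1, 0.9]})
        model = an.InhibitionModel.from_dataframe(df)
        assert len(model.a_pre) == 3 and len(model.a_base) == 3

    def test_lognormal_results_summary(self):
        rng = np.random.default_rng(13)
        res = an.LogNormalModel(np.exp(rng.normal(0.5, 0.2, 1000))).fit()
        assert res.mu == pytest.approx(0.5, abs=0.05)
        assert "sigma" in res.summary()

    def test_hard_sigmoid_results_predict_and_summary(self):
        x = np.arange(2.0, 26.1, 2.0)
        y = an.hard_sigmoid(x, 10.0, 0.05, 0.8)
        res = an.HardSigmoidModel(x, y).fit()
        assert res.threshold_dbspl == pytest.approx(10.0, abs=1e-6)
        np.testing.assert_allclose(res.predict(), y, atol=1e-6)
        assert "threshold" in res.summary()
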