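import math

import numpy as np
import pytest

from protmr.mr import (egger, ivw, mode_estimate, mr_result_from_or,
                       to_odds_ratio, wald_ratio, weighted_median)
from protmr.synthetic import simulate_instrument_set

from conftest import make_set


class TestWaldRatio:
    def test_basic_arithmetic(self):
        s = make_set([0.1], [0.05], se_y=[0.01])
        r = wald_ratio(s)
        assert math.isclose(r.beta, 0.5) and math.isclose(r.se, 0.1)

    def test_null_outcome_gives_p_one(self):
        r = wald_ratio(make_set([0.1], [0.0], se_y=[0.01]))
        assert r.beta == 0.0 and r.pval == 1.0

    def test_negative_exposure_effect(self):
        r = wald_ratio(make_set([-0.2], [0.05], se_y=[0.02]))
        assert math.isclose(r.beta, -0.25) and math.isclose(r.se, 0.1)

    def test_zero_exposure_effect_errors(self):
        with pytest.raises(ValueError):
            wald_ratio(make_set([0.0], [0.1], se_y=[0.01]))

    def test_requires_single_instrument(self):
        with pytest.raises(ValueError):
            wald_ratio(make_set([0.1, 0.2], [0.05, 0.1], se_y=0.01))


class TestIVW:
    def test_consistent_ratios_recovered_with_zero_q(self):
        s = make_set([0.1, 0.2], [0.05, 0.1], se_y=0.1)
        r = ivw(s, model="fixed")
        assert math.isclose(r.beta, 0.5)
        assert math.isclose(r.extra["Q"], 0.0, abs_tol=1e-20)

    def test_closed_form_weighted_ls(self):
        # w = 100 each: beta = 2.5/5 = 0.5, fixed SE = 1/sqrt(5)
        s = make_set([0.1, 0.2], [0.05, 0.10], se_y=0.1)
        r = ivw(s, model="fixed")
        assert math.isclose(r.se, 5 ** -0.5, rel_tol=1e-12)

    def test_mre_se_never_below_fixed(self):
        for seed in range(10):
            s, _ = simulate_instrument_set(k=20, theta_true=0.1, se_y=0.002,
                                           pleiotropy_model="balanced", seed=seed)
            assert ivw(s, "mre").se >= ivw(s, "fixed").se - 1e-15

    def test_auto_switches_on_heterogeneity(self):
        s, _ = simulate_instrument_set(k=30, theta_true=0.1, se_y=0.002,
                                       pleiotropy_model="balanced",
                                       pleiotropy_sd=0.02, seed=4)
        r = ivw(s, model="auto")
        assert r.extra["Q_pval"] < 0.05 and r.method == "ivw_mre"

    def test_recovery_within_three_se(self):
        s, _ = simulate_instrument_set(k=50, theta_true=0.2, se_y=0.002, seed=1)
        r = ivw(s)
        assert abs(r.beta - 0.2) < 3 * r.se

    def test_requires_two_instruments(self):
        with pytest.raises(ValueError, match="wald_ratio"):
            ivw(make_set([0.1], [0.05], se_y=[0.01]))


class TestEgger:
    def test_exact_line_recovered(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        s = make_set(bx, 0.01 + 0.5 * bx, se_y=0.01)
        r = egger(s)
        assert math.isclose(r.beta, 0.5, rel_tol=1e-9)
        assert math.isclose(r.extra["egger_intercept"], 0.01, rel_tol=1e-9)

    def test_orientation_handles_negative_beta_x(self):
        bx = np.array([0.1, -0.2, 0.3, -0.4])
        s = make_set(bx, 0.01 * np.sign(bx) + 0.5 * bx, se_y=0.01)
        # after orienting all beta_x >= 0 the points are exactly linear
        r = egger(s)
        assert math.isclose(r.beta, 0.5, rel_tol=1e-9)

    def test_requires_three_instruments(self):
        with pytest.raises(ValueError):
            egger(make_set([0.1, 0.2], [0.05, 0.1], se_y=0.01))

    def test_balanced_pleiotropy_intercept_unbiased(self):
        ints = []
        for seed in range(200):
            s, _ = simulate_instrument_set(k=20, theta_true=0.1, se_y=0.002,
                                           pleiotropy_model="balanced", seed=seed)
            ints.append(egger(s).extra["egger_intercept"])
        sem = np.std(ints) / math.sqrt(len(ints))
        assert abs(np.mean(ints)) < 2 * sem + 1e-12

    def test_directional_pleiotropy_intercept_recovered(self):
        ints = []
        for seed in range(200):
            s, _ = simulate_instrument_set(k=50, theta_true=0.1, se_y=0.002,
                                           pleiotropy_model="directional",
                                           pleiotropy_mean=0.01,
                                           pleiotropy_sd=0.002, seed=seed)
            ints.append(egger(s).extra["egger_intercept"])
        sem = np.std(ints) / math.sqrt(len(ints))
        assert abs(np.mean(ints) - 0.01) < 2 * sem


class TestWeightedMedian:
    def test_identical_ratios(self):
        s = make_set([0.1, 0.2, 0.3], [0.04, 0.08, 0.12], se_y=0.01)
        assert math.isclose(weighted_median(s, seed=0).beta, 0.4, rel_tol=1e-12)

    def test_equal_weight_interpolation(self):
        # theta = (0.1, 0.2, 0.9) with equal weights: cumulative midpoints
        # (1/6, 1/2, 5/6) put the 50th percentile exactly at 0.2
        s = make_set([0.1, 0.1, 0.1], [0.01, 0.02, 0.09], se_y=0.01)
        assert math.isclose(weighted_median(s, seed=0).beta, 0.2, rel_tol=1e-12)

    def test_seed_determinism(self):
        s, _ = simulate_instrument_set(k=10, theta_true=0.1, se_y=0.002, seed=3)
        assert weighted_median(s, seed=7).se == weighted_median(s, seed=7).se


class TestMode:
    def test_mode_ignores_outlier_ratio(self):
        s = make_set([0.1, 0.1, 0.1, 0.1], [0.05, 0.05, 0.05, 0.5], se_y=0.01)
        r = mode_estimate(s, seed=0)
        assert abs(r.beta - 0.5) < 0.05  # near the 0.5 cluster, not 5.0

    def test_degenerate_identical_ratios(self):
        s = make_set([0.1, 0.2, 0.3], [0.03, 0.06, 0.09], se_y=0.01)
        assert math.isclose(mode_estimate(s, seed=0).beta, 0.3, rel_tol=1e-12)

    def test_weighted_equals_simple_under_equal_weights(self):
        bx = np.array([0.2, 0.2, 0.2, 0.2])
        s = make_set(bx, np.array([0.05, 0.06, 0.08, 0.12]), se_y=0.01)
        simple = mode_estimate(s, weighted=False, n_boot=10, seed=0)
        weighted = mode_estimate(s, weighted=True, n_boot=10, seed=0)
        assert math.isclose(simple.beta, weighted.beta, rel_tol=1e-12)


class TestOddsRatio:
    def test_closed_form(self):
        or_pt, lo, hi = to_odds_ratio(0.0, 0.1)
        assert or_pt == 1.0
        assert math.isclose(lo, math.exp(-1.959964 * 0.1), rel_tol=1e-12)
        assert math.isclose(hi, math.exp(1.959964 * 0.1), rel_tol=1e-12)

    def test_log_two(self):
        assert math.isclose(to_odds_ratio(math.log(2), 0.05)[0], 2.0)

    def test_ci_brackets_point(self):
        for beta in (-1.5, 0.0, 2.0):
            or_pt, lo, hi = to_odds_ratio(beta, 0.3)
            assert lo < or_pt < hi

    def test_round_trip_from_or(self):
        r = mr_result_from_or("ivw", 1.0026, 1.0015, 1.0037)
        assert math.isclose(r.beta, math.log(1.0026), rel_tol=1e-12)
        assert math.isclose(r.se, (math.log(1.0037) - math.log(1.0015)) / (2 * 1.959964))


class TestEstimatorInvariants:
    def test_all_agree_on_proportional_set(self, proportional_set):
        s = proportional_set
        assert math.isclose(ivw(s).beta, 0.5, rel_tol=1e-12)
        assert math.isclose(egger(s).beta, 0.5, rel_tol=1e-9)
        assert math.isclose(egger(s).extra["egger_intercept"], 0.0, abs_tol=1e-12)
        assert math.isclose(weighted_median(s, seed=0).beta, 0.5, rel_tol=1e-12)
        assert math.isclose(mode_estimate(s, seed=0).beta, 0.5, rel_tol=1e-12)

    @pytest.mark.parametrize("c", [0.5, 2.0, 10.0])
    def test_scale_equivariance(self, c):
        """Rescaling the exposure's units by c divides every causal estimate by c."""
        s, _ = simulate_instrument_set(k=15, theta_true=0.2, se_y=0.002, seed=9)
        scaled = make_set(c * s.beta_x, s.beta_y, se_y=s.se_y, se_x=c * s.se_x,
                          pval_x=s.pval_x, pval_y=s.pval_y)
        base = make_set(s.beta_x, s.beta_y, se_y=s.se_y, se_x=s.se_x,
                        pval_x=s.pval_x, pval_y=s.pval_y)
        assert np.isclose(ivw(scaled).beta, ivw(base).beta / c, rtol=1e-10)
        assert np.isclose(egger(scaled).beta, egger(base).beta / c, rtol=1e-10)
        assert np.isclose(weighted_median(scaled, seed=1).beta,
                          weighted_median(base, seed=1).beta / c, rtol=1e-10)
        assert np.isclose(mode_estimate(scaled, seed=1).beta,
                          mode_estimate(base, seed=1).beta / c, rtol=1e-8)
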