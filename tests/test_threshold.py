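"""Threshold-effect machinery: hinge parameterisation, profile search,
LRT, bootstrap CI and per-SD rescaling."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from sepsisthresh.synthetic import CohortSpec, generate_cohort
from sepsisthresh.threshold import (GridSpec, bootstrap_turning_point_ci,
                                    fit_one_line, fit_two_piecewise, lrt_one_vs_two,
                                    make_grid, per_sd_or, search_turning_point,
                                    standardize_value, threshold_effect_analysis)


@pytest.fixture(scope="module")
def yx_20k(hinge_cohort_20k):
    spec, table = hinge_cohort_20k
    return spec, table["death28"].to_numpy(), table["ratio"].to_numpy()


class TestTwoPiecewise:
    def test_logit_continuous_at_K(self, yx_20k):
        _, y, x = yx_20k
        K = 3.3
        fit, _, _ = fit_two_piecewise(y, x, K)
        b = fit.params
        eps = 1e-6
        left = b["intercept"] + b["ratio"] * (K - eps) + b["ratio_hinge"] * 0.0
        right = b["intercept"] + b["ratio"] * (K + eps) + b["ratio_hinge"] * eps
        # limits agree as eps -> 0; at eps=1e-6 the gap is slope-bounded
        assert abs(right - left) < 1e-4
        at_k_left = b["intercept"] + b["ratio"] * K
        at_k_right = b["intercept"] + b["ratio"] * K + b["ratio_hinge"] * 0.0
        assert at_k_left == pytest.approx(at_k_right, abs=1e-10)

    def test_segment_or_recovery_at_true_K(self, yx_20k):
        spec, y, x = yx_20k
        fit, eff_lo, eff_hi = fit_two_piecewise(y, x, spec.turning_point_K)
        assert eff_lo.lower < np.exp(spec.slope_below) < eff_lo.upper
        assert eff_hi.lower < np.exp(spec.slope_above) < eff_hi.upper

    def test_no_threshold_data_gives_equal_segments(self, rng):
        n = 20_000
        x = rng.uniform(0.3, 10, n)
        y = (rng.random(n) < expit(-3 + 0.1 * x)).astype(float)
        fit, eff_lo, eff_hi = fit_two_piecewise(y, x, 4.0)
        hinge_se = fit.bse["ratio_hinge"]
        assert abs(fit.params["ratio_hinge"]) < 2 * hinge_se

    def test_delta_method_matches_reparameterised_refit(self, yx_20k):
        # refit with basis {1, x, min(x-K, 0)} so the 'ratio' coefficient IS
        # the above-K slope; its Wald SE must equal the delta-method SE
        from sepsisthresh.logistic import fit_logistic

        _, y, x = yx_20k
        K = 3.3
        fit, _, eff_hi = fit_two_piecewise(y, x, K)
        est, se = fit.linear_combination({"ratio": 1.0, "ratio_hinge": 1.0})
        X = pd.DataFrame({"intercept": np.ones_like(x), "ratio": x,
                          "neg_part": np.minimum(x - K, 0.0)})
        refit = fit_logistic(X, y)
        assert refit.params["ratio"] == pytest.approx(est, abs=1e-8)
        assert refit.bse["ratio"] == pytest.approx(se, rel=1e-6)

    def test_segment_size_guard(self, yx_20k):
        _, y, x = yx_20k
        with pytest.raises(ValueError, match="segment"):
            fit_two_piecewise(y, x, float(np.sort(x)[5]))
        with pytest.raises(ValueError):
            fit_two_piecewise(y, x, 99.0)


class TestSearch:
    def test_profile_matches_exhaustive_refit(self, yx_20k):
        _, y, x = yx_20k
        K_hat, grid, profile = search_turning_point(y, x)
        # independent code path: full-featured fit at every grid point
        slow = np.array([fit_two_piecewise(y, x, K)[0].loglik for K in grid])
        np.testing.assert_allclose(profile, slow, atol=1e-8)
        assert K_hat == grid[int(np.argmax(slow))]
        assert profile.max() == profile[list(grid).index(K_hat)]

    def test_recovers_true_K(self, yx_20k):
        spec, y, x = yx_20k
        K_hat, _, _ = search_turning_point(y, x)
        assert abs(K_hat - spec.turning_point_K) <= 0.3

    def test_nesting_two_piece_never_below_one_line(self, yx_20k):
        _, y, x = yx_20k
        fit1, _, _ = fit_one_line(y, x)
        K_hat, grid, profile = search_turning_point(y, x)
        assert profile[np.isfinite(profile)].min() >= fit1.loglik - 1e-6

    def test_grid_respects_min_segment(self, rng):
        x = rng.uniform(0, 10, 500)
        grid = make_grid(x, GridSpec(min_segment=50))
        assert all((x < k).sum() >= 50 and (x >= k).sum() >= 50 for k in grid)
        with pytest.raises(ValueError, match="candidates"):
            make_grid(x, GridSpec(min_segment=260))

    def test_flat_profile_on_linear_data_keeps_lrt_null(self, rng):
        n = 15_000
        spec = CohortSpec(n_patients=n, seed=77, slope_below=np.log(1.05),
                          slope_above=np.log(1.05), missing_rates={})
        t = generate_cohort(spec)
        y, x = t["death28"].to_numpy(), t["ratio"].to_numpy()
        fit1, eff, _ = fit_one_line(y, x)
        assert eff.lower < 1.05 < eff.upper
        K_hat, _, _ = search_turning_point(y, x)
        fit2, _, _ = fit_two_piecewise(y, x, K_hat)
        stat, p = lrt_one_vs_two(fit1, fit2)
        assert stat >= 0.0


class TestLRT:
    def test_identical_logliks(self, yx_20k):
        _, y, x = yx_20k
        fit1, _, _ = fit_one_line(y, x)
        stat, p = lrt_one_vs_two(fit1, fit1)
        assert stat == 0.0 and p == 1.0

    @pytest.mark.parametrize("stat, expected_p", [(3.841, 0.050), (5.170, 0.023)])
    def test_chi2_reference_values(self, stat, expected_p):
        from scipy.stats import chi2

        assert round(float(chi2.sf(stat, 1)), 3) == expected_p

    def test_negative_statistic_errors(self, yx_20k):
        _, y, x = yx_20k
        fit1, _, _ = fit_one_line(y, x)
        fit2, _, _ = fit_two_piecewise(y, x, 3.3)
        with pytest.raises(ValueError, match="inconsistent"):
            lrt_one_vs_two(fit2, fit1)  # reversed nesting


class TestBootstrap:
    def test_same_seed_identical_ci(self):
        t = generate_cohort(CohortSpec(n_patients=1500, seed=8, missing_rates={}))
        y, x = t["death28"].to_numpy(), t["ratio"].to_numpy()
        a = bootstrap_turning_point_ci(y, x, n_boot=100, seed=5)
        b = bootstrap_turning_point_ci(y, x, n_boot=100, seed=5)
        assert a[:2] == b[:2]
        np.testing.assert_array_equal(a[2], b[2])

    def test_minimum_n_boot_enforced(self, yx_20k):
        _, y, x = yx_20k
        with pytest.raises(ValueError, match="minimum"):
            bootstrap_turning_point_ci(y, x, n_boot=2, seed=0)


class TestRescaling:
    @pytest.mark.parametrize("or_unit, sd, expected", [
        (0.60, 2.01, 0.36),   # published below-threshold per-SD OR
        (1.28, 2.01, 1.64),   # published above-threshold per-SD OR
        (1.04, 2.01, 1.08),   # published one-line per-SD OR
        (1.00, 2.01, 1.00),
    ])
    def test_per_sd_or(self, or_unit, sd, expected):
        assert round(per_sd_or(or_unit, sd), 2) == expected

    @pytest.mark.parametrize("v, expected", [(2.9, -0.26), (3.43, 0.0), (3.9, 0.23)])
    def test_standardize_published_turning_point_ci(self, v, expected):
        assert round(standardize_value(v, 3.43, 2.01), 2) == expected

    def test_guards(self):
        with pytest.raises(ValueError):
            per_sd_or(-1.0, 2.0)
        with pytest.raises(ValueError):
            per_sd_or(1.2, 0.0)
        with pytest.raises(ValueError):
            standardize_value(1.0, 0.0, 0.0)


def test_full_analysis_consistency():
    t = generate_cohort(CohortSpec(n_patients=4000, seed=31, missing_rates={}))
    y, x = t["death28"].to_numpy(), t["ratio"].to_numpy()
    res = threshold_effect_analysis(y, x, n_boot=100, seed=3)
    assert res.K_hat in res.grid
    assert res.profile_loglik[list(res.grid).index(res.K_hat)] == \
        res.profile_loglik[np.isfinite(res.profile_loglik)].max()
    assert res.lrt_statistic >= 0 and 0 <= res.lrt_p <= 1
    # per-SD fields are powers of the per-unit fields
    assert res.or_below_sd.or_ == pytest.approx(res.or_below.or_ ** res.sd_used)
    assert res.or_above_sd.upper == pytest.approx(res.or_above.upper ** res.sd_used)
    d = res.to_dict()
    assert d["turning_point"] == res.K_hat
    table = res.to_table()
    assert len(table) == 6
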