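"""Agreement battery: summaries, correlations, Friedman/Wilcoxon, OLS, Bland-Altman.

Hand-computed values and independent oracles (exhaustive sign enumeration for
the Wilcoxon normal approximation, the raw rank formula for Friedman, the
normal equations for OLS, scipy cross-checks on non-degenerate inputs).
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fibroquant.agreement_stats import (
    LN_OFFSET,
    MethodMeasurements,
    ValidationError,
    bland_altman,
    fit_regression,
    format_p,
    friedman_test,
    ln_transform,
    pairs_table,
    pearson_matrix,
    summarize_methods,
    wilcoxon_pairs,
    wilcoxon_signed_rank,
    with_pathologist_mean,
)
from fibroquant.synthetic_histology import ParameterError


def _mm(**columns):
    return MethodMeasurements(pd.DataFrame(columns))


class TestMethodMeasurements:
    def test_out_of_scale_values_rejected(self):
        with pytest.raises(ValidationError):
            _mm(a=[10.0, 120.0])

    def test_pathologist_mean_must_be_consistent(self):
        with pytest.raises(ValidationError):
            _mm(
                pathologist_week0=[10.0],
                pathologist_week2=[20.0],
                pathologist_mean=[99.0],
            )

    def test_with_pathologist_mean_is_arithmetic_mean(self):
        df = with_pathologist_mean(
            pd.DataFrame({"pathologist_week0": [10.0, 0.0], "pathologist_week2": [20.0, 5.0]})
        )
        assert list(df["pathologist_mean"]) == [15.0, 2.5]


class TestSummaries:
    def test_two_point_column(self):
        s = summarize_methods(_mm(a=[10.0, 20.0]))
        row = s.loc["a"]
        assert (row["mean"], row["median"], row["range"]) == (15.0, 15.0, 10.0)

    def test_sample_sd_hand_value(self):
        s = summarize_methods(_mm(a=[0.0, 0.0, 100.0]))
        assert s.loc["a", "std"] == pytest.approx(57.735, abs=1e-3)

    def test_constant_column(self):
        s = summarize_methods(_mm(a=[5.0, 5.0, 5.0]))
        assert s.loc["a", "std"] == 0.0 and s.loc["a", "range"] == 0.0

    def test_range_is_max_minus_min(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(0, 100, 30)
        s = summarize_methods(_mm(a=vals))
        assert s.loc["a", "range"] == s.loc["a", "max"] - s.loc["a", "min"]


class TestPearson:
    def test_affine_relation_is_perfect(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        r, p = pearson_matrix(_mm(a=x, b=2 * x + 3))
        assert r.loc["a", "b"] == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_r(self):
        r, _ = pearson_matrix(_mm(a=[1.0, 2.0, 3.0, 4.0], b=[2.0, 1.0, 4.0, 3.0]))
        assert r.loc["a", "b"] == pytest.approx(0.6, abs=1e-12)

    def test_unit_diagonal_and_symmetry(self):
        rng = np.random.default_rng(3)
        r, p = pearson_matrix(_mm(a=rng.uniform(0, 90, 20), b=rng.uniform(0, 90, 20)))
        assert r.loc["a", "a"] == 1.0
        assert r.loc["a", "b"] == r.loc["b", "a"]
        assert 0.0 <= p.loc["a", "b"] <= 1.0

    def test_zero_variance_flagged_as_nan(self):
        r, p = pearson_matrix(_mm(a=[1.0, 1.0, 1.0], b=[1.0, 2.0, 3.0]))
        assert np.isnan(r.loc["a", "b"]) and np.isnan(p.loc["a", "b"])


class TestFriedman:
    def test_df_is_methods_minus_one(self):
        rng = np.random.default_rng(4)
        m = _mm(**{f"m{i}": rng.uniform(0, 90, 12) for i in range(4)})
        res = friedman_test(m)
        assert res.df == 3

    def test_identical_columns_give_zero(self):
        vals = [1.0, 5.0, 9.0]
        res = friedman_test(_mm(a=vals, b=vals, c=vals))
        assert res.chi_square == 0.0 and res.p_value == 1.0

    def test_three_by_three_brute_force_rank_formula(self):
        block = np.array([[1.0, 2.0, 3.0], [2.0, 3.0, 1.0], [1.0, 3.0, 2.0]])
        # hand ranks per row: (1,2,3),(2,3,1),(1,3,2) -> column sums 4,8,6
        n, k = 3, 3
        rank_sums = np.array([4.0, 8.0, 6.0])
        expected = 12.0 / (n * k * (k + 1)) * np.sum(rank_sums**2) - 3 * n * (k + 1)
        res = friedman_test(_mm(a=block[:, 0], b=block[:, 1], c=block[:, 2]))
        assert res.chi_square == pytest.approx(expected, abs=1e-12)

    def test_matches_scipy_on_tie_free_data(self):
        rng = np.random.default_rng(5)
        cols = {f"m{i}": rng.normal(50, 10, 25) for i in range(4)}
        res = friedman_test(_mm(**{k: np.clip(v, 0, 100) for k, v in cols.items()}))
        ref = stats.friedmanchisquare(*cols.values())
        assert res.chi_square == pytest.approx(ref.statistic, abs=1e-9)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_invariant_under_joint_monotone_transform(self):
        rng = np.random.default_rng(6)
        cols = {f"m{i}": rng.uniform(1, 90, 15) for i in range(3)}
        res_raw = friedman_test(_mm(**cols))
        res_log = friedman_test(_mm(**{k: np.log(v) for k, v in cols.items()}))
        assert res_raw.chi_square == pytest.approx(res_log.chi_square, abs=1e-12)

    def test_fewer_than_three_methods_rejected(self):
        with pytest.raises(ParameterError):
            friedman_test(_mm(a=[1.0, 2.0], b=[2.0, 3.0]))


class TestWilcoxon:
    def test_bonferroni_alpha_for_four_pairs(self):
        rng = np.random.default_rng(7)
        cols = {f"m{i}": rng.uniform(0, 90, 10) for i in range(4)}
        pairs = [("m0", "m1"), ("m0", "m2"), ("m0", "m3"), ("m1", "m2")]
        out = wilcoxon_pairs(_mm(**cols), pairs, family_alpha=0.05)
        assert all(c.adjusted_alpha == 0.0125 for c in out)

    def test_antisymmetric_differences_give_zero_z(self):
        a = np.array([10.0, 12.0, 20.0, 24.0])
        b = a - np.array([-1.0, 1.0, -2.0, 2.0])
        z, p = wilcoxon_signed_rank(a, b)
        assert z == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_sign_flips_when_pair_reversed(self):
        rng = np.random.default_rng(8)
        a = rng.uniform(0, 90, 15)
        b = np.clip(a + rng.normal(2, 3, 15), 0, 100)
        z_ab, _ = wilcoxon_signed_rank(a, b)
        z_ba, _ = wilcoxon_signed_rank(b, a)
        assert z_ab == pytest.approx(-z_ba, abs=1e-12)

    def test_zero_differences_dropped_matches_scipy(self):
        a = np.array([10.0, 11.0, 12.0, 13.0, 14.0, 20.0, 30.0, 40.0, 50.0])
        b = np.array([10.0, 12.0, 11.0, 16.0, 10.0, 26.0, 24.0, 45.0, 41.0])
        z, p = wilcoxon_signed_rank(a, b)
        ref = stats.wilcoxon(a, b, zero_method="wilcox", correction=False, method="approx")
        assert abs(z) == pytest.approx(abs(ref.zstatistic), abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approximation_close_to_exact_enumeration_at_n8(self):
        # exact two-sided p by enumerating all 2^8 sign assignments of the ranks
        d = np.array([3.0, -1.0, 4.0, 2.0, 7.0, 5.0, -6.0, 8.0])
        ranks = stats.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        total = ranks.sum()
        dist = [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([False, True], repeat=8)
        ]
        dist = np.asarray(dist)
        mu = total / 2.0
        p_exact = np.mean(np.abs(dist - mu) >= abs(w_obs - mu) - 1e-9)
        _, p_approx = wilcoxon_signed_rank(d + 100.0, np.full(8, 100.0))
        assert p_approx == pytest.approx(p_exact, abs=0.03)

    def test_all_zero_differences_flagged_degenerate(self):
        out = wilcoxon_pairs(_mm(a=[5.0, 6.0], b=[5.0, 6.0]), [("a", "b")])
        assert out[0].degenerate and np.isnan(out[0].z_statistic)

    def test_reported_difference_moments_are_raw(self):
        a = np.array([10.0, 20.0, 30.0])
        b = np.array([12.0, 19.0, 33.0])
        (cmp_,) = wilcoxon_pairs(_mm(a=a, b=b), [("a", "b")])
        assert cmp_.mean_difference == pytest.approx(-4.0 / 3.0, abs=1e-12)
        assert cmp_.sd_difference == pytest.approx(2.0816659994661326, abs=1e-12)

    def test_pairs_table_formats_small_p(self):
        rng = np.random.default_rng(9)
        a = rng.uniform(20, 80, 60)
        b = np.clip(a + 5.0, 0, 100)
        table = pairs_table(wilcoxon_pairs(_mm(a=a, b=b), [("a", "b")]))
        assert table["p_display"].iloc[0] == "<0.001"


class TestRegression:
    def test_identity_line(self):
        x = np.array([1.0, 4.0, 9.0, 16.0])
        fit = fit_regression(x, x)
        assert (fit.slope, fit.intercept, fit.r_squared) == pytest.approx((1.0, 0.0, 1.0))

    def test_exact_line_hand_values(self):
        fit = fit_regression([0.0, 1.0, 2.0], [1.0, 3.0, 5.0])
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(1.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(10)
        x = rng.uniform(0, 90, 10)
        y = np.clip(0.8 * x + 3 + rng.normal(0, 4, 10), 0, 100)
        fit = fit_regression(x, y)
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-12)
        assert fit.slope == pytest.approx(beta[1], abs=1e-12)

    def test_ln_transform_uses_offset_for_zeros(self):
        x = np.array([0.0, 10.0, 50.0])
        y = np.array([0.0, 12.0, 45.0])
        fit = fit_regression(x, y, transform="ln")
        assert np.allclose(fit.x, np.log(x + LN_OFFSET))
        assert np.isfinite(fit.slope)

    def test_confidence_band_contains_fit_line(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(0, 90, 30)
        y = np.clip(x + rng.normal(0, 5, 30), 0, 100)
        fit = fit_regression(x, y)
        xs = np.linspace(5, 85, 7)
        lo, hi = fit.confidence_band(xs)
        mid = fit.intercept + fit.slope * xs
        assert np.all(lo <= mid) and np.all(mid <= hi)

    def test_zero_variance_x_rejected(self):
        with pytest.raises(ParameterError):
            fit_regression([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])


class TestBlandAltman:
    def test_identical_methods_zero_bias_zero_width(self):
        x = np.array([10.0, 30.0, 70.0])
        res = bland_altman(x, x)
        assert res.mean_difference == 0.0
        assert res.loa_high - res.loa_low == 0.0

    def test_three_point_hand_computation(self):
        res = bland_altman([10.0, 20.0, 30.0], [12.0, 19.0, 33.0])
        assert np.allclose(res.differences, [2.0, -1.0, 3.0])
        assert res.mean_difference == pytest.approx(4.0 / 3.0, abs=1e-12)
        assert res.sd_difference == pytest.approx(2.0816659994661326, abs=1e-12)
        assert res.loa_low == pytest.approx(4.0 / 3.0 - 2 * 2.0816659994661326, abs=1e-12)
        assert res.loa_high == pytest.approx(4.0 / 3.0 + 2 * 2.0816659994661326, abs=1e-12)

    def test_x_axis_is_the_reference(self):
        ref = np.array([10.0, 20.0, 30.0])
        res = bland_altman(ref, [12.0, 19.0, 33.0])
        assert np.array_equal(res.x_values, ref)

    def test_loa_width_linear_in_multiplier(self):
        ref = np.array([10.0, 20.0, 30.0, 40.0])
        test = np.array([11.0, 18.0, 33.0, 44.0])
        w2 = bland_altman(ref, test, multiplier=2.0)
        w196 = bland_altman(ref, test, multiplier=1.96)
        assert (w196.loa_high - w196.loa_low) / (w2.loa_high - w2.loa_low) == pytest.approx(0.98)

    def test_histogram_counts_all_differences(self):
        res = bland_altman([0.0, 10.0, 20.0, 30.0], [1.0, 9.0, 25.0, 28.0])
        assert res.histogram[0].sum() == 4

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            bland_altman([1.0, 2.0], [1.0, 2.0, 3.0])


def test_format_p_never_prints_zero():
    assert format_p(1e-7) == "<0.001"
    assert format_p(0.024) == "0.024"


def test_ln_transform_of_zero_is_finite():
    assert np.isfinite(ln_transform(np.array([0.0]))).all()
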