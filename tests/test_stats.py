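"""The statistics battery against hand-derived and enumeration oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dtialps.stats import (
    chi_square_2x2,
    cohens_d,
    fisher_exact_2x2,
    linear_fit,
    logistic_fit,
    mann_whitney_u,
    pearson_r,
    pooled_t_test,
    pooled_t_test_data,
    vif,
    welch_t_test,
)

# observed group summaries of the processing-speed index (with vs without ePVS)
PSI_WITH = (98.7, 12.7, 26)
PSI_WITHOUT = (105.1, 14.5, 34)


class TestPooledT:
    def test_psi_group_summary(self):
        res = pooled_t_test(*PSI_WITH, *PSI_WITHOUT)
        assert res.effect_size == pytest.approx(-6.4)
        assert round(res.p_value, 2) == 0.08
        assert res.statistic == pytest.approx(-1.786, abs=5e-4)
        assert res.df == 58
        assert res.ci_low < -6.4 < res.ci_high

    def test_identical_groups(self):
        res = pooled_t_test(5.0, 1.0, 20, 5.0, 1.0, 20)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_raw_data_overload_matches_summary_form(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 30), rng.normal(0.5, 1.2, 25)
        a = pooled_t_test_data(x, y)
        b = pooled_t_test(x.mean(), x.std(ddof=1), 30, y.mean(), y.std(ddof=1), 25)
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pooled_t_test(1.0, 1.0, 1, 2.0, 1.0, 10)
        with pytest.raises(ValueError):
            pooled_t_test(1.0, 0.0, 10, 2.0, 1.0, 10)

    def test_type_one_error_rate_is_nominal(self):
        """Pooled t at alpha=0.05 rejects ~5% of 10,000 null simulations."""
        rng = np.random.default_rng(12345)
        n = 20
        x = rng.normal(0, 1, (10_000, n))
        y = rng.normal(0, 1, (10_000, n))
        res = pooled_t_test(
            x.mean(1), x.std(1, ddof=1), n, y.mean(1), y.std(1, ddof=1), n
        )
        rate = np.mean(res.p_value < 0.05)
        assert 0.04 <= rate <= 0.06


class TestWelchT:
    def test_identical_groups(self):
        assert welch_t_test(5.0, 1.0, 20, 5.0, 1.0, 20).p_value == 1.0

    def test_psi_summary_hand_value(self):
        res = welch_t_test(*PSI_WITH, *PSI_WITHOUT)
        assert res.statistic == pytest.approx(-1.818, abs=5e-4)

    def test_equal_variance_limit_matches_pooled(self):
        w = welch_t_test(3.0, 2.0, 30, 4.0, 2.0, 30)
        p = pooled_t_test(3.0, 2.0, 30, 4.0, 2.0, 30)
        assert w.statistic == pytest.approx(p.statistic, abs=1e-6)
        assert w.df == pytest.approx(p.df, abs=1e-6)


class TestMannWhitney:
    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert mann_whitney_u(x, x).p_value == pytest.approx(1.0)

    def test_complete_separation_gives_zero_u(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0

    def test_large_shift_detected(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 200)
        y = rng.normal(1.0, 1, 200)
        assert mann_whitney_u(x, y).p_value < 0.001


class TestTwoByTwo:
    def test_chi_square_closed_form(self):
        # n (ad - bc)^2 / (r1 r2 c1 c2)
        t = np.array([[12, 14], [3, 31]])
        n = t.sum()
        a, b, c, d = t.ravel()
        expected = n * (a * d - b * c) ** 2 / (
            t.sum(1)[0] * t.sum(1)[1] * t.sum(0)[0] * t.sum(0)[1]
        )
        res = chi_square_2x2(t, yates=False)
        assert res.statistic == pytest.approx(expected)
        assert res.statistic == pytest.approx(10.95, abs=5e-3)
        assert res.df == 1

    def test_uniform_table_null(self):
        res = chi_square_2x2([[10, 10], [10, 10]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_yates_never_exceeds_uncorrected(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            t = rng.integers(1, 30, (2, 2))
            assert (
                chi_square_2x2(t, yates=True).statistic
                <= chi_square_2x2(t, yates=False).statistic + 1e-12
            )

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[0, 0], [5, 10]])

    def test_fisher_matches_enumeration_oracle(self):
        t = np.array([[8, 18], [1, 33]])
        assert fisher_exact_2x2(t).p_value == pytest.approx(
            fisher_enumeration_p(t), abs=1e-12
        )

    def test_fisher_handles_zero_cells(self):
        res = fisher_exact_2x2([[0, 10], [10, 0]])
        assert 0.0 <= res.p_value <= 1.0


def fisher_enumeration_p(table) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration (oracle)."""
    t = np.asarray(table, dtype=int)
    r1, r2 = t.sum(axis=1)
    c1 = t[:, 0].sum()
    n = t.sum()
    dist = sps.hypergeom(n, r1, c1)
    support = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = dist.pmf(support)
    p_obs = dist.pmf(t[0, 0])
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-9)].sum()))


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        res = pearson_r(x, 2 * x)
        assert res.effect_size == pytest.approx(1.0)

    def test_hand_value(self):
        res = pearson_r([1, 2, 3], [1, 3, 2])
        assert res.effect_size == pytest.approx(0.5)

    def test_generating_correlation_recovered(self):
        rng = np.random.default_rng(21)
        n = 5000
        x = rng.normal(0, 1, n)
        y = 0.22 * x + np.sqrt(1 - 0.22**2) * rng.normal(0, 1, n)
        res = pearson_r(x, y)
        assert res.effect_size == pytest.approx(0.22, abs=0.03)
        assert res.p_value < 0.05


class TestCohensD:
    def test_equal_means(self):
        assert cohens_d(1.0, 1.0, 50, 1.0, 1.0, 50).effect_size == 0.0

    def test_unit_case(self):
        assert cohens_d(0.0, 1.0, 50, 1.0, 1.0, 50).effect_size == pytest.approx(-1.0)

    def test_psi_summary_pooled_formula(self):
        # pooled-SD formula on the group summaries gives -0.465
        res = cohens_d(*PSI_WITH, *PSI_WITHOUT)
        assert res.effect_size == pytest.approx(-0.465, abs=5e-4)
        assert res.ci_low < res.effect_size < res.ci_high


class TestLogistic:
    def test_null_predictor_odds_ratio_near_one(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 2000)
        x = rng.normal(0, 1, 2000)
        res = logistic_fit(y, x[:, None], names=["x"])
        assert res.converged
        assert res.odds_ratios["x"] == pytest.approx(1.0, abs=0.15)

    def test_saturated_2x2_equals_cross_product_odds_ratio(self):
        # cells: (x=1,y=1)=12 (x=1,y=0)=14 (x=0,y=1)=3 (x=0,y=0)=31
        x = np.r_[np.ones(26), np.zeros(34)]
        y = np.r_[np.ones(12), np.zeros(14), np.ones(3), np.zeros(31)]
        res = logistic_fit(y, x[:, None], names=["exposure"])
        assert res.converged
        assert res.odds_ratios["exposure"] == pytest.approx(12 * 31 / (14 * 3), rel=1e-5)

    def test_perfect_separation_flagged(self):
        x = np.r_[np.zeros(10), np.ones(10)]
        y = x.copy()
        res = logistic_fit(y, x[:, None] + np.random.default_rng(0).normal(0, 1e-6, (20, 1)))
        assert not res.converged

    def test_per_sd_rescales_continuous_predictors(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 2.0, 1500)
        y = (rng.random(1500) < 1 / (1 + np.exp(-0.5 * x))).astype(float)
        per_unit = logistic_fit(y, x[:, None], names=["x"])
        per_sd = logistic_fit(y, x[:, None], names=["x"], per_sd=True)
        sd = np.std(x, ddof=1)
        assert np.log(per_sd.odds_ratios["x"]) == pytest.approx(
            np.log(per_unit.odds_ratios["x"]) * sd, rel=1e-6
        )

    def test_non_binary_outcome_rejected(self):
        with pytest.raises(ValueError):
            logistic_fit([0, 1, 2], np.ones((3, 1)))


class TestLinear:
    def test_exact_fit_recovers_coefficients(self):
        rng = np.random.default_rng(6)
        X = rng.normal(0, 1, (50, 3))
        beta = np.array([1.5, -2.0, 0.25])
        y = X @ beta + 4.0
        res = linear_fit(y, X, names=["a", "b", "c"])
        np.testing.assert_allclose(res.coefficients[["a", "b", "c"]], beta, atol=1e-10)
        assert res.coefficients["const"] == pytest.approx(4.0)

    def test_standardized_beta_equals_r_for_single_predictor(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 3, 500)
        y = 0.4 * x + rng.normal(0, 1, 500)
        res = linear_fit(y, x[:, None], names=["x"])
        r = pearson_r(x, y).effect_size
        assert res.standardized_betas["x"] == pytest.approx(r, abs=1e-10)

    def test_standardize_flag_matches_posthoc_betas(self):
        rng = np.random.default_rng(10)
        X = rng.normal(0, [1.0, 5.0], (300, 2))
        y = X @ [0.5, -0.1] + rng.normal(0, 1, 300)
        raw = linear_fit(y, X, names=["a", "b"])
        std = linear_fit(y, X, names=["a", "b"], standardize=True)
        np.testing.assert_allclose(
            std.coefficients[["a", "b"]], raw.standardized_betas[["a", "b"]], atol=1e-10
        )


class TestVIF:
    def test_orthogonal_predictors_give_one(self):
        # full-factorial +/-1 design: columns mutually orthogonal and centered
        levels = np.array([-1.0, 1.0])
        X = np.array(np.meshgrid(levels, levels, levels)).reshape(3, -1).T
        v = vif(X)
        np.testing.assert_allclose(v.to_numpy(), 1.0, atol=1e-10)

    def test_known_pairwise_correlation(self):
        # two predictors with r = 0.9 -> VIF = 1/(1-0.81) = 5.263
        rng = np.random.default_rng(12)
        n = 50_000
        x = rng.normal(0, 1, n)
        y = 0.9 * x + np.sqrt(1 - 0.81) * rng.normal(0, 1, n)
        v = vif(np.column_stack([x, y]))
        assert v.iloc[0] == pytest.approx(5.263, abs=0.08)

    def test_vif_at_least_one(self):
        rng = np.random.default_rng(13)
        X = rng.normal(0, 1, (100, 4))
        assert (vif(X) >= 1.0 - 1e-12).all()
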