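import numpy as np
import pandas as pd
import pytest
from scipy import stats

import retestkit as rk
from retestkit.aggregation import AggregationRule, ScoreMatrix
from retestkit.datamodel import UndefinedStatisticError, Variable
from retestkit.reliability import (
    classify_icc,
    cv_percent,
    distribution_gates,
    icc_mean,
    icc_single,
    mean_squares,
    rm_anova,
)

from conftest import random_matrix


def brute_force_ss(Y):
    """Independent spreadsheet-style sums-of-squares decomposition."""
    Y = np.asarray(Y, dtype=float)
    n, k = Y.shape
    gm = Y.sum() / Y.size
    ssr = sum(k * (Y[i].mean() - gm) ** 2 for i in range(n))
    ssc = sum(n * (Y[:, j].mean() - gm) ** 2 for j in range(k))
    sst = sum((Y[i, j] - gm) ** 2 for i in range(n) for j in range(k))
    sse = sst - ssr - ssc
    return ssr, ssc, sse, sst


def _matrix(vals, rule=AggregationRule.HIGHEST):
    vals = np.asarray(vals, dtype=float)
    n, k = vals.shape
    return ScoreMatrix(Variable.JUMP_HEIGHT, rule,
                       [f"s{i}" for i in range(n)],
                       [f"S{j + 1}" for j in range(k)], vals)


class TestMeanSquares:
    def test_perfect_agreement_matrix(self):
        ms = mean_squares(np.array([[1, 1], [2, 2], [3, 3]]))
        assert ms.mse == pytest.approx(0)
        assert ms.msc == pytest.approx(0)
        assert ms.msr == pytest.approx(2.0)  # k * Var(row means) = 2 * 1

    def test_pure_column_effect(self):
        # [[0,1],[0,1]]: rows identical, columns differ by 1
        ms = mean_squares(np.array([[0, 1], [0, 1]]))
        ssr, ssc, sse, _ = brute_force_ss([[0, 1], [0, 1]])
        assert ms.msr == pytest.approx(ssr / 1)
        assert ms.msc == pytest.approx(ssc / 1)
        assert ms.mse == pytest.approx(sse / 1)

    def test_integer_fixture_matches_brute_force(self):
        Y = np.array([[12, 14, 13], [9, 11, 10], [15, 15, 17],
                      [8, 9, 11], [13, 12, 12]], dtype=float)
        ms = mean_squares(Y)
        ssr, ssc, sse, _ = brute_force_ss(Y)
        assert ms.msr == pytest.approx(ssr / 4, rel=1e-12)
        assert ms.msc == pytest.approx(ssc / 2, rel=1e-12)
        assert ms.mse == pytest.approx(sse / 8, rel=1e-12)

    def test_ss_decomposition_identity_on_random_matrices(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            Y = random_matrix(rng)
            ms = mean_squares(Y)
            ssr = ms.msr * ms.df_r
            ssc = ms.msc * ms.df_c
            sse = ms.mse * ms.df_e
            sst = np.sum((Y - Y.mean()) ** 2)
            assert ssr + ssc + sse == pytest.approx(sst, rel=1e-9)


class TestICC:
    def test_perfect_agreement_gives_one_with_collapsed_ci(self):
        ms = mean_squares(np.array([[1, 1], [2, 2], [3, 3], [4, 4]]))
        for fn in (icc_single, icc_mean):
            res = fn(ms)
            assert res.estimate == 1.0
            assert (res.ci_low, res.ci_high) == (1.0, 1.0)
            assert res.classification == "excellent"

    def test_zero_subject_variance_gives_nonpositive_estimate(self):
        Y = np.array([[0, 1], [1, 0], [0, 1], [1, 0]], dtype=float)
        res = icc_single(mean_squares(Y))
        assert res.estimate <= 0
        assert res.classification == "poor"

    def test_constant_matrix_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            icc_single(mean_squares(np.full((4, 3), 7.0)))

    def test_matches_pingouin_estimates_and_cis(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        for _ in range(40):
            Y = random_matrix(rng)
            n, k = Y.shape
            ms = mean_squares(Y)
            mine1, minek = icc_single(ms), icc_mean(ms)
            df = pd.DataFrame({
                "subject": np.repeat(np.arange(n), k),
                "session": np.tile(np.arange(k), n),
                "y": Y.ravel(),
            })
            table = pg.intraclass_corr(df, "subject", "session", "y").set_index("Type")
            assert mine1.estimate == pytest.approx(table.loc["ICC(A,1)", "ICC"], abs=1e-9)
            assert minek.estimate == pytest.approx(table.loc["ICC(A,k)", "ICC"], abs=1e-9)
            lo1, hi1 = table.loc["ICC(A,1)", "CI95"]  # rounded to 2 decimals
            assert mine1.ci_low == pytest.approx(lo1, abs=0.005 + 1e-9)
            assert mine1.ci_high == pytest.approx(hi1, abs=0.005 + 1e-9)
            lok, hik = table.loc["ICC(A,k)", "CI95"]
            assert minek.ci_low == pytest.approx(lok, abs=0.005 + 1e-9)
            assert minek.ci_high == pytest.approx(hik, abs=0.005 + 1e-9)

    def test_spearman_brown_identity(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            Y = random_matrix(rng)
            ms = mean_squares(Y)
            single = icc_single(ms).estimate
            mean = icc_mean(ms).estimate
            k = Y.shape[1]
            assert mean == pytest.approx(k * single / (1 + (k - 1) * single), rel=1e-9)
            if single >= 0:
                assert mean >= single - 1e-12

    def test_shift_invariance_and_scale_invariance(self):
        rng = np.random.default_rng(9)
        Y = random_matrix(rng, n=8, k=3)
        base = icc_single(mean_squares(Y))
        shifted = icc_single(mean_squares(Y + 123.4))
        scaled = icc_single(mean_squares(Y * 7.5))
        for other in (shifted, scaled):
            assert other.estimate == pytest.approx(base.estimate, rel=1e-9)
            assert other.ci_low == pytest.approx(base.ci_low, rel=1e-9)
            assert other.ci_high == pytest.approx(base.ci_high, rel=1e-9)

    def test_ci_bounds_bracket_estimate(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            res = icc_single(mean_squares(random_matrix(rng)))
            assert res.ci_low <= res.estimate <= res.ci_high
            assert res.ci_high <= 1.0


class TestClassification:
    @pytest.mark.parametrize(
        "estimate,expected",
        [
            (0.49, "poor"),
            (0.50, "moderate"),   # boundary closes the moderate band
            (0.75, "moderate"),
            (0.76, "good"),
            (0.90, "good"),       # 0.90 itself is not excellent
            (0.901, "excellent"),
            (0.988, "excellent"),
            (-0.3, "poor"),
        ],
    )
    def test_koo_li_bands(self, estimate, expected):
        assert classify_icc(estimate) == expected


class TestCV:
    def test_constant_subjects_give_zero(self):
        Y = np.tile(np.array([[3.0], [5.0], [9.0]]), (1, 4))
        assert cv_percent(Y) == 0.0

    def test_two_point_subject(self):
        # SD of (9, 11) is sqrt(2), mean 10 -> 14.14%
        Y = np.array([[9.0, 11.0], [10.0, 10.0]])
        expected = (np.sqrt(2.0) / 10 * 100 + 0.0) / 2
        assert cv_percent(Y) == pytest.approx(expected)
        assert np.sqrt(2.0) / 10 * 100 == pytest.approx(14.14, abs=0.005)

    def test_matches_independent_per_row_recomputation(self):
        rng = np.random.default_rng(21)
        Y = random_matrix(rng, n=17, k=3)
        per_row = [np.std(row, ddof=1) / np.mean(row) * 100 for row in Y]
        assert cv_percent(Y) == pytest.approx(np.mean(per_row), rel=1e-12)

    def test_nonpositive_subject_mean_rejected(self):
        Y = np.array([[0.0, 0.0], [1.0, 2.0]])
        with pytest.raises(UndefinedStatisticError):
            cv_percent(Y)

    def test_scale_invariance(self):
        rng = np.random.default_rng(23)
        Y = random_matrix(rng)
        assert cv_percent(Y * 3.7) == pytest.approx(cv_percent(Y), rel=1e-12)


class TestRmAnova:
    def test_identical_columns_give_f_zero(self):
        Y = np.array([[1.0, 1.0], [2.0, 2.0], [5.0, 5.0]])
        res = rm_anova(Y)
        assert res.f_stat == 0.0
        assert res.p_value == 1.0
        assert not res.significant

    def test_pure_shift_without_noise_is_degenerate_infinite_f(self):
        Y = np.array([[0.0, 1.0], [2.0, 3.0], [4.0, 5.0]])
        res = rm_anova(Y)
        assert res.degenerate
        assert np.isinf(res.f_stat)
        assert res.p_value == 0.0
        assert res.significant

    def test_k2_equals_squared_paired_t(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            Y = random_matrix(rng, k=2)
            res = rm_anova(Y)
            t, p = stats.ttest_rel(Y[:, 0], Y[:, 1])
            assert res.f_stat == pytest.approx(t**2, rel=1e-9)
            assert res.p_value == pytest.approx(p, abs=1e-9)

    def test_matches_statsmodels_anova_rm(self):
        AnovaRM = pytest.importorskip("statsmodels.stats.anova").AnovaRM
        rng = np.random.default_rng(37)
        Y = random_matrix(rng, n=8, k=3)
        res = rm_anova(Y)
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(8), 3),
            "session": np.tile(np.arange(3), 8),
            "y": Y.ravel(),
        })
        sm_res = AnovaRM(long, "y", "subject", within=["session"]).fit()
        assert res.f_stat == pytest.approx(sm_res.anova_table["F Value"].iloc[0], rel=1e-9)
        assert res.p_value == pytest.approx(sm_res.anova_table["Pr > F"].iloc[0], abs=1e-9)

    def test_shift_invariance(self):
        rng = np.random.default_rng(41)
        Y = random_matrix(rng)
        assert rm_anova(Y + 55.0).p_value == pytest.approx(rm_anova(Y).p_value, rel=1e-9)


class TestGates:
    def test_gaussian_columns_pass(self):
        rng = np.random.default_rng(43)
        Y = _matrix(rng.normal(50, 5, size=(17, 3)))
        gates = distribution_gates(Y)
        assert len(gates) == 4  # 3 Shapiro columns + Levene
        assert all(g.passed for g in gates)

    def test_extreme_outlier_fails_normality(self):
        rng = np.random.default_rng(47)
        vals = rng.normal(1.0, 0.1, size=(17, 3))
        vals[0, 0] = 1e6
        gates = distribution_gates(_matrix(vals))
        shapiro_s1 = [g for g in gates if g.test == "shapiro_wilk" and g.column == "S1"]
        assert not shapiro_s1[0].passed

    def test_equal_columns_give_levene_zero(self):
        vals = np.tile(np.array([[1.0], [2.0], [4.0], [9.0]]), (1, 3))
        gates = distribution_gates(_matrix(vals))
        levene = [g for g in gates if g.test == "levene"][0]
        assert levene.statistic == 0.0
        assert levene.passed

    def test_small_n_skips_normality(self):
        vals = np.array([[1.0, 2.0], [3.0, 5.0]])
        gates = distribution_gates(_matrix(vals))
        assert all(g.test == "levene" for g in gates)
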