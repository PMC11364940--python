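"""Evaluation statistics against independent oracles and closed forms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from crutchgait import (
    GroupSummary,
    SusResponse,
    above_average_fraction,
    box_m_test,
    combined_summary,
    format_p,
    levene_test,
    manova_stats_from_eigenvalue,
    manova_two_group,
    one_way_anova,
    pearson_correlation,
    proportion_yes,
    sus_score,
)


class TestManovaClosedForm:
    def test_single_eigenvalue_identities(self):
        r = manova_stats_from_eigenvalue(0.763, 25, 2)
        assert r.pillai == pytest.approx(0.763 / 1.763)
        assert r.wilks == pytest.approx(1 / 1.763)
        assert r.hotelling_trace == 0.763
        assert r.roy == 0.763
        assert r.F == pytest.approx(0.763 * 22 / 2)
        assert (r.df1, r.df2) == (2, 22)

    def test_zero_eigenvalue_degenerates(self):
        r = manova_stats_from_eigenvalue(0.0, 25, 2)
        assert (r.pillai, r.wilks, r.hotelling_trace, r.F, r.p) == (0.0, 1.0, 0.0, 0.0, 1.0)

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            manova_stats_from_eigenvalue(0.5, 3, 2)
        with pytest.raises(ValueError):
            manova_stats_from_eigenvalue(-0.1, 25, 2)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        lam=st.floats(0.0, 50.0, allow_nan=False),
        n=st.integers(5, 200),
        p=st.integers(1, 3),
    )
    def test_identities_hold_for_all_inputs(self, lam, n, p):
        if n <= p + 1:
            return
        r = manova_stats_from_eigenvalue(lam, n, p)
        assert r.pillai + r.wilks == pytest.approx(1.0)
        assert r.roy == r.hotelling_trace
        assert r.F == pytest.approx(r.roy * r.df2 / r.df1)


class TestManovaTwoGroup:
    def test_identical_groups_give_null_result(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(10, 2))
        r = manova_two_group(A, A)
        assert r.eigenvalue == pytest.approx(0.0, abs=1e-12)
        assert r.wilks == pytest.approx(1.0)
        assert r.F == pytest.approx(0.0, abs=1e-10)

    def test_agrees_with_brute_force_hotelling_t2(self):
        # independent oracle: T^2 from pooled covariance; lambda = T^2/(N-2)
        rng = np.random.default_rng(11)
        for _ in range(20):
            na, nb, p = rng.integers(5, 15), rng.integers(5, 15), rng.integers(1, 4)
            A = rng.normal(size=(na, p))
            B = rng.normal(rng.normal(), 1.5, size=(nb, p))
            d = A.mean(0) - B.mean(0)
            Sp = ((na - 1) * np.cov(A, rowvar=False, ddof=1) + (nb - 1) * np.cov(B, rowvar=False, ddof=1)) / (na + nb - 2)
            T2 = (na * nb / (na + nb)) * d @ np.linalg.solve(np.atleast_2d(Sp), d)
            lam_oracle = T2 / (na + nb - 2)
            r = manova_two_group(A, B)
            assert r.eigenvalue == pytest.approx(lam_oracle, abs=1e-10)

    def test_agrees_with_statsmodels(self):
        import pandas as pd
        from statsmodels.multivariate.manova import MANOVA

        rng = np.random.default_rng(5)
        A = rng.normal(0, 1, (12, 2))
        B = rng.normal(0.7, 1.1, (13, 2))
        r = manova_two_group(A, B)
        df = pd.DataFrame(np.vstack([A, B]), columns=["v1", "v2"])
        df["g"] = ["a"] * 12 + ["b"] * 13
        tbl = MANOVA.from_formula("v1 + v2 ~ g", data=df).mv_test().results["g"]["stat"]
        assert r.wilks == pytest.approx(tbl.loc["Wilks' lambda", "Value"], abs=1e-10)
        assert r.pillai == pytest.approx(tbl.loc["Pillai's trace", "Value"], abs=1e-10)
        assert r.F == pytest.approx(tbl.loc["Wilks' lambda", "F Value"], abs=1e-8)

    def test_singular_within_covariance_names_variable(self):
        A = np.column_stack([np.arange(5.0), np.ones(5)])
        B = np.column_stack([np.arange(5.0) + 1, np.ones(5)])
        with pytest.raises(ValueError, match="singular"):
            manova_two_group(A, B)

    def test_type_one_error_calibrated_under_null(self):
        # two groups from the same bivariate normal: rejection rate ~ alpha
        rng = np.random.default_rng(314)
        n_sim, alpha = 10_000, 0.05
        rejections = 0
        for _ in range(n_sim):
            A = rng.normal(size=(12, 2))
            B = rng.normal(size=(13, 2))
            if manova_two_group(A, B).p < alpha:
                rejections += 1
        assert rejections / n_sim == pytest.approx(alpha, abs=0.01)


class TestHomogeneityTests:
    def test_levene_identical_patterns_give_zero(self):
        g = [1.0, 2.0, 3.0, 4.0]
        W, p = levene_test([g, [x + 10 for x in g]])
        assert W == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_levene_agrees_with_scipy(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            gs = [rng.normal(0, s, rng.integers(5, 20)) for s in (1.0, 2.0, 0.5)]
            W, p = levene_test(gs)
            ref = sps.levene(*gs, center="mean")
            assert W == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_levene_median_variant_matches_brown_forsythe(self):
        rng = np.random.default_rng(22)
        gs = [rng.normal(0, s, 15) for s in (1.0, 3.0)]
        W, p = levene_test(gs, center="median")
        ref = sps.levene(*gs, center="median")
        assert W == pytest.approx(ref.statistic, abs=1e-10)

    def test_levene_detects_strong_heteroscedasticity(self):
        rng = np.random.default_rng(23)
        a = rng.normal(0, 1, 50)
        b = rng.normal(0, 10, 50)
        _, p = levene_test([a, b])
        assert p < 0.05

    def test_box_m_identical_covariances(self):
        rng = np.random.default_rng(31)
        A = rng.normal(size=(15, 2))
        M, chi2, df, p = box_m_test([A, A + 5.0])  # shift changes nothing
        assert M == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_box_m_agrees_with_pingouin(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(32)
        A = rng.normal(0, 1, (12, 2))
        B = rng.normal(0, 2, (13, 2))
        M, chi2, df, p = box_m_test([A, B])
        dfr = pd.DataFrame(np.vstack([A, B]), columns=["v1", "v2"])
        dfr["g"] = ["a"] * 12 + ["b"] * 13
        ref = pg.box_m(dfr, dvs=["v1", "v2"], group="g")
        assert chi2 == pytest.approx(float(ref["Chi2"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(ref["pval"].iloc[0]), abs=1e-10)
        assert df == int(ref["df"].iloc[0])

    def test_box_m_detects_gross_covariance_difference(self):
        rng = np.random.default_rng(33)
        A = rng.normal(0, 1, (30, 2))
        B = rng.normal(0, 6, (30, 2))
        *_, p = box_m_test([A, B])
        assert p < 0.001


class TestAnova:
    def test_identical_groups_give_f_zero(self):
        g = [1.0, 2.0, 3.0]
        F, *_ , p = one_way_anova([g, g])
        assert F == pytest.approx(0.0, abs=1e-12)

    def test_correct_run_counts_reproduce_reported_nonsignificance(self):
        intervention = [3] * 10 + [2] * 2
        control = [3] * 8 + [2] * 3 + [1] * 2
        F, df1, df2, p = one_way_anova([intervention, control])
        assert (df1, df2) == (1, 23)
        assert p == pytest.approx(0.15, abs=0.005)

    def test_agrees_with_scipy_f_oneway(self):
        rng = np.random.default_rng(41)
        for _ in range(20):
            gs = [rng.normal(rng.normal(), 1, rng.integers(4, 15)) for _ in range(3)]
            F, _, _, p = one_way_anova(gs)
            ref = sps.f_oneway(*gs)
            assert F == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_degenerate_all_equal_gives_p_one(self):
        F, _, _, p = one_way_anova([[2.0, 2.0], [2.0, 2.0]])
        assert (F, p) == (0.0, 1.0)


class TestCombinedSummary:
    def test_pooled_age_and_height_means(self):
        a = GroupSummary(14, {"age": 44.4, "height": 173.1}, {"age": 20.7, "height": 11.6})
        b = GroupSummary(14, {"age": 37.8, "height": 175.3}, {"age": 17.6, "height": 11.9})
        c = combined_summary(a, b)
        assert c.n == 28
        assert c.mean["age"] == pytest.approx(41.1, abs=0.05)
        assert c.mean["height"] == pytest.approx(174.2, abs=0.05)

    def test_equal_groups_equal_sds_pool_like_concatenated_data(self):
        # two n=10 groups, same mean, SD 2: concatenating gives
        # SS = 2 * 9 * 4 = 72 on 19 df, slightly below the group SD
        a = GroupSummary(10, {"v": 5.0}, {"v": 2.0})
        b = GroupSummary(10, {"v": 5.0}, {"v": 2.0})
        assert combined_summary(a, b).sd["v"] == pytest.approx(math.sqrt(72 / 19))

    def test_pooling_matches_concatenated_data(self):
        rng = np.random.default_rng(51)
        x, y = rng.normal(0, 1, 9), rng.normal(2, 3, 14)
        a = GroupSummary(9, {"v": x.mean()}, {"v": x.std(ddof=1)})
        b = GroupSummary(14, {"v": y.mean()}, {"v": y.std(ddof=1)})
        c = combined_summary(a, b)
        z = np.concatenate([x, y])
        assert c.mean["v"] == pytest.approx(z.mean(), abs=1e-12)
        assert c.sd["v"] == pytest.approx(z.std(ddof=1), abs=1e-12)


class TestSus:
    def test_neutral_best_and_worst_responses(self):
        assert sus_score([3] * 10) == 50.0
        assert sus_score([5, 1] * 5) == 100.0
        assert sus_score([1, 5] * 5) == 0.0

    def test_out_of_range_item_rejected(self):
        with pytest.raises(ValueError):
            SusResponse(tuple([3] * 9 + [6]))
        with pytest.raises(ValueError):
            SusResponse(tuple([3] * 9))

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(items=st.lists(st.integers(1, 5), min_size=10, max_size=10))
    def test_scores_live_on_the_quarter_point_grid(self, items):
        s = sus_score(items)
        assert 0.0 <= s <= 100.0
        assert (s / 2.5) == int(s / 2.5)

    def test_above_average_fraction(self):
        scores = [70] * 9 + [60] * 5
        assert above_average_fraction(scores) == (9, 64)
        assert above_average_fraction([50, 40]) == (0, 0)
        assert above_average_fraction([10, 20], threshold=0)[1] == 100

    def test_exactly_at_threshold_not_above(self):
        assert above_average_fraction([68.0, 70.0])[0] == 1


class TestProportions:
    @pytest.mark.parametrize("k,n,expected", [(11, 14, 79), (6, 14, 43), (0, 14, 0), (14, 14, 100)])
    def test_rounded_percentages(self, k, n, expected):
        assert proportion_yes(k, n) == expected

    def test_half_rounds_away_from_zero(self):
        assert proportion_yes(1, 8) == 13  # 12.5 -> 13

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            proportion_yes(5, 4)
        with pytest.raises(ValueError):
            proportion_yes(-1, 4)


class TestPearson:
    def test_perfect_correlations(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson_correlation(x, x)[0] == pytest.approx(1.0)
        assert pearson_correlation(x, [-v for v in x])[0] == pytest.approx(-1.0)

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(61)
        for _ in range(20):
            x = rng.normal(size=12)
            y = 0.4 * x + rng.normal(size=12)
            r, p = pearson_correlation(x, y)
            ref = sps.pearsonr(x, y)
            assert r == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestFormatting:
    def test_journal_style_p_values(self):
        assert format_p(0.0005) == "<.001"
        assert format_p(0.002) == ".002"
        assert format_p(0.47) == ".470"
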