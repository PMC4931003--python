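"""Contracts of the inferential-statistics layer, checked against
small-instance hand arithmetic and (for the model-comparison F-tests)
against statsmodels as an independent oracle."""

import numpy as np
import pytest
import scipy.stats as ss
from hypothesis import given, strategies as st

from thermoreg.stats import (
    ancova_slope_homogeneity,
    kruskal_wallis,
    linear_regression,
    mann_whitney_u,
    nemenyi_posthoc,
    oneway_anova,
    twoway_interaction,
)


class TestMannWhitney:
    def test_complete_separation(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0
        # Exact two-sided p at full separation: 2 / C(6,3)
        assert res.p_value == pytest.approx(0.1)

    def test_interleaved_pair_count(self):
        # pairs with a > b: (3,2), (5,2), (5,4) -> U_a = 3 = min side
        res = mann_whitney_u([1, 3, 5], [2, 4, 6])
        assert res.statistic == 3

    @given(
        a=st.lists(st.floats(0, 100), min_size=1, max_size=25),
        b=st.lists(st.floats(0, 100), min_size=1, max_size=25),
    )
    def test_u_identity(self, a, b):
        """U_a + U_b = n_a * n_b, so min(U_a, U_b) <= n_a n_b / 2."""
        res = mann_whitney_u(a, b)
        assert res.statistic <= len(a) * len(b) / 2

    def test_exact_and_asymptotic_branches_agree(self):
        """At n=15 per group the exact-enumeration p and the
        tie-corrected normal approximation differ by < 0.02."""
        rng = np.random.default_rng(8)
        worst = 0.0
        for _ in range(100):
            a, b = rng.normal(size=15), rng.normal(0.3, 1, size=15)
            exact = ss.mannwhitneyu(a, b, method="exact").pvalue
            approx = ss.mannwhitneyu(a, b, method="asymptotic").pvalue
            worst = max(worst, abs(exact - approx))
            assert mann_whitney_u(a, b).p_value == pytest.approx(exact)
        assert worst < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestKruskalWallis:
    def test_hand_ranked_instance(self):
        """Three tie-free groups of ranks {1-3},{4-6},{7-9}: the
        rank-sum formula gives H = 12/(N(N+1)) sum R_i^2/n_i - 3(N+1)
        = 7.2."""
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res.statistic == pytest.approx(7.2)
        assert res.df == (2,)

    def test_rank_invariance_within_groups(self):
        g = [[3.0, 1.0, 2.0], [6.0, 4.0, 5.0], [9.0, 7.0, 8.0]]
        assert kruskal_wallis(g).statistic == pytest.approx(7.2)

    def test_two_identical_groups(self):
        res = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert res.statistic == pytest.approx(0.0)

    def test_all_values_identical_defined_with_warning(self):
        with pytest.warns(RuntimeWarning, match="identical"):
            res = kruskal_wallis([[5.0, 5.0], [5.0, 5.0, 5.0]])
        assert res.statistic == 0.0 and res.p_value == 1.0


class TestNemenyi:
    def test_identical_groups_all_insignificant(self):
        g = [[1, 2, 3, 4, 5]] * 3
        p = nemenyi_posthoc(g)
        off = p.values[~np.eye(3, dtype=bool)]
        assert np.all(off > 0.99)

    def test_symmetry_and_unit_diagonal(self):
        rng = np.random.default_rng(2)
        g = [rng.normal(size=12), rng.normal(1, 1, size=12), rng.normal(2, 1, size=12)]
        p = nemenyi_posthoc(g)
        assert np.allclose(p.values, p.values.T)
        assert np.all(np.diag(p.values) == 1.0)

    def test_well_separated_groups_all_significant(self):
        rng = np.random.default_rng(11)
        g = [rng.normal(0, 1, 50), rng.normal(10, 1, 50), rng.normal(20, 1, 50)]
        p = nemenyi_posthoc(g)
        off = p.values[~np.eye(3, dtype=bool)]
        assert np.all(off < 0.001)

    def test_chisquare_variant_matches_hand_rank_arithmetic(self):
        """Unequal-n variant: the chi statistic is hand-computable
        from mean ranks; the p-value must be its chi-square tail."""
        g = [[1.0, 2.0], [3.0, 4.0, 5.0], [6.0, 7.0, 8.0, 9.0]]
        # mean ranks: 1.5, 4.0, 7.5; N = 9; no ties
        p = nemenyi_posthoc(g, labels=["a", "b", "c"], method="chisquare")
        n = 9
        for (i, j, ni, nj, ri, rj) in [
            (0, 1, 2, 3, 1.5, 4.0),
            (0, 2, 2, 4, 1.5, 7.5),
            (1, 2, 3, 4, 4.0, 7.5),
        ]:
            chi = (ri - rj) ** 2 / (n * (n + 1) / 12.0 * (1.0 / ni + 1.0 / nj))
            assert p.iloc[i, j] == pytest.approx(ss.chi2.sf(chi, 2))

    def test_needs_three_groups(self):
        with pytest.raises(ValueError, match="at least 3"):
            nemenyi_posthoc([[1, 2], [3, 4]])


class TestOnewayAnova:
    def test_identical_groups_f_zero(self):
        res = oneway_anova([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_separated_tight_groups(self):
        res = oneway_anova([1.0, 1.001, 0.999], [10.0, 10.001, 9.999])
        assert res.p_value < 1e-6

    def test_degenerate_equal_constant_groups_error(self):
        with pytest.raises(ValueError, match="undefined"):
            oneway_anova([2.0, 2.0], [2.0, 2.0])

    def test_null_f_near_one_in_expectation(self):
        rng = np.random.default_rng(4)
        fs = [
            oneway_anova(rng.normal(size=20), rng.normal(size=20)).statistic
            for _ in range(500)
        ]
        # E[F] = d2/(d2-2) = 38/36 under H0
        assert np.mean(fs) == pytest.approx(38 / 36, abs=0.12)


class TestTwowayInteraction:
    def test_additive_cells_no_interaction(self):
        vals, types, eras = [], [], []
        for ti, teff in enumerate([0.0, 5.0, 8.0]):
            for ei, eeff in enumerate([0.0, 3.0]):
                for rep in (0.0, 1.0):  # same within-cell pattern everywhere
                    vals.append(10.0 + teff + eeff + rep)
                    types.append(f"T{ti}")
                    eras.append(f"E{ei}")
        res = twoway_interaction(vals, types, eras)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)

    def test_shifted_cell_detected(self):
        vals, types, eras = [], [], []
        for ti in range(3):
            for ei in range(2):
                base = 10.0 + (5.0 if (ti, ei) == (2, 1) else 0.0)
                for rep in (-0.01, 0.01):
                    vals.append(base + rep)
                    types.append(f"T{ti}")
                    eras.append(f"E{ei}")
        assert twoway_interaction(vals, types, eras).p_value < 1e-8

    def test_balanced_2x2_matches_hand_model_comparison(self):
        """Cells [1,2],[3,4],[5,6],[9,10]: RSS_full = 2, additive RSS
        = 4, so F = (4-2)/1 / (2/4) = 4 with df (1, 4)."""
        vals = [1, 2, 3, 4, 5, 6, 9, 10]
        types = ["t1", "t1", "t1", "t1", "t2", "t2", "t2", "t2"]
        eras = ["e1", "e1", "e2", "e2", "e1", "e1", "e2", "e2"]
        res = twoway_interaction(vals, types, eras)
        assert res.statistic == pytest.approx(4.0)
        assert res.df == (1, 4)
        assert res.p_value == pytest.approx(ss.f.sf(4.0, 1, 4))

    def test_unbalanced_matches_statsmodels(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        import pandas as pd

        rng = np.random.default_rng(17)
        n_per = {("t_b", "a"): 87, ("t_b", "b"): 40, ("t_a", "a"): 84,
                 ("t_a", "b"): 40, ("t_s", "a"): 83, ("t_s", "b"): 40}
        rows = []
        for (ty, er), n in n_per.items():
            rows += [
                {"y": rng.normal(loc=hash((ty, er)) % 5, scale=2), "ty": ty, "er": er}
                for _ in range(n)
            ]
        df = pd.DataFrame(rows)
        res = twoway_interaction(df["y"], df["ty"], df["er"])
        full = smf.ols("y ~ C(ty) * C(er)", df).fit()
        red = smf.ols("y ~ C(ty) + C(er)", df).fit()
        f_sm, p_sm, df_sm = full.compare_f_test(red)
        assert res.statistic == pytest.approx(f_sm, rel=1e-8)
        assert res.p_value == pytest.approx(p_sm, rel=1e-8)

    def test_empty_cell_named_in_error(self):
        with pytest.raises(ValueError, match="t_a.*late"):
            twoway_interaction(
                [1.0, 2.0, 3.0],
                ["t_a", "t_b", "t_b"],
                ["early", "early", "late"],
            )


class TestLinearRegression:
    def test_exact_line(self):
        x = np.arange(10.0)
        fit = linear_regression(x, 2 + 3 * x)
        assert fit.slope == pytest.approx(3.0)
        assert fit.intercept == pytest.approx(2.0)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-10)

    def test_closed_form_small_instance(self):
        # Sxy = 3, Sxx = 2 -> slope 1.5; R^2 = 4.5/(42/9) = 27/28
        fit = linear_regression([0, 1, 2], [0, 2, 3])
        assert fit.slope == pytest.approx(1.5)
        assert fit.intercept == pytest.approx(1 / 6)
        assert fit.r_squared == pytest.approx(27 / 28, abs=1e-6)

    def test_independent_noise_r2_near_zero(self):
        rng = np.random.default_rng(21)
        x = rng.normal(size=5000)
        fit = linear_regression(x, rng.normal(size=5000))
        assert fit.r_squared < 0.01

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            linear_regression([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestAncovaSlopeHomogeneity:
    def test_same_line_both_groups(self):
        x = np.arange(6.0)
        y = 1.0 + 0.5 * x
        res = ancova_slope_homogeneity(
            np.concatenate([x, x]), np.concatenate([y, y]),
            ["a"] * 6 + ["b"] * 6,
        )
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)

    def test_opposite_slopes_detected(self):
        x = np.arange(6.0)
        res = ancova_slope_homogeneity(
            np.concatenate([x, x]),
            np.concatenate([0.55 * x, -0.55 * x + 0.001 * np.arange(6) ** 2]),
            ["a"] * 6 + ["b"] * 6,
        )
        assert res.p_value < 1e-6

    def test_tiny_instance_matches_hand_sse_comparison(self):
        """g1: y=[0,1,1], g2: y=[2,2,4] on x=[0,1,2]: separate-slopes
        RSS = 5/6, common-slope RSS = 13/12, F = (1/4)/(5/12) = 0.6
        with df (1, 2)."""
        res = ancova_slope_homogeneity(
            [0, 1, 2, 0, 1, 2], [0, 1, 1, 2, 2, 4], ["a"] * 3 + ["b"] * 3
        )
        assert res.statistic == pytest.approx(0.6)
        assert res.df == (1, 2)
        assert res.p_value == pytest.approx(ss.f.sf(0.6, 1, 2))

    def test_matches_statsmodels(self):
        import pandas as pd
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(9)
        df = pd.DataFrame({
            "x": rng.normal(size=60),
            "g": ["a"] * 35 + ["b"] * 25,
        })
        df["y"] = 0.5 * df.x + np.where(df.g == "b", 0.3 * df.x, 0) + rng.normal(size=60)
        res = ancova_slope_homogeneity(df.x, df.y, df.g)
        full = smf.ols("y ~ x * C(g)", df).fit()
        red = smf.ols("y ~ x + C(g)", df).fit()
        f_sm, p_sm, _ = full.compare_f_test(red)
        assert res.statistic == pytest.approx(f_sm, rel=1e-8)
        assert res.p_value == pytest.approx(p_sm, rel=1e-8)

    def test_constant_x_group_rejected(self):
        with pytest.raises(ValueError, match="constant x"):
            ancova_slope_homogeneity(
                [1, 1, 1, 0, 1, 2], [1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3
            )


def test_kruskal_and_anova_agree_on_group_ordering():
    """On well-separated fixtures both tests point the same way: the
    same omnibus rejection and the same ranking of group centres."""
    rng = np.random.default_rng(33)
    g = [rng.normal(m, 1.0, size=30) for m in (0.0, 3.0, 6.0)]
    kw = kruskal_wallis(g)
    an = oneway_anova(*g)
    assert kw.p_value < 0.001 and an.p_value < 0.001
    means = [np.mean(x) for x in g]
    mean_ranks = [
        np.mean(ss.rankdata(np.concatenate(g))[i * 30:(i + 1) * 30]) for i in range(3)
    ]
    assert np.argsort(means).tolist() == np.argsort(mean_ranks).tolist()
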