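"""Sequential ANOVA, MANOVA, phylogenetic ANOVA, regressions and rank tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from morphoflight import simulate
from morphoflight.stats import (
    linear_regression,
    manova_wilks,
    pearson_correlation,
    percent_difference,
    phylogenetic_anova,
    sequential_anova,
    tree_vcv,
    wilcoxon_rank_sum,
)

STAR_TREE = "(a:1,b:1,c:1,d:1,e:1,f:1,g:1);"


def _two_group_frame(rng, n=100, delta=1.0):
    y = np.concatenate([rng.normal(0.0, 1.0, n), rng.normal(delta, 1.0, n)])
    g = ["a"] * n + ["b"] * n
    return pd.DataFrame({"y": y, "group": g})


class TestSequentialAnova:
    def test_two_group_f_equals_t_squared(self, rng):
        df = _two_group_frame(rng)
        tab = sequential_anova(df, "y", ["group"]).table
        t, _ = sps.ttest_ind(df[df.group == "a"].y, df[df.group == "b"].y)
        assert tab.loc["group", "F"] == pytest.approx(t**2, rel=1e-9)

    def test_constant_response_degenerate(self, rng):
        df = _two_group_frame(rng)
        df["y"] = 5.0
        tab = sequential_anova(df, "y", ["group"]).table
        assert tab.loc["group", "F"] == 0.0
        assert tab.loc["group", "p"] == 1.0

    def test_ss_decomposition_sums_to_total(self, rng):
        cohort = simulate.generate_cohort(simulate.CohortDesign(seed=3))
        wb = cohort.wingbeats
        res = sequential_anova(
            wb, "gamma_climb",
            ["microhabitat", "species", "individual", "flight", "wingbeat_index"],
        )
        total = np.sum((wb.gamma_climb - wb.gamma_climb.mean()) ** 2)
        assert res.total_ss == pytest.approx(total, rel=1e-9)

    def test_matches_statsmodels_type1(self, rng):
        """Cross-check the sequential decomposition against statsmodels."""
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        n = 40
        df = pd.DataFrame(
            {
                "y": rng.normal(size=n),
                "f1": rng.choice(["u", "v"], n),
                "f2": rng.choice(["p", "q", "r"], n),
            }
        )
        mine = sequential_anova(df, "y", ["f1", "f2"]).table
        model = ols("y ~ C(f1) + C(f2)", data=df).fit()
        ref = sm.stats.anova_lm(model, typ=1)
        assert mine.loc["f1", "ss"] == pytest.approx(ref.loc["C(f1)", "sum_sq"], rel=1e-9)
        assert mine.loc["f2", "ss"] == pytest.approx(ref.loc["C(f2)", "sum_sq"], rel=1e-9)
        assert mine.loc["f1", "F"] == pytest.approx(ref.loc["C(f1)", "F"], rel=1e-9)

    def test_confounded_factor_rejected(self, rng):
        df = _two_group_frame(rng, n=5)
        df["dup"] = df["group"]
        with pytest.raises(ValueError, match="confounded"):
            sequential_anova(df, "y", ["group", "dup"])


class TestManovaWilks:
    def test_null_lambda_near_one(self, rng):
        n = 4000
        df = pd.DataFrame(
            {
                "y1": rng.normal(size=n),
                "y2": rng.normal(size=n),
                "group": rng.choice(["a", "b"], n),
            }
        )
        lam, _, p = manova_wilks(df, ["y1", "y2"], "group")
        assert lam > 0.995
        assert p > 0.01

    def test_one_response_matches_anova_identity(self, rng):
        df = _two_group_frame(rng, n=30)
        lam, F, _ = manova_wilks(df, ["y"], "group")
        tab = sequential_anova(df, "y", ["group"]).table
        F1 = tab.loc["group", "F"]
        df1, df2 = 1, len(df) - 2
        assert lam == pytest.approx(1.0 / (1.0 + F1 * df1 / df2), rel=1e-9)

    def test_hand_computed_fixture(self):
        """Tiny integer fixture checked against the determinant ratio."""
        df = pd.DataFrame(
            {
                "y1": [1.0, 2.0, 3.0, 5.0, 6.0, 7.0],
                "y2": [2.0, 1.0, 3.0, 4.0, 6.0, 5.0],
                "group": ["a", "a", "a", "b", "b", "b"],
            }
        )
        Y = df[["y1", "y2"]].to_numpy()
        W = np.zeros((2, 2))
        B = np.zeros((2, 2))
        grand = Y.mean(axis=0)
        for g in ("a", "b"):
            Yg = Y[(df.group == g).to_numpy()]
            W += (Yg - Yg.mean(0)).T @ (Yg - Yg.mean(0))
            B += 3 * np.outer(Yg.mean(0) - grand, Yg.mean(0) - grand)
        expected = np.linalg.det(W) / np.linalg.det(W + B)
        lam, _, _ = manova_wilks(df, ["y1", "y2"], "group")
        assert lam == pytest.approx(expected, rel=1e-12)

    def test_equal_group_means_lambda_one(self):
        df = pd.DataFrame(
            {
                "y1": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
                "y2": [2.0, 1.0, 3.0, 2.0, 1.0, 3.0],
                "group": ["a", "a", "a", "b", "b", "b"],
            }
        )
        lam, _, _ = manova_wilks(df, ["y1", "y2"], "group")
        assert lam == pytest.approx(1.0, rel=1e-12)


class TestPhylogeneticAnova:
    GROUPS = ["g1", "g1", "g1", "g2", "g2", "g2", "g2"]

    def test_star_tree_matches_standard_anova(self):
        """On a star phylogeny the simulated null is the classical one."""
        diffs = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            x = r.normal(0.0, 1.0, 7)
            res = phylogenetic_anova(x, self.GROUPS, STAR_TREE, n_sim=2000, seed=seed)
            diffs.append(res.p_phylo - res.p_standard)
        assert np.max(np.abs(diffs)) < 0.05
        assert abs(np.mean(diffs)) < 0.02

    def test_clade_segregated_groups_lose_significance(self):
        """Groups that follow deep clades on a long-stemmed tree are easy to
        produce by drift, so the phylogenetic p is much larger than the
        naive one."""
        tree = "((a:0.1,b:0.1,c:0.1):4.0,(d:0.1,e:0.1,f:0.1,g:0.1):4.0);"
        ratio = []
        for seed in range(10):
            r = np.random.default_rng(100 + seed)
            x = np.concatenate([r.normal(0, 0.1, 3), r.normal(2.0, 0.1, 4)])
            res = phylogenetic_anova(x, self.GROUPS, tree,
                                     species=list("abcdefg"), n_sim=1000, seed=seed)
            ratio.append(res.p_phylo / max(res.p_standard, 1e-12))
        assert np.median(ratio) > 10.0

    def test_unmatched_tips_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            phylogenetic_anova(np.zeros(7), self.GROUPS, STAR_TREE,
                               species=["nope"] * 7, n_sim=100)

    def test_small_n_sim_rejected(self):
        with pytest.raises(ValueError, match="n_sim"):
            phylogenetic_anova(np.zeros(7), self.GROUPS, STAR_TREE, n_sim=50)

    def test_reproducible_from_seed(self):
        x = np.arange(7.0)
        a = phylogenetic_anova(x, self.GROUPS, STAR_TREE, n_sim=500, seed=42)
        b = phylogenetic_anova(x, self.GROUPS, STAR_TREE, n_sim=500, seed=42)
        assert a.p_phylo == b.p_phylo
        assert np.array_equal(a.f_null, b.f_null)

    def test_vcv_depths_and_shared_paths(self):
        tree = "((a:1,b:1):1,c:2);"
        import dendropy

        C = tree_vcv(dendropy.Tree.get(data=tree, schema="newick"), ["a", "b", "c"])
        assert C[0, 0] == pytest.approx(2.0)
        assert C[0, 1] == pytest.approx(1.0)
        assert C[0, 2] == pytest.approx(0.0)


class TestRegressionAndCorrelation:
    def test_exact_line(self):
        x = np.arange(10.0)
        fit = linear_regression(x, 2.0 * x + 1.0)
        assert fit.slope == pytest.approx(2.0, rel=1e-12)
        assert fit.intercept == pytest.approx(1.0, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0, rel=1e-12)

    def test_five_point_fixture_normal_equations(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        # brute-force normal equations
        sl = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        ic = y.mean() - sl * x.mean()
        r2 = 1.0 - np.sum((y - ic - sl * x) ** 2) / np.sum((y - y.mean()) ** 2)
        fit = linear_regression(x, y)
        assert fit.slope == pytest.approx(sl, rel=1e-12)
        assert fit.intercept == pytest.approx(ic, rel=1e-12)
        assert fit.r_squared == pytest.approx(r2, rel=1e-12)

    def test_r_squared_equals_squared_pearson(self, rng):
        x = rng.normal(size=50)
        y = 0.5 * x + rng.normal(size=50)
        fit = linear_regression(x, y)
        r, _ = pearson_correlation(x, y)
        assert fit.r_squared == pytest.approx(r**2, rel=1e-12)

    def test_configured_r2_recovered_at_n120(self):
        x, y = simulate.generate_regression_sample(
            n=120, slope=0.5, intercept=0.2, x_mean=2.5, x_sd=0.6,
            r_squared=0.94, seed=11,
        )
        fit = linear_regression(x, y)
        assert fit.r_squared == pytest.approx(0.94, abs=0.05)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            linear_regression(np.ones(10), np.arange(10.0))

    def test_pearson_identity_and_fixture(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        r, _ = pearson_correlation(x, x)
        assert r == pytest.approx(1.0, rel=1e-12)
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        r, _ = pearson_correlation(x, y)
        assert r == pytest.approx(num / den, rel=1e-12)

    def test_pearson_orthogonal_zero(self):
        x = np.array([1.0, 1.0, -1.0, -1.0])
        y = np.array([1.0, -1.0, 1.0, -1.0])
        with pytest.raises(ValueError):
            pearson_correlation(x[:2], y[:2])
        r, _ = pearson_correlation(x, y)
        assert r == pytest.approx(0.0, abs=1e-12)


class TestWilcoxonRankSum:
    def test_extreme_ranking_exact_p(self):
        W, p = wilcoxon_rank_sum([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert W == 6.0  # ranks 1+2+3
        assert p == pytest.approx(0.1, rel=1e-9)  # 2/20 orderings as extreme

    def test_identical_groups_p_one(self):
        _, p = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_power_increases_with_shift(self):
        rng = np.random.default_rng(0)
        rejections = []
        for shift in (0.2, 0.6, 1.2):
            rej = 0
            for _ in range(200):
                a = rng.normal(0.0, 1.0, 30)
                b = rng.normal(shift, 1.0, 30)
                _, p = wilcoxon_rank_sum(a, b)
                rej += p < 0.05
            rejections.append(rej)
        assert rejections[0] < rejections[1] < rejections[2]

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestPercentDifference:
    @pytest.mark.parametrize(
        "a, b, ndigits, expected",
        [
            (46.7, 36.5, 0, 28.0),
            (1.56, 1.32, 1, 18.2),
            (1.07, 0.72, 0, 49.0),
            (1.55, 1.24, 0, 25.0),
            (3.3, 3.3, 0, 0.0),
        ],
    )
    def test_group_contrasts(self, a, b, ndigits, expected):
        assert percent_difference(a, b, ndigits=ndigits) == expected

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            percent_difference(1.0, 0.0)
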