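import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from traitplast.stats import (coefficient_of_variation, compact_letter_display,
                              oneway_anova, pearson_correlation, site_summary,
                              tukey_hsd, twoway_anova_site_variety,
                              variance_components)

from conftest import make_table, small_config
from traitplast.simulate import simulate_trait_table


class TestCoefficientOfVariation:
    def test_hand_example(self):
        assert coefficient_of_variation([1.0, 2.0, 3.0]) == pytest.approx(50.0)

    def test_constant_vector_is_zero(self):
        assert coefficient_of_variation([4.0, 4.0, 4.0]) == 0.0

    @settings(derandomize=True, max_examples=40)
    @given(c=st.floats(0.1, 100.0))
    def test_scale_invariance(self, c):
        x = np.array([1.0, 2.5, 3.0, 4.5])
        assert coefficient_of_variation(c * x) == \
            pytest.approx(coefficient_of_variation(x), rel=1e-10)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            coefficient_of_variation([1.0])
        with pytest.raises(ValueError):
            coefficient_of_variation([-1.0, 1.0])


class TestOnewayAnova:
    def test_hand_closed_form(self):
        out = oneway_anova([1.0, 2.0, 3.0, 4.0], ["g1", "g1", "g2", "g2"])
        assert out.loc["group", "sum_sq"] == pytest.approx(4.0)
        assert out.loc["Residual", "sum_sq"] == pytest.approx(1.0)
        assert out.loc["group", "F"] == pytest.approx(8.0)
        assert (out["df"].tolist() == [1, 2])

    def test_identical_group_means_give_zero_f(self):
        out = oneway_anova([1.0, 3.0, 1.0, 3.0], ["a", "a", "b", "b"])
        assert out.loc["group", "sum_sq"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc["group", "F"] == pytest.approx(0.0, abs=1e-12)

    def test_projection_matrix_oracle(self, rng):
        """SS from the hat-matrix projection on 100 random small datasets."""
        for _ in range(100):
            k = rng.integers(2, 5)
            ni = rng.integers(2, 6, size=k)
            y = rng.normal(size=ni.sum())
            g = np.repeat([f"g{i}" for i in range(k)], ni)
            out = oneway_anova(y, g)
            X = np.column_stack([(g == lab).astype(float) for lab in np.unique(g)])
            H = X @ np.linalg.pinv(X)
            fitted = H @ y
            ssb = np.sum((fitted - y.mean()) ** 2)
            ssw = np.sum((y - fitted) ** 2)
            assert out.loc["group", "sum_sq"] == pytest.approx(ssb, rel=1e-10)
            assert out.loc["Residual", "sum_sq"] == pytest.approx(ssw, rel=1e-10)
            f_ref, p_ref = sps.f_oneway(*[y[g == lab] for lab in np.unique(g)])
            assert out.loc["group", "F"] == pytest.approx(f_ref, rel=1e-10)
            assert out.loc["group", "p"] == pytest.approx(p_ref, rel=1e-8)

    def test_decomposition_exact(self, rng):
        y = rng.normal(size=30)
        g = rng.choice(["a", "b", "c"], size=30)
        out = oneway_anova(y, g)
        total = np.sum((y - y.mean()) ** 2)
        assert out["sum_sq"].sum() == pytest.approx(total, rel=1e-10)
        assert out["df"].sum() == len(y) - 1

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            oneway_anova([1.0, 2.0], ["a", "a"])


class TestTwowayAnova:
    @staticmethod
    def _table(rng, n_varieties=5, balanced=True):
        rows = []
        for site in ["A", "B"]:
            for v in range(n_varieties):
                n = 3 if balanced else int(rng.integers(2, 4))
                for t in range(n):
                    rows.append({"site": site, "variety": f"v{v}",
                                 "tree": f"t{t}",
                                 "LMA": float(rng.normal(250, 20))})
        return make_table(pd.DataFrame(rows))

    def test_balanced_components_sum_to_total(self, rng):
        table = self._table(rng, balanced=True)
        out = twoway_anova_site_variety(table, "LMA")
        assert out["sum_sq"].sum() == pytest.approx(out.attrs["total_ss"], rel=1e-10)

    def test_pure_additive_data_has_zero_interaction(self):
        rows = []
        site_eff = {"A": 0.0, "B": 7.0}
        var_eff = {f"v{i}": 3.0 * i for i in range(4)}
        for site in ["A", "B"]:
            for v, ve in var_eff.items():
                for t, tweak in enumerate([0.0, 1.0]):
                    rows.append({"site": site, "variety": v, "tree": f"t{t}",
                                 "LMA": 200.0 + site_eff[site] + ve + tweak})
        out = twoway_anova_site_variety(make_table(pd.DataFrame(rows)), "LMA")
        assert out.loc["site:variety", "sum_sq"] == pytest.approx(0.0, abs=1e-10)

    def test_type_ii_least_squares_oracle(self, rng):
        """Full-vs-reduced RSS comparisons via statsmodels on unbalanced data."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm
        for _ in range(20):
            table = self._table(rng, n_varieties=4, balanced=False)
            ours = twoway_anova_site_variety(table, "LMA")
            df = table.data.rename(columns={"LMA": "y"})
            fit = smf.ols("y ~ C(site) * C(variety)", data=df).fit()
            ref = anova_lm(fit, typ=2)
            assert ours.loc["site", "sum_sq"] == \
                pytest.approx(ref.loc["C(site)", "sum_sq"], rel=1e-8)
            assert ours.loc["variety", "sum_sq"] == \
                pytest.approx(ref.loc["C(variety)", "sum_sq"], rel=1e-8)
            assert ours.loc["site:variety", "sum_sq"] == \
                pytest.approx(ref.loc["C(site):C(variety)", "sum_sq"], rel=1e-8)
            assert ours.loc["Residual", "sum_sq"] == \
                pytest.approx(ref.loc["Residual", "sum_sq"], rel=1e-8)
            assert ours.loc["site:variety", "p"] == \
                pytest.approx(ref.loc["C(site):C(variety)", "PR(>F)"], rel=1e-6)

    def test_variety_missing_at_one_site_rejected(self, rng):
        table = self._table(rng)
        df = table.data[~((table.data["site"] == "B")
                          & (table.data["variety"] == "v0"))]
        with pytest.raises(ValueError, match="missing at one site"):
            twoway_anova_site_variety(make_table(df), "LMA")


class TestVarianceComponents:
    def test_pure_site_effect_is_all_plasticity(self):
        cfg = small_config(traits=("LMA",), fractions=(0.0, 1.0, 0.0, 0.0),
                           n_distinct_per_site=0, trees_per_variety=2, seed=3)
        table, _ = simulate_trait_table(cfg)
        part = variance_components(table, table, "LMA")
        assert part.plasticity_pct == pytest.approx(100.0, abs=1e-6)
        assert part.genetic_pct == pytest.approx(0.0, abs=1e-6)

    def test_pure_genetic_effect_is_all_genetic(self):
        cfg = small_config(traits=("LMA",), fractions=(1.0, 0.0, 0.0, 0.0),
                           n_distinct_per_site=0, trees_per_variety=2, seed=3)
        table, _ = simulate_trait_table(cfg)
        part = variance_components(table, table, "LMA")
        assert part.genetic_pct == pytest.approx(100.0, abs=1e-6)
        assert part.plasticity_pct == pytest.approx(0.0, abs=1e-6)
        assert part.residual_pct == pytest.approx(0.0, abs=1e-6)


class TestTukeyHSD:
    def test_two_groups_reduce_to_t_test(self, rng):
        y = np.concatenate([rng.normal(0, 1, 8), rng.normal(0.8, 1, 6)])
        g = np.array(["a"] * 8 + ["b"] * 6)
        out = tukey_hsd(y, g)
        t_ref, p_ref = sps.ttest_ind(y[g == "a"], y[g == "b"], equal_var=True)
        assert out["p_adj"].iloc[0] == pytest.approx(p_ref, rel=1e-6)

    def test_identical_groups_give_p_one(self):
        y = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        g = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        out = tukey_hsd(y, g)
        assert (out["p_adj"] > 0.999).all()

    def test_adjusted_p_at_least_unadjusted_t(self, rng):
        y = rng.normal(size=24)
        g = np.repeat(["a", "b", "c", "d"], 6)
        out = tukey_hsd(y, g)
        for row in out.itertuples():
            _, p_t = sps.ttest_ind(y[g == row.group1], y[g == row.group2],
                                   equal_var=True)
            assert row.p_adj >= p_t - 1e-12

    def test_against_statsmodels(self, rng):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        y = rng.normal(size=30)
        g = rng.choice(["a", "b", "c"], size=30)
        ours = tukey_hsd(y, g)
        ref = pairwise_tukeyhsd(y, g)
        ref_p = np.asarray(ref.pvalues)
        np.testing.assert_allclose(ours["p_adj"].to_numpy(), ref_p, atol=1e-6)

    def test_studentized_range_cdf_against_monte_carlo(self, rng):
        """q CDF (k=4, df=20) vs simulation, 1e6 draws, within 0.003."""
        k, df = 4, 20
        z = rng.normal(size=(10 ** 6, k))
        rng_range = z.max(axis=1) - z.min(axis=1)
        s = np.sqrt(rng.chisquare(df, size=10 ** 6) / df)
        q_draws = rng_range / s
        for q in (2.0, 3.0, 4.0):
            mc = (q_draws <= q).mean()
            exact = sps.studentized_range.cdf(q, k, df)
            assert abs(mc - exact) < 0.003


class TestCompactLetterDisplay:
    @staticmethod
    def _comparisons(groups, sig_pairs, means=None):
        rows = []
        for g1, g2 in itertools.combinations(sorted(groups), 2):
            sig = frozenset((g1, g2)) in sig_pairs
            rows.append((g1, g2, 0.0, 0.01 if sig else 0.5, sig))
        out = pd.DataFrame(rows, columns=["group1", "group2", "mean_diff",
                                          "p_adj", "significant"])
        out.attrs["group_means"] = means or {g: -i for i, g in enumerate(sorted(groups))}
        return out

    def test_no_significant_pairs_single_letter(self):
        letters = compact_letter_display(self._comparisons("abc", set()))
        assert set(letters.values()) == {"a"}

    def test_all_significant_distinct_letters(self):
        sig = {frozenset(p) for p in itertools.combinations("abc", 2)}
        letters = compact_letter_display(self._comparisons("abc", sig))
        assert sorted(letters.values()) == ["a", "b", "c"]

    def test_chain_pattern(self):
        # A~B, B~C, A!=C -> a, ab, b
        letters = compact_letter_display(
            self._comparisons("ABC", {frozenset(("A", "C"))},
                              means={"A": 3.0, "B": 2.0, "C": 1.0}))
        assert letters == {"A": "a", "B": "ab", "C": "b"}

    @settings(derandomize=True, max_examples=80)
    @given(st.integers(2, 6), st.integers(0, 2 ** 15 - 1))
    def test_consistency_brute_force(self, k, pattern_seed):
        """Letter sharing <-> non-significance, for random patterns, k <= 6."""
        groups = [f"g{i}" for i in range(k)]
        pairs = list(itertools.combinations(groups, 2))
        rng = np.random.default_rng(pattern_seed)
        sig = {frozenset(p) for p in pairs if rng.random() < 0.4}
        letters = compact_letter_display(self._comparisons(groups, sig))
        for g1, g2 in pairs:
            share = bool(set(letters[g1]) & set(letters[g2]))
            assert share == (frozenset((g1, g2)) not in sig)


class TestPearson:
    def test_perfect_linear(self):
        r, p = pearson_correlation([1, 2, 3, 4], [3, 5, 7, 9])
        assert r == pytest.approx(1.0)
        r, _ = pearson_correlation([1, 2, 3, 4], [-1, -2, -3, -4])
        assert r == pytest.approx(-1.0)

    def test_hand_example(self):
        r, p = pearson_correlation([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8)

    def test_against_scipy(self, rng):
        for _ in range(25):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            r, p = pearson_correlation(x, y)
            ref = sps.pearsonr(x, y)
            assert r == pytest.approx(ref.statistic, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-8)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1, 1, 1], [1, 2, 3])


class TestSiteSummary:
    def test_single_tree_sd_missing(self):
        df = pd.DataFrame({"site": ["A"], "variety": ["v"], "tree": ["t"],
                           "LMA": [250.0]})
        out = site_summary(make_table(df), "LMA")
        assert out["mean"].iloc[0] == 250.0 and np.isnan(out["sd"].iloc[0])

    def test_two_equal_sites_identical_rows(self):
        df = pd.DataFrame({"site": ["A", "A", "B", "B"],
                           "variety": ["v"] * 4, "tree": ["t1", "t2"] * 2,
                           "LMA": [240.0, 260.0, 240.0, 260.0]})
        out = site_summary(make_table(df), "LMA")
        assert out.iloc[0][["mean", "sd", "n"]].tolist() == \
            out.iloc[1][["mean", "sd", "n"]].tolist()

    def test_unknown_trait(self, toy_table):
        with pytest.raises(KeyError):
            site_summary(toy_table, "XXX")
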