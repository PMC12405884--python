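"""Category statistics: chi-square, rank-sum, median scaled curves."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from rbpcompendium.io import ExpressionMatrix
from rbpcompendium.stats import (
    chi_square_2x2,
    compare_half_life_distributions,
    flag_proportions_by_category,
    median_scaled_expression,
    rank_sum_test,
)


def hand_chi2(table):
    """Closed-form sum (O-E)^2/E oracle."""
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    total = table.sum()
    expected = np.outer(row, col) / total
    return ((table - expected) ** 2 / expected).sum()


class TestChiSquare:
    def test_identical_proportions_give_zero(self):
        stat, p = chi_square_2x2([[40, 60], [40, 60]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_oracle(self):
        stat, p = chi_square_2x2([[30, 70], [10, 90]])
        assert stat == pytest.approx(hand_chi2([[30, 70], [10, 90]]), abs=1e-10)
        assert p == pytest.approx(sps.chi2.sf(stat, df=1))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(cells=st.tuples(*[st.integers(1, 500)] * 4))
    def test_random_tables_match_oracle_and_z_squared(self, cells):
        a, b, c, d = cells
        stat, _ = chi_square_2x2([[a, b], [c, d]])
        assert stat == pytest.approx(hand_chi2([[a, b], [c, d]]), abs=1e-10)
        # identity with the square of the two-proportion z statistic
        n1, n2 = a + b, c + d
        p1, p2, pp = a / n1, c / n2, (a + c) / (n1 + n2)
        if 0 < pp < 1:
            z = (p1 - p2) / np.sqrt(pp * (1 - pp) * (1 / n1 + 1 / n2))
            assert stat == pytest.approx(z**2, rel=1e-9)

    def test_zero_expected_count_is_undefined(self):
        stat, p = chi_square_2x2([[0, 10], [0, 20]])
        assert np.isnan(stat) and np.isnan(p)


class TestRankSum:
    def test_identical_samples_give_p_one(self):
        _, p = rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_fully_separated_small_samples(self):
        _, p = rank_sum_test([1, 2, 3], [4, 5, 6])
        # 2 of the C(6,3)=20 assignments are as extreme
        assert p == pytest.approx(0.1)

    @pytest.mark.parametrize("n1, n2", [(2, 3), (3, 3), (4, 4), (5, 5), (3, 7)])
    def test_exact_path_matches_scipy_exact_without_ties(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        x, y = rng.normal(size=n1), rng.normal(1.0, size=n2)
        _, p = rank_sum_test(x, y)
        expected = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert p == pytest.approx(expected, abs=1e-12)

    def test_exact_path_with_ties_matches_enumeration(self):
        x, y = [1.0, 2.0, 2.0], [2.0, 3.0, 4.0]
        w, p = rank_sum_test(x, y)
        ranks = sps.rankdata(np.concatenate([x, y]))
        mean = ranks.sum() * len(x) / len(ranks)
        sums = [sum(c) for c in itertools.combinations(ranks, len(x))]
        expected = np.mean([abs(s - mean) >= abs(w - mean) - 1e-9 for s in sums])
        assert p == pytest.approx(expected)

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=40), rng.normal(0.8, size=40)
        _, p = rank_sum_test(x, y)
        expected = sps.ranksums(x, y).pvalue
        assert p == pytest.approx(expected, rel=1e-6)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            rank_sum_test([], [1.0])


class TestFlagProportions:
    def make_inputs(self):
        genes = [f"G{i}" for i in range(200)]
        categories = pd.Series(
            ["group1"] * 50 + ["tf"] * 50 + ["other"] * 100,
            index=pd.Index(genes, name="gene_id"),
        )
        flagged = genes[:30] + genes[50:60]  # 30/50 group1, 10/50 tf, 0/100 other
        flags = pd.DataFrame(
            {"gene_id": flagged, "flag_name": "embryonic_lethal", "value": True}
        )
        return categories, flags

    def test_proportions_and_chi2_vs_all_gene_background(self):
        categories, flags = self.make_inputs()
        out = flag_proportions_by_category(categories, flags).set_index("category")
        assert out.loc["group1", "n_genes"] == 50
        assert out.loc["group1", "proportion"] == pytest.approx(0.6)
        assert out.loc["other", "proportion"] == 0.0
        # background = all 200 genes, 40 flagged
        expected = hand_chi2([[30, 20], [40, 160]])
        assert out.loc["group1", "chi2_statistic"] == pytest.approx(expected, abs=1e-10)
        assert out.loc["group1", "p_value"] < 0.001

    def test_invariant_to_gene_order_and_duplicate_flags(self):
        categories, flags = self.make_inputs()
        base = flag_proportions_by_category(categories, flags)
        shuffled = categories.sample(frac=1, random_state=0)
        doubled = pd.concat([flags, flags], ignore_index=True)
        again = flag_proportions_by_category(shuffled, doubled)
        merged = base.merge(again, on=["category", "flag_name"], suffixes=("_a", "_b"))
        assert np.allclose(merged["proportion_a"], merged["proportion_b"])
        assert np.allclose(merged["chi2_statistic_a"], merged["chi2_statistic_b"])


class TestHalfLifeComparisons:
    def test_medians_and_pairwise_p(self):
        categories = pd.Series(
            ["a"] * 3 + ["b"] * 3,
            index=pd.Index([f"G{i}" for i in range(6)], name="gene_id"),
        )
        hl = pd.DataFrame({"gene_id": [f"G{i}" for i in range(6)],
                           "half_life": [10.0, 20.0, 30.0, 40.0, 50.0, 60.0]})
        out = compare_half_life_distributions(categories, hl).set_index("group_label")
        assert out.loc["a", "median_half_life"] == pytest.approx(20.0)
        assert out.loc["b", "median_half_life"] == pytest.approx(50.0)
        assert out.loc["a", "pairwise_p"]["b"] == pytest.approx(0.1)
        assert out.loc["a", "n_genes"] == 3

    def test_unmeasured_category_excluded(self):
        categories = pd.Series(
            ["a", "a", "b", "b", "c"],
            index=pd.Index([f"G{i}" for i in range(5)], name="gene_id"),
        )
        hl = pd.DataFrame({"gene_id": ["G0", "G1", "G2", "G3"],
                           "half_life": [10.0, 20.0, 30.0, 40.0]})
        out = compare_half_life_distributions(categories, hl)
        assert sorted(out["group_label"]) == ["a", "b"]


class TestMedianScaledExpression:
    def make_expr(self, rows, index):
        values = pd.DataFrame(
            np.asarray(rows, dtype=float),
            index=pd.Index(index, name="gene_id"),
            columns=[f"t{j}" for j in range(np.asarray(rows).shape[1])],
        )
        return ExpressionMatrix(values=values, unit="TPM", condition_kind="time_point")

    def test_identical_profiles_reduce_to_one_standardized_profile(self):
        expr = self.make_expr([[1, 2, 3], [1, 2, 3], [1, 2, 3]], ["G0", "G1", "G2"])
        out = median_scaled_expression({"s": ["G0", "G1", "G2"]}, expr)
        z = (np.array([1, 2, 3]) - 2.0) / 1.0  # sd with ddof=1 is 1.0
        assert np.allclose(out.loc["s"], z)

    def test_mirror_profiles_cancel_to_zero(self):
        expr = self.make_expr([[1, 2, 3], [3, 2, 1]], ["G0", "G1"])
        out = median_scaled_expression({"s": ["G0", "G1"]}, expr)
        assert np.allclose(out.loc["s"], 0.0)

    def test_matches_per_column_median_oracle(self):
        rng = np.random.default_rng(0)
        rows = rng.uniform(0, 100, size=(5, 6))
        genes = [f"G{i}" for i in range(5)]
        expr = self.make_expr(rows, genes)
        out = median_scaled_expression({"s": genes}, expr)
        z = (rows - rows.mean(axis=1, keepdims=True)) / rows.std(axis=1, ddof=1, keepdims=True)
        assert np.allclose(out.loc["s"], np.median(z, axis=0))

    def test_small_sets_skipped(self):
        expr = self.make_expr([[1, 2, 3]], ["G0"])
        out = median_scaled_expression({"s": ["G0"], "t": []}, expr)
        assert len(out) == 0
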