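"""Expression analytics: Tau, markers, clustering, trends, maternal calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from rbpcompendium.io import ExpressionMatrix
from rbpcompendium.profiles import (
    MarkerCaller,
    MaternalClassifier,
    PseudotimeTrendClassifier,
    TauTransformer,
    TemporalProfileClusterer,
    classify_maternal_zygotic,
    classify_pseudotime_trend,
    cluster_temporal_profiles,
    compute_tau,
    prep_heatmap_matrix,
)


def matrix(rows, index=None, columns=None, unit="TPM", kind="cell_type"):
    arr = np.asarray(rows, dtype=float)
    values = pd.DataFrame(
        arr,
        index=pd.Index(index or [f"G{i}" for i in range(arr.shape[0])], name="gene_id"),
        columns=columns or [f"c{j}" for j in range(arr.shape[1])],
    )
    return ExpressionMatrix(values=values, unit=unit, condition_kind=kind)


# ---------------------------------------------------------------------------
# Tau
# ---------------------------------------------------------------------------

def brute_force_tau(x):
    """Direct formula evaluation, scalar loop."""
    x = np.asarray(x, dtype=float)
    if x.max() == 0:
        return np.nan
    return sum(1 - xi / x.max() for xi in x) / (len(x) - 1)


class TestTau:
    @pytest.mark.parametrize(
        "vector, expected",
        [([5, 5, 5, 5], 0.0), ([0, 0, 10], 1.0), ([10, 5, 0], 0.75)],
    )
    def test_hand_oracle_examples(self, vector, expected):
        tau = TauTransformer().fit_transform(np.array([vector], dtype=float))
        assert tau[0] == pytest.approx(expected, abs=1e-12)

    def test_all_zero_gene_has_no_tau(self):
        tau = TauTransformer().fit_transform(np.array([[0.0, 0.0, 0.0]]))
        assert np.isnan(tau[0])

    def test_fewer_than_two_conditions_rejected(self):
        with pytest.raises(ValueError, match="at least 2 conditions"):
            TauTransformer().fit(np.array([[1.0]]))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        vec=hnp.arrays(
            float, st.integers(2, 12),
            elements=st.floats(0, 1e6, allow_nan=False, width=32),
        )
    )
    def test_matches_brute_force_and_is_bounded(self, vec):
        tau = TauTransformer().fit_transform(vec[None, :])[0]
        expected = brute_force_tau(vec)
        if np.isnan(expected):
            assert np.isnan(tau)
        else:
            assert tau == pytest.approx(expected, abs=1e-12)
            assert 0.0 <= tau <= 1.0
            # extremes: 0 iff uniform at max, 1 iff single nonzero condition
            if tau == 0:
                assert (vec == vec.max()).all()
            if (vec > 0).sum() == 1:
                assert tau == pytest.approx(1.0, abs=1e-12)

    def test_compute_tau_stage_filter(self, expr_matrix):
        stage = matrix([[6, 2], [4, 1], [0, 0]], index=["G1", "G2", "G3"], kind="time_point")
        out = compute_tau(expr_matrix, stage).set_index("gene_id")
        assert out.loc["G1", "pass_filter"] and not out.loc["G2", "pass_filter"]
        assert out.loc["G1", "tau"] == pytest.approx(0.75)
        assert not out.loc["G1", "broad"] and out.loc["G2", "broad"]  # tau 0 < 0.4


# ---------------------------------------------------------------------------
# Markers
# ---------------------------------------------------------------------------

class TestMarkerCaller:
    def make_planted(self, n_rep=20, in_mean=100.0, out_mean=1.0, seed=0):
        rng = np.random.default_rng(seed)
        in_vals = in_mean * np.exp(rng.normal(0, 0.1, n_rep))
        out_vals = out_mean * np.exp(rng.normal(0, 0.1, 2 * n_rep))
        null = np.exp(rng.normal(0, 0.1, 3 * n_rep)) * 10
        X = np.vstack([np.concatenate([in_vals, out_vals]), null])
        y = np.array(["A"] * n_rep + ["B"] * n_rep + ["C"] * n_rep)
        return X, y

    def test_planted_marker_is_called(self):
        X, y = self.make_planted()
        caller = MarkerCaller().fit(X, y)
        assert caller.is_marker_.iloc[0]["A"]
        assert not caller.is_marker_.iloc[0][["B", "C"]].any()

    def test_identical_distributions_not_called(self):
        X, y = self.make_planted()
        caller = MarkerCaller().fit(X, y)
        assert not caller.is_marker_.iloc[1].any()

    def test_fold_change_gate_blocks_significant_but_small_effects(self):
        # in-type mean ~2.5x out-of-type: log2FC < 1.5 but p tiny
        rng = np.random.default_rng(1)
        inside = 25.0 * np.exp(rng.normal(0, 0.05, 50))
        outside = 10.0 * np.exp(rng.normal(0, 0.05, 50))
        X = np.vstack([np.concatenate([inside, outside])])
        y = np.array(["A"] * 50 + ["B"] * 50)
        caller = MarkerCaller().fit(X, y)
        assert caller.adjusted_p_.iloc[0]["A"] < 0.001
        assert caller.log2_fold_change_.iloc[0]["A"] < 1.5
        assert not caller.is_marker_.iloc[0]["A"]

    def test_single_cell_type_rejected(self):
        with pytest.raises(ValueError, match="at least 2 cell types"):
            MarkerCaller().fit(np.ones((2, 4)), np.array(["A"] * 4))

    def test_label_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="labels for"):
            MarkerCaller().fit(np.ones((2, 4)), np.array(["A", "B"]))


def brute_force_bh(pvals):
    """Step-up BH: independent of statsmodels."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        k = m - rank_from_end  # 1-based rank of this p-value
        running_min = min(running_min, p[idx] * m / k)
        adjusted[idx] = running_min
    return adjusted


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    pvals=hnp.arrays(float, st.integers(1, 40),
                     elements=st.floats(0, 1, allow_nan=False, width=32))
)
def test_bh_adjustment_matches_step_up_oracle(pvals):
    from statsmodels.stats.multitest import multipletests

    adjusted = multipletests(pvals, method="fdr_bh")[1]
    assert np.allclose(adjusted, brute_force_bh(pvals), atol=1e-12)


# ---------------------------------------------------------------------------
# Temporal clustering
# ---------------------------------------------------------------------------

class TestTemporalClustering:
    def make_two_shapes(self, n=10, seed=0):
        rng = np.random.default_rng(seed)
        rising = np.linspace(0, 5, 8)
        falling = rising[::-1]
        rows = [rising + rng.normal(0, 0.1, 8) for _ in range(n)]
        rows += [falling + rng.normal(0, 0.1, 8) for _ in range(n)]
        return np.array(rows)

    def test_identical_rows_share_a_cluster(self):
        X = self.make_two_shapes()
        X[1] = X[0]
        model = TemporalProfileClusterer(n_clusters=2, n_drop=0).fit(X)
        assert model.labels_[0] == model.labels_[1]

    def test_two_shapes_separate(self):
        X = self.make_two_shapes()
        labels = TemporalProfileClusterer(n_clusters=2, n_drop=0).fit_predict(X)
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[10]

    def test_retained_count_is_k_minus_n_drop(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 6))
        model = TemporalProfileClusterer(n_clusters=10, n_drop=2).fit(X)
        assert len(np.unique(model.labels_[model.retained_])) == 8
        assert len(np.unique(model.labels_)) == 10

    def test_invalid_parameters_rejected(self):
        X = np.random.default_rng(0).normal(size=(5, 4))
        with pytest.raises(ValueError, match="must exceed n_drop"):
            TemporalProfileClusterer(n_clusters=2, n_drop=2).fit(X)
        with pytest.raises(ValueError, match="cannot form 10 clusters"):
            TemporalProfileClusterer(n_clusters=10).fit(X)

    def test_invariant_to_row_order_and_affine_rescaling(self):
        X = self.make_two_shapes()
        base = TemporalProfileClusterer(n_clusters=2, n_drop=0).fit_predict(X)
        scaled = X * 7.0 + 3.0  # per-row affine maps vanish under standardization
        assert np.array_equal(
            TemporalProfileClusterer(n_clusters=2, n_drop=0).fit_predict(scaled), base
        )
        perm = np.random.default_rng(1).permutation(len(X))
        permuted = TemporalProfileClusterer(n_clusters=2, n_drop=0).fit_predict(X[perm])
        # same partition after inverting the permutation
        assert np.array_equal(permuted, base[perm])

    def test_retained_labels_ordered_by_peak_time(self):
        X = self.make_two_shapes()
        model = TemporalProfileClusterer(n_clusters=2, n_drop=0).fit(X)
        peaks = [int(np.argmax(model.cluster_profiles_.loc[c])) for c in
                 model.cluster_profiles_.index]
        assert peaks == sorted(peaks)

    def test_zero_variance_rows_excluded_by_wrapper(self):
        X = self.make_two_shapes()
        X[3] = 5.0  # flat row
        expr = matrix(np.abs(X), kind="time_point")
        assignments, _ = cluster_temporal_profiles(expr, k=2, n_drop=0)
        flat = assignments.set_index("gene_id").loc["G3"]
        assert flat["cluster_id"] == -1 and not flat["retained"]


# ---------------------------------------------------------------------------
# Pseudotime trends
# ---------------------------------------------------------------------------

class TestTrends:
    @pytest.mark.parametrize(
        "first, last, expected_dir, expected_ratio",
        [
            (10, 10, "flat", 0.0),
            (0, 15, "increase", 4.0),   # log2(16/1) with pseudocount 1
            (15, 0, "decrease", -4.0),
            (10, 21, "increase", 1.0),  # boundary: ratio exactly 1 is inclusive
        ],
    )
    def test_hand_oracle_examples(self, first, last, expected_dir, expected_ratio):
        expr = matrix([[first, 5, last]], kind="pseudotime_bin")
        out = classify_pseudotime_trend(expr)
        assert out.loc[0, "direction"] == expected_dir
        assert out.loc[0, "log2_last_over_first"] == pytest.approx(expected_ratio)

    def test_middle_bins_are_ignored(self):
        a = classify_pseudotime_trend(matrix([[1, 100, 8]], kind="pseudotime_bin"))
        b = classify_pseudotime_trend(matrix([[1, 0, 8]], kind="pseudotime_bin"))
        assert a.loc[0, "direction"] == b.loc[0, "direction"] == "increase"

    def test_needs_two_bins(self):
        with pytest.raises(ValueError, match="at least 2"):
            PseudotimeTrendClassifier().fit(np.array([[1.0]]))

    def test_wrong_condition_kind_rejected(self, expr_matrix):
        with pytest.raises(ValueError, match="pseudotime_bin"):
            classify_pseudotime_trend(expr_matrix)


# ---------------------------------------------------------------------------
# Maternal / zygotic
# ---------------------------------------------------------------------------

class TestMaternal:
    @pytest.mark.parametrize(
        "tpm, rpkm, expected",
        [
            (10.0, 0.0, "maternal"),        # inclusive TPM boundary
            (9.9, 19.9, "zygotic_only"),
            (0.0, 20.0, "maternal"),        # OR of criteria, inclusive RPKM boundary
            (0.0, 0.0, "zygotic_only"),
        ],
    )
    def test_threshold_boundaries(self, tpm, rpkm, expected):
        assert MaternalClassifier().predict(np.array([[tpm, rpkm]]))[0] == expected

    def test_calls_partition_the_union_of_inputs(self):
        we = matrix([[12.0], [1.0]], index=["G1", "G2"], unit="TPM", kind="stage")
        sc = matrix([[25.0], [5.0]], index=["G2", "G3"], unit="RPKM", kind="stage")
        calls = classify_maternal_zygotic(we, sc)
        assert sorted(calls["gene_id"]) == ["G1", "G2", "G3"]
        by_gene = calls.set_index("gene_id")
        assert by_gene.loc["G1", "call"] == "maternal"      # TPM branch
        assert by_gene.loc["G2", "call"] == "maternal"      # RPKM branch
        assert by_gene.loc["G3", "call"] == "zygotic_only"
        assert by_gene.loc["G2", "evidence"] == "single_cell_rpkm"

    def test_unit_mismatch_rejected(self):
        we = matrix([[12.0]], unit="RPKM", kind="stage")
        sc = matrix([[25.0]], unit="RPKM", kind="stage")
        with pytest.raises(ValueError, match="must be TPM"):
            classify_maternal_zygotic(we, sc)


# ---------------------------------------------------------------------------
# Heatmap preparation
# ---------------------------------------------------------------------------

class TestHeatmapPrep:
    def test_log2_pseudocount_values(self):
        expr = matrix([[0.0, 7.0], [3.0, 1.0]], kind="time_point")
        out, order = prep_heatmap_matrix(expr, mode="log2_pseudocount")
        assert out.iloc[0, 0] == pytest.approx(0.0)   # log2(0 + 1)
        assert out.iloc[0, 1] == pytest.approx(3.0)   # log2(7 + 1)
        assert set(order) == {"G0", "G1"}

    def test_row_centered_rows_sum_to_zero(self):
        expr = matrix([[1.0, 3.0], [2.0, 8.0]], kind="time_point")
        out, _ = prep_heatmap_matrix(expr, mode="log2_pseudocount_row_centered")
        assert np.allclose(out.sum(axis=1), 0.0)

    def test_log2_mode_is_invertible(self):
        expr = matrix([[0.0, 7.0, 2.5]], kind="time_point")
        out, _ = prep_heatmap_matrix(expr, mode="log2_pseudocount", pseudocount=1.0)
        assert np.allclose(np.exp2(out) - 1.0, expr.values)

    def test_unknown_mode_rejected(self, expr_matrix):
        with pytest.raises(ValueError, match="unknown mode"):
            prep_heatmap_matrix(expr_matrix, mode="rank")
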