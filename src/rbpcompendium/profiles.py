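"""Per-gene expression analytics as scikit-learn-style estimators.

The estimators operate on genes x conditions matrices (numpy arrays or
DataFrames) and follow sklearn conventions: parameters are set in
``__init__``, validated in ``fit``, and results live in trailing-underscore
attributes. Module-level wrapper functions accept ``io.ExpressionMatrix``
inputs and return tidy tables; they are thin shims over the estimators.

Implemented analytics:

* ``TauTransformer`` — the Tau expression-specificity index,
  Tau = sum_i(1 - x_i/max_j x_j) / (N - 1) over N conditions, in [0, 1]
  (0 = uniform expression, 1 = restricted to a single condition).
* ``MarkerCaller`` — cell-type marker calling: per (gene, type) log2 fold
  change of in-type vs out-of-type mean expression (pseudocount 1 on both
  means), a two-sided Wilcoxon rank-sum test per (gene, type), and
  Benjamini-Hochberg correction across all tests.
* ``TemporalProfileClusterer`` — hierarchical clustering of standardized
  time-course profiles under the correlation distance d = 1 - Pearson r,
  with the smallest clusters dropped and retained clusters relabelled by
  their time of peak mean expression.
* ``PseudotimeTrendClassifier`` — increase/decrease/flat calls from the
  log2 ratio of last over first pseudotime bin (pseudocount 1).
* ``MaternalClassifier`` — maternal vs zygotic-only calls from 1-cell-stage
  abundance thresholds (whole-embryo TPM >= 10 OR single-cell mean
  RPKM >= 20).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

TAU_BROAD_THRESHOLD = 0.4
TAU_MIN_STAGE_TPM = 5.0


def _as_array(X) -> np.ndarray:
    arr = X.to_numpy() if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D genes x conditions matrix, got shape {arr.shape}")
    return arr.astype(float)


def _index_of(X, n: int) -> pd.Index:
    if isinstance(X, pd.DataFrame):
        return X.index
    return pd.RangeIndex(n)


# ---------------------------------------------------------------------------
# Tau specificity
# ---------------------------------------------------------------------------

class TauTransformer(TransformerMixin, BaseEstimator):
    """Tau expression-specificity index over the columns of a matrix.

    ``transform`` returns one Tau value per row (gene). Rows whose maximum
    is zero have no defined Tau and yield NaN.
    """

    def fit(self, X, y=None):
        arr = _as_array(X)
        if arr.shape[1] < 2:
            raise ValueError("Tau needs at least 2 conditions (N - 1 division)")
        if (arr < 0).any():
            raise ValueError("Tau requires non-negative expression values")
        self.n_conditions_ = arr.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        arr = _as_array(X)
        if arr.shape[1] < 2:
            raise ValueError("Tau needs at least 2 conditions (N - 1 division)")
        if (arr < 0).any():
            raise ValueError("Tau requires non-negative expression values")
        maxes = arr.max(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            xhat = arr / maxes[:, None]
            tau = (1.0 - xhat).sum(axis=1) / (arr.shape[1] - 1)
        tau[maxes == 0] = np.nan
        return tau


def compute_tau(
    expr: ExpressionMatrix, stage_expr: ExpressionMatrix | None = None
) -> pd.DataFrame:
    """Per-gene Tau over cell types, with the stage-level detection filter.

    Returns a table (gene_id, tau, pass_filter, broad). ``pass_filter`` is
    true iff the gene reaches at least 5 TPM at some stage of the
    whole-embryo series (all genes pass when no stage matrix is supplied);
    ``broad`` marks Tau < 0.4. Genes with all-zero cell-type expression get
    tau = NaN.
    """
    if expr.condition_kind != "cell_type":
        raise ValueError(f"Tau expects a cell_type matrix, got {expr.condition_kind!r}")
    tau = TauTransformer().fit(expr.values).transform(expr.values)
    out = pd.DataFrame({"gene_id": expr.gene_ids, "tau": tau})
    if stage_expr is None:
        out["pass_filter"] = True
    else:
        stage_max = stage_expr.values.max(axis=1)
        out["pass_filter"] = (
            out["gene_id"].map(stage_max).fillna(0.0) >= TAU_MIN_STAGE_TPM
        )
    out["broad"] = out["tau"] < TAU_BROAD_THRESHOLD
    return out


# ---------------------------------------------------------------------------
# Marker calling
# ---------------------------------------------------------------------------

class MarkerCaller(BaseEstimator):
    """Cell-type marker calling over a replicated genes x cells matrix.

    Parameters
    ----------
    log2fc_threshold : float, default 1.5
        Minimum log2 fold change of in-type vs out-of-type mean expression.
    alpha : float, default 0.05
        BH-adjusted p-value cutoff (strict: adjusted p < alpha).
    pseudocount : float, default 1.0
        Added to both group means before the ratio.

    After ``fit(X, y)`` (``y`` giving the cell type of each column):

    Attributes
    ----------
    cell_types_ : ndarray of unique cell types
    log2_fold_change_, pvalue_, adjusted_p_, is_marker_ :
        DataFrames of shape (n_genes, n_types).
    """

    def __init__(self, log2fc_threshold: float = 1.5, alpha: float = 0.05,
                 pseudocount: float = 1.0):
        self.log2fc_threshold = log2fc_threshold
        self.alpha = alpha
        self.pseudocount = pseudocount

    def fit(self, X, y):
        arr = _as_array(X)
        y = np.asarray(y)
        if y.shape[0] != arr.shape[1]:
            raise ValueError(
                f"{y.shape[0]} cell-type labels for {arr.shape[1]} expression columns"
            )
        types, counts = np.unique(y, return_counts=True)
        if len(types) < 2:
            raise ValueError("marker calling needs at least 2 cell types")
        if (counts == 0).any():  # unreachable via np.unique; guards explicit empty groups
            raise ValueError("every cell type needs at least one column")
        index = _index_of(X, arr.shape[0])

        lfc = np.empty((arr.shape[0], len(types)))
        pvals = np.empty_like(lfc)
        for j, ct in enumerate(types):
            mask = y == ct
            inside, outside = arr[:, mask], arr[:, ~mask]
            lfc[:, j] = np.log2(
                (inside.mean(axis=1) + self.pseudocount)
                / (outside.mean(axis=1) + self.pseudocount)
            )
            # Two-sided Wilcoxon rank-sum (Mann-Whitney), normal approximation
            # with midranks/tie correction; vectorized across genes.
            res = sps.mannwhitneyu(inside, outside, axis=1, alternative="two-sided",
                                   method="asymptotic")
            pvals[:, j] = res.pvalue

        adj = multipletests(pvals.ravel(), method="fdr_bh")[1].reshape(pvals.shape)
        self.cell_types_ = types
        self.log2_fold_change_ = pd.DataFrame(lfc, index=index, columns=types)
        self.pvalue_ = pd.DataFrame(pvals, index=index, columns=types)
        self.adjusted_p_ = pd.DataFrame(adj, index=index, columns=types)
        self.is_marker_ = (self.log2_fold_change_ >= self.log2fc_threshold) & (
            self.adjusted_p_ < self.alpha
        )
        return self

    def predict(self, X=None) -> pd.DataFrame:
        """Boolean genes x types marker matrix from the fitted model."""
        return self.is_marker_


def call_markers(expr: ExpressionMatrix, cell_type_labels: pd.DataFrame) -> pd.DataFrame:
    """Tidy marker calls for a replicated cell-type expression matrix.

    ``cell_type_labels`` maps column_id -> cell_type (from
    ``io.read_cell_type_labels``). Returns one row per (gene, cell type)
    with log2_fold_change, adjusted_p and is_marker.
    """
    label_map = dict(zip(cell_type_labels["column_id"], cell_type_labels["cell_type"]))
    missing = [c for c in expr.condition_ids if c not in label_map]
    if missing:
        raise ValueError(f"expression columns without a cell-type label: {missing[:5]}")
    y = np.array([label_map[c] for c in expr.condition_ids])
    caller = MarkerCaller().fit(expr.values, y)
    long = (
        caller.log2_fold_change_.rename_axis("gene_id")
        .reset_index()
        .melt(id_vars="gene_id", var_name="cell_type", value_name="log2_fold_change")
    )
    long["adjusted_p"] = caller.adjusted_p_.to_numpy().T.ravel()
    long["is_marker"] = caller.is_marker_.to_numpy().T.ravel()
    return long


# ---------------------------------------------------------------------------
# Temporal clustering
# ---------------------------------------------------------------------------

def correlation_distance_condensed(arr: np.ndarray) -> np.ndarray:
    """Condensed pairwise distance d = 1 - Pearson r between matrix rows."""
    r = np.corrcoef(arr)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 2.0)
    return squareform(d, checks=False)


class TemporalProfileClusterer(ClusterMixin, BaseEstimator):
    """Hierarchical clustering of standardized expression time courses.

    Rows are standardized to mean 0, sd 1; the pairwise distance is
    1 - Pearson correlation; the tree (default complete linkage) is cut at
    ``n_clusters`` and the ``n_drop`` smallest clusters are marked not
    retained. Retained clusters are relabelled 0..m-1 in order of the time
    at which their mean standardized profile peaks; dropped clusters get
    the labels after the retained ones (largest dropped first).

    Attributes (after ``fit``)
    ----------
    labels_ : int array, cluster id per gene
    retained_ : bool array per gene
    cluster_profiles_ : DataFrame (cluster id x time) of mean standardized
        profiles for retained clusters
    """

    def __init__(self, n_clusters: int = 10, n_drop: int = 2, linkage: str = "complete"):
        self.n_clusters = n_clusters
        self.n_drop = n_drop
        self.linkage = linkage

    def fit(self, X, y=None):
        arr = _as_array(X)
        if self.n_clusters <= self.n_drop:
            raise ValueError(f"n_clusters ({self.n_clusters}) must exceed n_drop ({self.n_drop})")
        if arr.shape[0] < self.n_clusters:
            raise ValueError(
                f"cannot form {self.n_clusters} clusters from {arr.shape[0]} genes"
            )
        sd = arr.std(axis=1, ddof=1)
        if (sd == 0).any():
            raise ValueError("zero-variance rows cannot enter the correlation distance")
        z = (arr - arr.mean(axis=1, keepdims=True)) / sd[:, None]

        link = hierarchy.linkage(correlation_distance_condensed(z), method=self.linkage)
        raw = hierarchy.fcluster(link, t=self.n_clusters, criterion="maxclust")
        ids, sizes = np.unique(raw, return_counts=True)
        # Smallest n_drop clusters are dropped; ties break on raw label.
        order_by_size = sorted(zip(sizes, ids))
        dropped = {cid for _, cid in order_by_size[: self.n_drop]}
        retained_ids = [cid for cid in ids if cid not in dropped]

        profiles = {cid: z[raw == cid].mean(axis=0) for cid in retained_ids}
        peak_order = sorted(retained_ids, key=lambda cid: (int(np.argmax(profiles[cid])), cid))
        relabel = {cid: k for k, cid in enumerate(peak_order)}
        for cid in sorted(dropped, key=lambda c: (-sizes[list(ids).index(c)], c)):
            relabel[cid] = len(relabel)

        self.labels_ = np.array([relabel[c] for c in raw])
        self.retained_ = np.array([c not in dropped for c in raw])
        cols = list(X.columns) if isinstance(X, pd.DataFrame) else list(range(arr.shape[1]))
        self.cluster_profiles_ = pd.DataFrame(
            [profiles[cid] for cid in peak_order],
            index=pd.Index(range(len(peak_order)), name="cluster_id"),
            columns=cols,
        )
        self.linkage_ = link
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def cluster_temporal_profiles(
    expr: ExpressionMatrix, k: int = 10, n_drop: int = 2, linkage: str = "complete"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cluster gene expression time courses; returns (assignments, profiles).

    Zero-variance rows cannot enter the Pearson distance and are excluded
    with a logged warning. Assignments have columns gene_id, cluster_id,
    retained (cluster_id = -1 for excluded zero-variance genes).
    """
    values = expr.values
    sd = values.std(axis=1, ddof=1)
    flat = sd[sd == 0].index.tolist()
    if flat:
        logger.warning("excluding %d zero-variance genes from clustering", len(flat))
        values = values.loc[sd > 0]
    model = TemporalProfileClusterer(n_clusters=k, n_drop=n_drop, linkage=linkage).fit(values)
    assignments = pd.DataFrame(
        {"gene_id": values.index, "cluster_id": model.labels_, "retained": model.retained_}
    )
    if flat:
        assignments = pd.concat(
            [assignments,
             pd.DataFrame({"gene_id": flat, "cluster_id": -1, "retained": False})],
            ignore_index=True,
        )
    return assignments, model.cluster_profiles_


# ---------------------------------------------------------------------------
# Pseudotime trends
# ---------------------------------------------------------------------------

class PseudotimeTrendClassifier(BaseEstimator):
    """Increase/decrease/flat calls over ordered pseudotime bins.

    The statistic is log2((last + pseudocount) / (first + pseudocount));
    a gene is called "increase" when it is >= ``threshold_log2``,
    "decrease" when <= -``threshold_log2``, otherwise "flat".
    """

    def __init__(self, threshold_log2: float = 1.0, pseudocount: float = 1.0):
        self.threshold_log2 = threshold_log2
        self.pseudocount = pseudocount

    def fit(self, X, y=None):
        arr = _as_array(X)
        if arr.shape[1] < 2:
            raise ValueError("trend calling needs at least 2 ordered pseudotime bins")
        self.n_bins_ = arr.shape[1]
        return self

    def log2_ratio(self, X) -> np.ndarray:
        arr = _as_array(X)
        return np.log2((arr[:, -1] + self.pseudocount) / (arr[:, 0] + self.pseudocount))

    def predict(self, X) -> np.ndarray:
        arr = _as_array(X)
        if arr.shape[1] < 2:
            raise ValueError("trend calling needs at least 2 ordered pseudotime bins")
        ratio = self.log2_ratio(arr)
        out = np.where(
            ratio >= self.threshold_log2, "increase",
            np.where(ratio <= -self.threshold_log2, "decrease", "flat"),
        )
        return out


def classify_pseudotime_trend(
    expr: ExpressionMatrix, threshold_log2: float = 1.0
) -> pd.DataFrame:
    """Per-gene trend calls over the (ordered) pseudotime-bin columns."""
    if expr.condition_kind != "pseudotime_bin":
        raise ValueError(
            f"trend calling expects a pseudotime_bin matrix, got {expr.condition_kind!r}"
        )
    clf = PseudotimeTrendClassifier(threshold_log2=threshold_log2).fit(expr.values)
    return pd.DataFrame(
        {
            "gene_id": expr.gene_ids,
            "direction": clf.predict(expr.values),
            "log2_last_over_first": clf.log2_ratio(expr.values),
        }
    )


# ---------------------------------------------------------------------------
# Maternal / zygotic-only classification
# ---------------------------------------------------------------------------

class MaternalClassifier(BaseEstimator):
    """Maternal vs zygotic-only calls from 1-cell-stage abundances.

    ``predict`` takes a 2-column array [whole-embryo TPM, single-cell mean
    RPKM] and returns "maternal" where TPM >= tpm_threshold OR
    RPKM >= rpkm_threshold (inclusive, as the thresholds are stated),
    "zygotic_only" otherwise.
    """

    def __init__(self, tpm_threshold: float = 10.0, rpkm_threshold: float = 20.0):
        self.tpm_threshold = tpm_threshold
        self.rpkm_threshold = rpkm_threshold

    def fit(self, X=None, y=None):
        return self

    def predict(self, X) -> np.ndarray:
        arr = _as_array(X)
        if arr.shape[1] != 2:
            raise ValueError("expected 2 columns: [1-cell TPM, 1-cell mean RPKM]")
        maternal = (arr[:, 0] >= self.tpm_threshold) | (arr[:, 1] >= self.rpkm_threshold)
        return np.where(maternal, "maternal", "zygotic_only")


def classify_maternal_zygotic(
    whole_embryo_1cell: ExpressionMatrix, sc_1cell: ExpressionMatrix
) -> pd.DataFrame:
    """Classify every gene in either input as maternal or zygotic-only.

    ``whole_embryo_1cell`` must be TPM and ``sc_1cell`` RPKM (both restricted
    to 1-cell-stage columns; the single-cell matrix is averaged over its
    cells). Genes absent from one input count as 0 there; genes absent from
    both would be zygotic-only by definition and cannot appear here. The
    evidence column records which threshold(s) fired.
    """
    if whole_embryo_1cell.unit != "TPM":
        raise ValueError(f"whole-embryo matrix must be TPM, got {whole_embryo_1cell.unit}")
    if sc_1cell.unit != "RPKM":
        raise ValueError(f"single-cell matrix must be RPKM, got {sc_1cell.unit}")
    tpm = whole_embryo_1cell.values.mean(axis=1)
    rpkm = sc_1cell.values.mean(axis=1)
    genes = tpm.index.union(rpkm.index)
    tpm = tpm.reindex(genes, fill_value=0.0)
    rpkm = rpkm.reindex(genes, fill_value=0.0)
    clf = MaternalClassifier()
    calls = clf.predict(np.column_stack([tpm.to_numpy(), rpkm.to_numpy()]))
    evidence = np.select(
        [
            (tpm >= clf.tpm_threshold) & (rpkm >= clf.rpkm_threshold),
            tpm >= clf.tpm_threshold,
            rpkm >= clf.rpkm_threshold,
        ],
        ["whole_embryo_tpm,single_cell_rpkm", "whole_embryo_tpm", "single_cell_rpkm"],
        default="none",
    )
    return pd.DataFrame({"gene_id": genes, "call": calls, "evidence": evidence}).reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# Heatmap preparation
# ---------------------------------------------------------------------------

HEATMAP_MODES = ("log2_pseudocount", "log2_pseudocount_row_centered", "zscore")


def prep_heatmap_matrix(
    expr: ExpressionMatrix,
    mode: str = "log2_pseudocount",
    pseudocount: float = 1.0,
    linkage: str = "complete",
) -> tuple[pd.DataFrame, list[str]]:
    """Transform a matrix for heatmap display and order rows by clustering.

    Modes: ``log2_pseudocount`` (log2(x + pc)), ``log2_pseudocount_row_centered``
    (the same, mean-centered by row), ``zscore`` (row standardization).
    The row order comes from hierarchical clustering of the transformed
    matrix under the 1 - Pearson distance (leaves order). Constant rows are
    placed after the clustered ones, in input order.
    """
    if mode not in HEATMAP_MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {HEATMAP_MODES}")
    values = expr.values
    if mode == "log2_pseudocount":
        out = np.log2(values + pseudocount)
    elif mode == "log2_pseudocount_row_centered":
        out = np.log2(values + pseudocount)
        out = out.sub(out.mean(axis=1), axis=0)
    else:
        out = values.sub(values.mean(axis=1), axis=0).div(values.std(axis=1, ddof=1), axis=0)
    sd = out.std(axis=1, ddof=1)
    variable = out.loc[(sd > 0) & sd.notna()]
    constant = [g for g in out.index if g not in variable.index]
    if len(variable) >= 2:
        link = hierarchy.linkage(
            correlation_distance_condensed(variable.to_numpy()), method=linkage
        )
        order = [variable.index[i] for i in hierarchy.leaves_list(link)]
    else:
        order = list(variable.index)
    row_order = order + constant
    return out, row_order
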