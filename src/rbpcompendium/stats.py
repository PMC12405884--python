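"""Category-level comparisons: flag proportions, half-lives, median curves.

Three analyses over the exclusive gene categories (group1..group4, tf,
other):

* ``flag_proportions_by_category`` — per category x binary flag (RNAi
  phenotype, orthology, ...), the proportion flagged, compared against the
  all-protein-coding background with a 2x2 chi-square test
  (classical statistic sum (O-E)^2/E, no continuity correction by default).
* ``compare_half_life_distributions`` — per-category n and median mRNA
  half-life, with pairwise two-sided Wilcoxon rank-sum p-values (exact by
  enumeration for small samples, normal approximation with midranks
  otherwise).
* ``median_scaled_expression`` — per-gene standardization (mean 0, sd 1,
  as R's scale()) followed by the per-time-point median over a gene set.
"""

from __future__ import annotations

import itertools
import logging
import math

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

#: Largest pooled sample size for which the rank-sum p-value is computed by
#: exact enumeration over all C(n, n1) group assignments (handles ties).
EXACT_RANKSUM_MAX_N = 12


def chi_square_2x2(table: np.ndarray, yates: bool = False) -> tuple[float, float]:
    """Classical chi-square test on a 2x2 contingency table.

    Returns (statistic, p) with 1 degree of freedom; the statistic is
    sum (O-E)^2/E without continuity correction unless ``yates``.
    Returns (nan, nan) when any expected count is zero.
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {table.shape}")
    expected = sps.contingency.expected_freq(table)
    if (expected == 0).any():
        logger.warning("chi-square undefined: expected cell count of zero")
        return float("nan"), float("nan")
    stat, p, _, _ = sps.chi2_contingency(table, correction=yates)
    return float(stat), float(p)


def rank_sum_test(
    x, y, exact_max_n: int = EXACT_RANKSUM_MAX_N
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (statistic W, p-value).

    W is the sum of pooled midranks in the first sample. For pooled sizes
    up to ``exact_max_n`` the p-value is exact: every C(n, n1) assignment
    of the pooled midranks is enumerated (ties handled naturally, and two
    identical samples give p = 1). Larger samples use the normal
    approximation with midranks and tie correction (scipy ranksums-style,
    no continuity correction).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("rank-sum test needs non-empty samples")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w = ranks[:n1].sum()
    if n1 + n2 <= exact_max_n:
        sums = np.array([sum(c) for c in itertools.combinations(ranks, n1)])
        mean = ranks.sum() * n1 / (n1 + n2)
        dev = abs(w - mean) - 1e-9  # tolerate float noise in midrank sums
        p = float(np.mean(np.abs(sums - mean) >= dev))
        return float(w), min(1.0, p)
    mean = n1 * (n1 + n2 + 1) / 2.0
    # Tie-corrected variance of the rank sum.
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / ((n1 + n2) * (n1 + n2 - 1))
    var = n1 * n2 / 12.0 * (n1 + n2 + 1 - tie_term)
    if var == 0:
        return float(w), 1.0
    z = (w - mean) / math.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return float(w), min(1.0, float(p))


def flag_proportions_by_category(
    categories: pd.Series,
    flags: pd.DataFrame,
    background_category: str | None = None,
    yates: bool = False,
) -> pd.DataFrame:
    """Per category x flag: proportion flagged, chi-square vs background.

    Parameters
    ----------
    categories
        Series mapping gene_id (index) -> category label over all live
        protein-coding genes (``compendium.category_map`` output).
    flags
        Long table (gene_id, flag_name, value) of boolean flags; genes of a
        category absent from the table count as unflagged for that flag.
    background_category
        Which category is the comparison background. ``None`` means all
        genes in ``categories`` (the all-protein-coding background, which
        includes the category under test).
    """
    flags = flags.drop_duplicates(["gene_id", "flag_name"])
    if background_category is None:
        background_ids = pd.Index(categories.index)
    else:
        background_ids = categories.index[categories == background_category]
        if len(background_ids) == 0:
            raise ValueError(f"background category {background_category!r} has no genes")
    rows = []
    for flag_name, sub in flags.groupby("flag_name", sort=True):
        flagged = set(sub.loc[sub["value"], "gene_id"])
        bg_n = len(background_ids)
        bg_flagged = sum(g in flagged for g in background_ids)
        for category in sorted(categories.unique()):
            ids = categories.index[categories == category]
            n = len(ids)
            if n == 0:
                logger.warning("category %r has no genes; skipped", category)
                continue
            k = sum(g in flagged for g in ids)
            table = np.array([[k, n - k], [bg_flagged, bg_n - bg_flagged]], dtype=float)
            chi2, p = chi_square_2x2(table, yates=yates)
            rows.append(
                {
                    "category": category,
                    "flag_name": flag_name,
                    "n_genes": n,
                    "n_flagged": k,
                    "proportion": k / n,
                    "chi2_statistic": chi2,
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)


def compare_half_life_distributions(
    categories: pd.Series,
    half_lives: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
    exact_max_n: int = EXACT_RANKSUM_MAX_N,
) -> pd.DataFrame:
    """Per-category median mRNA half-life with pairwise rank-sum p-values.

    Medians are computed only over genes with a measured half-life;
    categories with no measured genes are excluded with a warning. ``pairs``
    defaults to all unordered pairs of represented categories. Returns one
    row per category with columns group_label, n_genes, median_half_life
    and pairwise_p (dict of "other_label" -> p).
    """
    hl = half_lives.set_index("gene_id")["half_life"]
    samples: dict[str, np.ndarray] = {}
    for category in sorted(categories.unique()):
        ids = categories.index[categories == category]
        vals = hl.reindex(ids).dropna().to_numpy()
        if len(vals) == 0:
            logger.warning("category %r has no measured half-lives; excluded", category)
            continue
        samples[category] = vals
    if len(samples) < 2:
        raise ValueError("need at least 2 categories with measured half-lives")
    if pairs is None:
        pairs = list(itertools.combinations(sorted(samples), 2))
    pairwise: dict[str, dict[str, float]] = {label: {} for label in samples}
    for a, b in pairs:
        if a not in samples or b not in samples:
            continue
        _, p = rank_sum_test(samples[a], samples[b], exact_max_n=exact_max_n)
        pairwise[a][b] = p
        pairwise[b][a] = p
    return pd.DataFrame(
        [
            {
                "group_label": label,
                "n_genes": len(vals),
                "median_half_life": float(np.median(vals)),
                "pairwise_p": pairwise[label],
            }
            for label, vals in samples.items()
        ]
    )


def median_scaled_expression(
    gene_sets: dict[str, list[str]], expr: ExpressionMatrix
) -> pd.DataFrame:
    """Median scaled expression curve per gene set over a time series.

    Each gene's profile is standardized to mean 0, sd 1 (sample sd, as R's
    scale()); the curve is the per-time-point median across the set's genes.
    Sets with fewer than 2 usable (present, nonzero-variance) genes are
    skipped with a warning. Returns a curves x time-points table indexed by
    the set label.
    """
    values = expr.values
    sd = values.std(axis=1, ddof=1)
    usable = values.loc[sd > 0]
    z = usable.sub(usable.mean(axis=1), axis=0).div(sd[usable.index], axis=0)
    curves = {}
    for label, genes in gene_sets.items():
        present = [g for g in genes if g in z.index]
        if len(present) < 2:
            logger.warning("gene set %r has <2 usable genes; skipped", label)
            continue
        curves[label] = z.loc[present].median(axis=0)
    if not curves:
        return pd.DataFrame(columns=values.columns)
    out = pd.DataFrame(curves).T
    out.index.name = "gene_set_label"
    return out
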