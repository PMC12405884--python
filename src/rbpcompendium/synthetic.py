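"""Seeded generators for every input the pipeline consumes.

Each generator emulates one of the external resources the real analysis
reads — domain-annotation dumps, a TF compendium, a legacy RBP list,
cell-type atlases, whole-embryo time series, germline pseudotime bins,
and an mRNA-decay atlas — and emits a ground-truth table alongside, so
every downstream stage can be tested end-to-end without downloads.

All expression noise is log-normal (multiplicative): the simplest model
that keeps abundances non-negative and fold-changes stable. One scenario
seed governs everything; per-generator sub-seeds are derived from it
deterministically so a scenario reproduces piecewise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .catalog import RBDFamily, load_catalog
from .io import ExpressionMatrix

#: Default planted composition of the simulated proteome, as fractions of
#: n_genes. Mirrors the rough census of a nematode proteome — ~900 RBPs and
#: ~900 TFs among ~20k coding genes — compressed so that every analysis
#: category is well-populated at the default n=500.
DEFAULT_GROUP_FRACTIONS = {1: 0.12, 2: 0.07, 3: 0.12, 4: 0.13}
DEFAULT_TF_ONLY_FRACTION = 0.15

#: A decoy (non-RBD) domain used for background genes.
_DECOY_DOMAINS = [
    ("PF00069", "Protein kinase domain"),
    ("PF00400", "WD40 repeat"),
    ("PF00076X", "Unrelated domain"),
    ("PF07690", "Major facilitator superfamily"),
]


def _spawn(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


@dataclass
class SyntheticScenario:
    """In-memory bundle of generated inputs plus the planted truth."""

    registry: pd.DataFrame | None = None
    domain_hits: pd.DataFrame | None = None
    tf_ids: list[str] = field(default_factory=list)
    legacy: pd.DataFrame | None = None
    name_map: dict[str, str] = field(default_factory=dict)
    truth: pd.DataFrame | None = None


def _families_by_group(catalog: list[RBDFamily]) -> dict[int, list[RBDFamily]]:
    by_group: dict[int, list[RBDFamily]] = {1: [], 2: [], 3: [], 4: []}
    for fam in catalog:
        by_group[fam.group].append(fam)
    return by_group


def _hit_for(gene_id: str, fam: RBDFamily, rng: np.random.Generator, source: str | None = None,
             isoform: str = "a") -> dict:
    return {
        "gene_id": gene_id,
        "protein_id": f"{gene_id}{isoform}",
        "domain_accession": fam.accessions[int(rng.integers(len(fam.accessions)))],
        "domain_name": f"{fam.name} domain",
        "source_db": source or sorted(fam.sources)[int(rng.integers(len(fam.sources)))],
    }


def simulate_proteome(
    n_genes: int = 500,
    group_fractions: dict[int, float] | None = None,
    tf_overlap_fraction: float = 0.10,
    multi_domain_fraction: float = 0.10,
    dead_fraction: float = 0.05,
    tf_only_fraction: float = DEFAULT_TF_ONLY_FRACTION,
    legacy_only_count: int = 5,
    seed: int = 0,
) -> SyntheticScenario:
    """Simulate a proteome: registry, domain dumps, TF list, legacy list.

    Genes are planted into roles — RBP of a given group, TF-only, plain
    protein-coding, dead/transposon — and receive domain hits drawn from
    the default catalog consistent with the role. A ``multi_domain_fraction``
    of RBP genes carry hits mapping to two different groups (planted truth
    is the precedence winner, the smaller group number); a fraction of hits
    carry a disqualified source_db="other"; dead and transposon-origin
    genes carry qualifying hits so the removal rule is exercised; a few
    legacy-only members enter only through the legacy list under old names.

    Truth columns: gene_id, true_group (empty when not an RBP),
    true_category (the exclusive analysis category implied by the planted
    role and the TF-resolution rules), status.
    """
    fractions = dict(DEFAULT_GROUP_FRACTIONS if group_fractions is None else group_fractions)
    for key, frac in [("tf_overlap", tf_overlap_fraction), ("multi_domain", multi_domain_fraction),
                      ("dead", dead_fraction), ("tf_only", tf_only_fraction)]:
        if not 0 <= frac <= 1:
            raise ValueError(f"{key} fraction must be in [0, 1], got {frac}")
    if sum(fractions.values()) + dead_fraction + tf_only_fraction > 1:
        raise ValueError("planted fractions exceed the gene budget")

    rng = _spawn(seed, 0)
    catalog = load_catalog()
    by_group = _families_by_group(catalog)
    ccch = next(f for f in catalog if f.name == "CCCH")

    gene_ids = [f"SYNG{idx:05d}" for idx in range(n_genes)]
    n_dead = round(n_genes * dead_fraction)
    n_rbp = {g: round(n_genes * frac) for g, frac in fractions.items()}
    n_tf_only = round(n_genes * tf_only_fraction)

    cursor = 0

    def take(k: int) -> list[str]:
        nonlocal cursor
        out = gene_ids[cursor:cursor + k]
        cursor += k
        return out

    dead_ids = take(n_dead)
    rbp_ids = {g: take(k) for g, k in n_rbp.items()}
    tf_only_ids = take(n_tf_only)
    other_ids = gene_ids[cursor:]

    registry_rows, hit_rows, truth_rows = [], [], []
    tf_ids: list[str] = []

    for i, gid in enumerate(dead_ids):
        status = "dead" if i % 2 == 0 else "transposon"
        registry_rows.append((gid, f"dead-{i}", "protein_coding", status))
        # qualifying hit that must be removed by the status filter
        fam = by_group[1][int(rng.integers(len(by_group[1])))]
        hit_rows.append(_hit_for(gid, fam, rng))
        truth_rows.append((gid, "", "", status))

    for group, ids in rbp_ids.items():
        n_overlap = round(len(ids) * tf_overlap_fraction)
        n_multi = round(len(ids) * multi_domain_fraction)
        for i, gid in enumerate(ids):
            registry_rows.append((gid, f"rbp-{group}-{i}", "protein_coding", "live"))
            is_tf = i < n_overlap
            is_multi = n_overlap <= i < n_overlap + n_multi
            if is_tf and group == 1 and i % 2 == 0:
                fam = ccch  # CCCH-carrying TF overlaps stay RBPs
            else:
                fams = by_group[group]
                fam = fams[int(rng.integers(len(fams)))]
            hit_rows.append(_hit_for(gid, fam, rng))
            families = {fam.name}
            if is_multi and group < 4:
                extra_group = int(rng.integers(group + 1, 5))
                extra = by_group[extra_group][int(rng.integers(len(by_group[extra_group])))]
                hit_rows.append(_hit_for(gid, extra, rng, isoform="b"))
                families.add(extra.name)
            if rng.random() < 0.3:  # disqualified evidence never adds a family
                decoy_fam = by_group[int(rng.integers(1, 5))][0]
                hit_rows.append(_hit_for(gid, decoy_fam, rng, source="other"))
            if is_tf:
                tf_ids.append(gid)
            # The exclusive category implied by the planted role, applying
            # the TF-resolution rules at generation time (by construction).
            if not is_tf:
                category = f"group{group}"
            elif group == 1:
                category = "group1" if "CCCH" in families else "tf"
            elif group == 2:
                category = "tf"
            else:
                category = f"group{group}"
            truth_rows.append((gid, str(group), category, "live"))

    for i, gid in enumerate(tf_only_ids):
        registry_rows.append((gid, f"tf-{i}", "protein_coding", "live"))
        tf_ids.append(gid)
        if rng.random() < 0.5:
            acc, name = _DECOY_DOMAINS[int(rng.integers(len(_DECOY_DOMAINS)))]
            hit_rows.append({"gene_id": gid, "protein_id": f"{gid}a", "domain_accession": acc,
                             "domain_name": name, "source_db": "Pfam"})
        truth_rows.append((gid, "", "tf", "live"))

    for i, gid in enumerate(other_ids):
        registry_rows.append((gid, f"other-{i}", "protein_coding", "live"))
        if rng.random() < 0.5:
            acc, name = _DECOY_DOMAINS[int(rng.integers(len(_DECOY_DOMAINS)))]
            hit_rows.append({"gene_id": gid, "protein_id": f"{gid}a", "domain_accession": acc,
                             "domain_name": name, "source_db": "Pfam"})
        truth_rows.append((gid, "", "other", "live"))

    # Legacy-only members: genes with no current domain evidence that enter
    # through the legacy list under old names, mapped by the name map. One of
    # them points at a dead gene to exercise the merge-removal rule.
    legacy_rows, name_map = [], {}
    for j in range(legacy_only_count):
        gid = f"SYNG{n_genes + j:05d}"
        old = f"legacy-{j}"
        if j == legacy_only_count - 1 and dead_ids:
            name_map[old] = dead_ids[0]  # resolves to a dead gene -> dropped
            legacy_rows.append((old, 4))
            continue
        registry_rows.append((gid, f"legacy-new-{j}", "protein_coding", "live"))
        name_map[old] = gid
        legacy_rows.append((old, 4))
        truth_rows.append((gid, "4", "group4", "live"))

    scenario = SyntheticScenario(
        registry=pd.DataFrame(registry_rows,
                              columns=["gene_id", "public_name", "biotype", "status"]),
        domain_hits=pd.DataFrame(hit_rows)[
            ["gene_id", "protein_id", "domain_accession", "domain_name", "source_db"]
        ],
        tf_ids=sorted(tf_ids),
        legacy=pd.DataFrame(legacy_rows, columns=["gene_name", "group"]),
        name_map=name_map,
        truth=pd.DataFrame(truth_rows,
                           columns=["gene_id", "true_group", "true_category", "status"]),
    )
    return scenario


def simulate_celltype_atlas(
    n_genes: int = 2000,
    n_types: int = 8,
    n_replicates: int = 20,
    marker_fraction: float = 0.10,
    log2_effect: float = 3.0,
    dispersion: float = 0.5,
    restricted_fraction: float = 0.05,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame]:
    """Simulate a replicated cell-type expression atlas with planted markers.

    Baseline expression is log-normal around a per-gene mean; each planted
    marker gene is up-shifted by ``log2_effect`` (log2 units) in its one
    marker type. A ``restricted_fraction`` of genes express in a single
    type only (high-Tau archetypes); an equal fraction are flat broad
    archetypes (low Tau). Truth columns: gene_id, true_marker_types
    (comma-joined), archetype ∈ {background, marker, restricted, broad}.

    Returns (matrix[TPM, cell_type], column-label table, truth).
    """
    if n_types < 2:
        raise ValueError("need at least 2 cell types")
    rng = _spawn(seed, 1)
    types = [f"type{t:02d}" for t in range(n_types)]
    columns = [f"{ct}_rep{r:02d}" for ct in types for r in range(n_replicates)]
    col_type = np.repeat(np.arange(n_types), n_replicates)

    n_marker = round(n_genes * marker_fraction)
    n_restricted = round(n_genes * restricted_fraction)
    n_broad = n_restricted
    gene_ids = [f"SYNG{idx:05d}" for idx in range(n_genes)]

    base_log2 = rng.normal(loc=4.0, scale=1.0, size=n_genes)
    mean_log2 = np.tile(base_log2[:, None], (1, len(columns)))
    truth_rows = []
    for i in range(n_genes):
        if i < n_marker:
            ct = i % n_types
            mean_log2[i, col_type == ct] += log2_effect
            truth_rows.append((gene_ids[i], types[ct], "marker"))
        elif i < n_marker + n_restricted:
            ct = i % n_types
            mean_log2[i, :] = -10.0  # effectively zero outside the one type
            mean_log2[i, col_type == ct] = base_log2[i] + 2.0
            # single-type expression makes these markers of that type too
            truth_rows.append((gene_ids[i], types[ct], "restricted"))
        elif i < n_marker + n_restricted + n_broad:
            truth_rows.append((gene_ids[i], "", "broad"))
        else:
            truth_rows.append((gene_ids[i], "", "background"))

    noise = rng.normal(scale=dispersion, size=mean_log2.shape)
    values = np.exp2(mean_log2 + noise)
    values[mean_log2 <= -10.0] = 0.0  # restricted archetypes are silent off-type

    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=columns),
        unit="TPM",
        condition_kind="cell_type",
    )
    labels = pd.DataFrame(
        {"column_id": columns, "cell_type": [types[t] for t in col_type],
         "broad_type": [types[t] for t in col_type]}
    )
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "true_marker_types", "archetype"])
    return matrix, labels, truth


#: Named archetype curves (log2-TPM over 12 embryo time points) for the
#: whole-embryo time-series generator: maternal decay, an early peak, a
#: middle peak and a late rise — the qualitative shapes of embryonic
#: expression clusters.
DEFAULT_ARCHETYPES = {
    "maternal_decay": [8, 7.5, 6.5, 5.5, 4.5, 3.5, 3, 2.5, 2, 2, 2, 2],
    "early_peak": [3, 5, 7, 8, 7, 5.5, 4, 3, 2.5, 2.5, 2.5, 2.5],
    "middle_peak": [2, 2, 2.5, 3.5, 5, 7, 8, 7, 5, 3.5, 3, 3],
    "late_rise": [1.5, 1.5, 1.5, 2, 2.5, 3, 4, 5, 6, 7, 7.5, 8],
}


def simulate_time_series(
    n_genes_per_archetype: int = 50,
    archetypes: dict[str, list[float]] | None = None,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate a whole-embryo time series from planted archetype curves.

    Each gene is one archetype's log2 curve plus Gaussian noise (sd
    ``noise_sd`` in log2 units), back-transformed to TPM. Truth columns:
    gene_id, true_cluster (the archetype name).
    """
    archetypes = dict(DEFAULT_ARCHETYPES if archetypes is None else archetypes)
    if len(archetypes) < 2:
        raise ValueError("need at least 2 archetypes")
    lengths = {len(v) for v in archetypes.values()}
    if len(lengths) != 1:
        raise ValueError("all archetype curves must have the same number of time points")
    rng = _spawn(seed, 2)
    n_time = lengths.pop()
    columns = [f"t{j:02d}" for j in range(n_time)]
    rows, truth_rows, gene_ids = [], [], []
    idx = 0
    for name, curve in archetypes.items():
        curve = np.asarray(curve, dtype=float)
        for _ in range(n_genes_per_archetype):
            gid = f"SYNG{idx:05d}"
            idx += 1
            log2_profile = curve + rng.normal(scale=noise_sd, size=n_time)
            rows.append(np.exp2(log2_profile))
            gene_ids.append(gid)
            truth_rows.append((gid, name))
    matrix = ExpressionMatrix(
        values=pd.DataFrame(rows, index=pd.Index(gene_ids, name="gene_id"), columns=columns),
        unit="TPM",
        condition_kind="time_point",
    )
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "true_cluster"])
    return matrix, truth


def simulate_pseudotime_series(
    n_genes: int = 150,
    fractions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
    effect_log2: float = 3.0,
    n_bins: int = 8,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate germline pseudotime bins with planted monotone trends.

    ``fractions`` = (increase, decrease, flat). Increasing genes rise
    log-linearly by ``effect_log2`` log2 units from first to last bin,
    decreasing genes fall by the same amount, flat genes stay level; all
    get Gaussian log2 noise of sd ``noise_sd``. Truth columns: gene_id,
    true_trend.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 pseudotime bins")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("trend fractions must sum to 1")
    rng = _spawn(seed, 3)
    n_inc = round(n_genes * fractions[0])
    n_dec = round(n_genes * fractions[1])
    directions = ["increase"] * n_inc + ["decrease"] * n_dec
    directions += ["flat"] * (n_genes - len(directions))
    columns = [f"bin{j:02d}" for j in range(n_bins)]
    ramp = np.linspace(0.0, 1.0, n_bins)
    rows, truth_rows, gene_ids = [], [], []
    for i, direction in enumerate(directions):
        gid = f"SYNG{i:05d}"
        base = 4.0
        slope = {"increase": effect_log2, "decrease": -effect_log2, "flat": 0.0}[direction]
        log2_profile = base + slope * ramp + rng.normal(scale=noise_sd, size=n_bins)
        rows.append(np.exp2(log2_profile))
        gene_ids.append(gid)
        truth_rows.append((gid, direction))
    matrix = ExpressionMatrix(
        values=pd.DataFrame(rows, index=pd.Index(gene_ids, name="gene_id"), columns=columns),
        unit="TPM",
        condition_kind="pseudotime_bin",
    )
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "true_trend"])
    return matrix, truth


def simulate_half_lives(
    group_medians: dict[str, float] | None = None,
    n_per_group: int = 200,
    lognormal_sd: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an mRNA-decay atlas with planted per-group median half-lives.

    Half-lives are log-normal with median exactly the planted value
    (log-normal median = exp(mu)). Default medians echo the contrast of
    interest in embryonic decay data: long-lived sequence-specific RBP
    transcripts (45 min) vs shorter-lived TF (30 min) and bulk (35 min)
    transcripts. Truth columns: gene_id, true_half_life_group.

    Returns (half-life table, truth).
    """
    medians = {"group1": 45.0, "tf": 30.0, "other": 35.0} if group_medians is None else group_medians
    rng = _spawn(seed, 4)
    rows, truth_rows = [], []
    idx = 0
    for label in sorted(medians):
        median = float(medians[label])
        if median <= 0:
            raise ValueError(f"median half-life must be positive, got {median} for {label!r}")
        draws = median * np.exp(rng.normal(scale=lognormal_sd, size=n_per_group))
        for val in draws:
            gid = f"SYNG{idx:05d}"
            idx += 1
            rows.append((gid, float(val)))
            truth_rows.append((gid, label))
    half_lives = pd.DataFrame(rows, columns=["gene_id", "half_life"])
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "true_half_life_group"])
    return half_lives, truth


# ---------------------------------------------------------------------------
# Scenario writer
# ---------------------------------------------------------------------------

def write_scenario(outdir, seed: int = 0, n_genes: int = 500) -> Path:
    """Write a full synthetic scenario (inputs + truth + manifest) to disk.

    The directory is consumable by the pipeline's ``run``/``build``
    subcommands; returns the manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scen = simulate_proteome(n_genes=n_genes, seed=seed)
    scen.registry.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    scen.domain_hits.to_csv(outdir / "domain_hits.tsv", sep="\t", index=False)
    pd.Series(scen.tf_ids, name="gene_id").to_csv(outdir / "tf_list.tsv", sep="\t", index=False)
    scen.legacy.to_csv(outdir / "legacy_compendium.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"old_name": list(scen.name_map), "gene_id": list(scen.name_map.values())}
    ).to_csv(outdir / "name_map.tsv", sep="\t", index=False)
    scen.truth.to_csv(outdir / "truth_proteome.tsv", sep="\t", index=False)

    atlas, labels, atlas_truth = simulate_celltype_atlas(n_genes=min(n_genes, 500),
                                                         n_replicates=5, seed=seed)
    atlas.to_tsv(outdir / "celltype_expression.tsv")
    labels.to_csv(outdir / "celltype_labels.tsv", sep="\t", index=False)
    atlas_truth.to_csv(outdir / "truth_celltype.tsv", sep="\t", index=False)

    series, series_truth = simulate_time_series(seed=seed)
    series.to_tsv(outdir / "time_series.tsv")
    series_truth.to_csv(outdir / "truth_time_series.tsv", sep="\t", index=False)

    pseudo, pseudo_truth = simulate_pseudotime_series(seed=seed)
    pseudo.to_tsv(outdir / "pseudotime.tsv")
    pseudo_truth.to_csv(outdir / "truth_pseudotime.tsv", sep="\t", index=False)

    # Half-lives keyed to the proteome's planted categories, so the
    # pipeline's per-category medians recover the planted contrast.
    hl_medians = {"group1": 45.0, "group2": 40.0, "group3": 38.0, "group4": 50.0,
                  "tf": 30.0, "other": 35.0}
    hl_rng = _spawn(seed, 5)
    live = scen.truth[scen.truth.status == "live"]
    half_lives = pd.DataFrame(
        {
            "gene_id": live.gene_id.to_numpy(),
            "half_life": [
                float(hl_medians[cat] * np.exp(hl_rng.normal(scale=0.5)))
                for cat in live.true_category
            ],
        }
    )
    hl_truth = pd.DataFrame(
        {"gene_id": live.gene_id.to_numpy(), "true_half_life_group": live.true_category.to_numpy()}
    )
    half_lives.to_csv(outdir / "half_lives.tsv", sep="\t", index=False)
    hl_truth.to_csv(outdir / "truth_half_lives.tsv", sep="\t", index=False)

    manifest = {
        "seed": int(seed),
        "inputs": {
            "registry": "genes.tsv",
            "domain_hits": "domain_hits.tsv",
            "tf_list": "tf_list.tsv",
            "legacy": "legacy_compendium.tsv",
            "name_map": "name_map.tsv",
            "celltype_expression": "celltype_expression.tsv",
            "celltype_labels": "celltype_labels.tsv",
            "time_series": "time_series.tsv",
            "pseudotime": "pseudotime.tsv",
            "half_lives": "half_lives.tsv",
        },
        "params": {},
    }
    manifest_path = outdir / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    return manifest_path
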