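"""Readers and normalizers for all tabular inputs.

Every input is a UTF-8, tab-separated table with a header row; "." or the
empty string mark missing values. All joins key on the stable gene_id;
public names are display-only. Readers fail loudly on malformed input and
never silently coerce.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import normalize_source

logger = logging.getLogger(__name__)

GENE_STATUSES = frozenset({"live", "dead", "transposon"})
CONDITION_KINDS = frozenset({"cell_type", "time_point", "pseudotime_bin", "stage"})
EXPRESSION_UNITS = frozenset({"TPM", "RPKM"})

_NA_VALUES = [".", ""]


class ParseError(ValueError):
    """Raised when an input table violates its contract."""


def _read_tsv(path, required: tuple[str, ...], dtype=None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=dtype, na_values=_NA_VALUES, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")
    return df


# ---------------------------------------------------------------------------
# Gene metadata
# ---------------------------------------------------------------------------

def read_gene_table(path) -> pd.DataFrame:
    """Read a gene-metadata table (gene_id, public_name, biotype, status).

    Biotype and status are normalized to closed vocabularies
    ({protein_coding, other} and {live, dead, transposon}); duplicate
    gene_ids are an error.
    """
    df = _read_tsv(path, ("gene_id", "public_name", "biotype", "status"), dtype=str)
    df["biotype"] = df["biotype"].str.strip().str.lower()
    df["biotype"] = np.where(df["biotype"] == "protein_coding", "protein_coding", "other")
    df["status"] = df["status"].str.strip().str.lower()
    bad_status = sorted(set(df["status"]) - GENE_STATUSES)
    if bad_status:
        raise ParseError(f"{path}: unknown gene status value(s) {bad_status}")
    dupes = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
    if dupes:
        raise ParseError(f"{path}: duplicate gene_id rows: {sorted(set(dupes))}")
    return df.reset_index(drop=True)


def read_domain_hits(path) -> pd.DataFrame:
    """Read an InterPro-style domain dump; dedupe and normalize sources.

    Unknown source databases map to "other" (and will never qualify a hit);
    (gene_id, protein_id, domain_accession, source_db) tuples are
    deduplicated on ingest.
    """
    df = _read_tsv(
        path, ("gene_id", "protein_id", "domain_accession", "domain_name", "source_db"), dtype=str
    )
    df["source_db"] = df["source_db"].map(normalize_source)
    df = df.drop_duplicates(["gene_id", "protein_id", "domain_accession", "source_db"])
    return df.reset_index(drop=True)


def read_gene_list(path) -> list[str]:
    """Read a one-column gene list (header ``gene_id`` or headerless)."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, na_values=_NA_VALUES,
                     keep_default_na=False)
    names = df.iloc[:, 0].dropna().tolist()
    if names and names[0] == "gene_id":
        names = names[1:]
    return names


def read_legacy_compendium(path) -> pd.DataFrame:
    """Read a legacy compendium table (columns gene_name, group)."""
    df = _read_tsv(path, ("gene_name", "group"))
    df["group"] = df["group"].astype(int)
    bad = sorted(set(df["group"]) - {1, 2, 3, 4})
    if bad:
        raise ParseError(f"{path}: legacy group values outside 1-4: {bad}")
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """A genes x conditions abundance table with declared unit and kind.

    ``values`` is a DataFrame indexed by gene_id with condition columns;
    abundances are non-negative, in a single unit (TPM or RPKM), and the
    condition kind records what the columns are (cell types, time points,
    pseudotime bins, or life-cycle stages).
    """

    values: pd.DataFrame
    unit: str
    condition_kind: str

    def __post_init__(self) -> None:
        if self.unit not in EXPRESSION_UNITS:
            raise ParseError(f"unknown expression unit {self.unit!r}; expected one of {sorted(EXPRESSION_UNITS)}")
        if self.condition_kind not in CONDITION_KINDS:
            raise ParseError(
                f"unknown condition kind {self.condition_kind!r}; expected one of {sorted(CONDITION_KINDS)}"
            )
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ParseError(f"duplicate gene ids in expression matrix: {dupes}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ParseError(f"duplicate condition ids in expression matrix: {dupes}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ParseError("expression matrix contains non-numeric values")
        if np.isnan(arr).any():
            raise ParseError("expression matrix contains missing values")
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ParseError(
                f"negative abundance at gene {self.values.index[i]!r}, condition {self.values.columns[j]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def condition_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path) -> None:
        self.values.rename_axis("gene_id").to_csv(path, sep="\t")


def read_expression_matrix(path, unit: str, condition_kind: str) -> ExpressionMatrix:
    """Read a genes x conditions TSV (first column gene ids, rest numeric)."""
    raw = pd.read_csv(path, sep="\t", dtype=str, na_values=_NA_VALUES, keep_default_na=False)
    if raw.shape[0] == 0:
        raise ParseError(f"{path}: no data rows")
    if raw.shape[1] < 2:
        raise ParseError(f"{path}: expected a gene-id column plus at least one condition column")
    values = raw.set_index(raw.columns[0])
    for col in values.columns:
        try:
            values[col] = values[col].astype(float)
        except ValueError:
            bad = values[col][pd.to_numeric(values[col], errors="coerce").isna()]
            raise ParseError(
                f"{path}: non-numeric cell at gene {bad.index[0]!r}, column {col!r}: {bad.iloc[0]!r}"
            ) from None
    values.index.name = "gene_id"
    return ExpressionMatrix(values=values, unit=unit, condition_kind=condition_kind)


# ---------------------------------------------------------------------------
# Flags, half-lives, name maps, cell-type labels
# ---------------------------------------------------------------------------

def read_flag_table(path) -> pd.DataFrame:
    """Read a per-gene boolean flag table (gene_id, flag_name, value)."""
    df = _read_tsv(path, ("gene_id", "flag_name", "value"), dtype=str)
    mapping = {"true": True, "false": False, "1": True, "0": False}
    vals = df["value"].str.strip().str.lower().map(mapping)
    if vals.isna().any():
        bad = df.loc[vals.isna(), "value"].iloc[0]
        raise ParseError(f"{path}: non-boolean flag value {bad!r}")
    df["value"] = vals.astype(bool)
    if df.duplicated(["gene_id", "flag_name"]).any():
        raise ParseError(f"{path}: duplicate (gene_id, flag_name) rows")
    return df.reset_index(drop=True)


def read_half_life_table(path) -> pd.DataFrame:
    """Read a per-gene mRNA half-life table (gene_id, half_life in minutes)."""
    df = _read_tsv(path, ("gene_id", "half_life"))
    df["half_life"] = df["half_life"].astype(float)
    if not np.isfinite(df["half_life"]).all() or (df["half_life"] <= 0).any():
        raise ParseError(f"{path}: half-lives must be finite and positive")
    if df["gene_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate gene_id rows")
    return df.reset_index(drop=True)


def read_name_map(path) -> dict[str, str]:
    """Read an old_name -> current gene_id map; each old name maps to <=1 id."""
    df = _read_tsv(path, ("old_name", "gene_id"), dtype=str)
    if df["old_name"].duplicated().any():
        dupes = df.loc[df["old_name"].duplicated(), "old_name"].tolist()
        raise ParseError(f"{path}: old names mapped more than once: {sorted(set(dupes))}")
    return dict(zip(df["old_name"], df["gene_id"]))


def read_cell_type_labels(path) -> pd.DataFrame:
    """Read column_id -> cell_type (and optional broad_type) labels."""
    df = _read_tsv(path, ("column_id", "cell_type"), dtype=str)
    if "broad_type" not in df.columns:
        df["broad_type"] = df["cell_type"]
    return df.reset_index(drop=True)


@dataclass
class NameMapReport:
    """Outcome of resolving a list of gene names against the registry."""

    mapped: dict[str, str] = field(default_factory=dict)
    unmapped: list[str] = field(default_factory=list)
    dropped: list[tuple[str, str, str]] = field(default_factory=list)  # (name, gene_id, status)


def apply_name_map(
    names: list[str], name_map: dict[str, str], registry: pd.DataFrame
) -> NameMapReport:
    """Resolve gene names to live gene_ids via the registry and a name map.

    A name resolves if it already is a registry gene_id, matches a registry
    public_name uniquely, or has a name-map entry; names resolving to dead
    or transposon-origin genes are dropped (and logged), everything else is
    reported unmapped. Idempotent: resolved ids resolve to themselves.
    """
    status_by_id = dict(zip(registry["gene_id"], registry["status"]))
    public = registry["public_name"].dropna()
    by_public = {
        name: gid
        for name, gid in zip(public, registry.loc[public.index, "gene_id"])
        if (public == name).sum() == 1
    }
    report = NameMapReport()
    for name in names:
        gid = None
        if name in status_by_id:
            gid = name
        elif name in name_map:
            gid = name_map[name]
        elif name in by_public:
            gid = by_public[name]
        if gid is None or gid not in status_by_id:
            report.unmapped.append(name)
            continue
        status = status_by_id[gid]
        if status != "live":
            report.dropped.append((name, gid, status))
            logger.info("dropping %s -> %s (status %s)", name, gid, status)
        else:
            report.mapped[name] = gid
    return report
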