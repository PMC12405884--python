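"""Catalog of RNA-binding-domain (RBD) families and domain-evidence matching.

RBP prediction here is a declarative rule engine: a gene is called an RBP
when at least one of its protein isoforms carries a domain hit that (a)
matches one of the 17 RBD families in the catalog and (b) was identified by
one of the accepted source databases (Pfam, SMART, Superfamily, ProSite).
Each family belongs to one of four tiers:

    1 — gene- and RNA-sequence-specific binders
        (RRM, KH, PUF, CCCH, CCHC, DSRBD, RGG Box, La)
    2 — gene-specific, RNA-nonspecific binders
        (Helicase, PAZ, PIWI, Argonaute, NTF2)
    3 — ambiguous DNA/RNA/protein binders (C2H2, SAM, Cold shock)
    4 — non-gene-specific binders (Sm/Lsm)

The default catalog ships as a YAML resource; the accession lists are a
curated approximation of what annotation databases emit for each family and
are fully user-overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd
import yaml

#: Source databases whose domain calls qualify a hit as evidence.
QUALIFYING_SOURCES = frozenset({"Pfam", "SMART", "Superfamily", "ProSite"})

#: Canonical spellings for source databases, keyed by lowercase form.
_SOURCE_ALIASES = {
    "pfam": "Pfam",
    "smart": "SMART",
    "superfamily": "Superfamily",
    "ssf": "Superfamily",
    "prosite": "ProSite",
    "prosite_profiles": "ProSite",
    "prosite_patterns": "ProSite",
    "profile": "ProSite",
}

#: The fixed family -> group tier mapping of the default 17-family catalog.
DEFAULT_FAMILY_GROUPS = {
    "RRM": 1, "KH": 1, "PUF": 1, "CCCH": 1, "CCHC": 1, "DSRBD": 1,
    "RGG Box": 1, "La": 1,
    "Helicase": 2, "PAZ": 2, "PIWI": 2, "Argonaute": 2, "NTF2": 2,
    "C2H2": 3, "SAM": 3, "Cold shock": 3,
    "Sm/Lsm": 4,
}


class CatalogError(ValueError):
    """Raised when a catalog config fails validation."""


def normalize_source(source: str) -> str:
    """Map a free-text source-database string onto the closed vocabulary.

    Unknown databases map to ``"other"`` and never qualify a hit.
    """
    return _SOURCE_ALIASES.get(str(source).strip().lower(), "other")


@dataclass(frozen=True)
class RBDFamily:
    """One RBD family: its tier, accession patterns and accepted sources.

    ``accessions`` are matched exactly against ``domain_accession``;
    ``name_patterns`` are matched case-insensitively as substrings of
    ``domain_name``.
    """

    name: str
    group: int
    accessions: tuple[str, ...]
    name_patterns: tuple[str, ...] = ()
    sources: frozenset[str] = field(default_factory=lambda: QUALIFYING_SOURCES)

    def __post_init__(self) -> None:
        if self.group not in (1, 2, 3, 4):
            raise CatalogError(f"family {self.name!r}: group must be 1-4, got {self.group!r}")
        if not self.accessions and not self.name_patterns:
            raise CatalogError(f"family {self.name!r}: needs at least one accession or name pattern")
        if not self.sources:
            raise CatalogError(f"family {self.name!r}: needs at least one allowed source")
        bad = set(self.sources) - QUALIFYING_SOURCES
        if bad:
            raise CatalogError(f"family {self.name!r}: unknown sources {sorted(bad)}")

    def matches(self, domain_accession: str, domain_name: str, source_db: str) -> bool:
        """True if a single (accession, name, source) hit is evidence for this family."""
        if source_db not in self.sources:
            return False
        if str(domain_accession).strip() in self.accessions:
            return True
        name = str(domain_name).strip().lower()
        return any(pat in name for pat in self.name_patterns)


def _family_from_config(entry: Mapping, index: int) -> RBDFamily:
    if not isinstance(entry, Mapping):
        raise CatalogError(f"family entry #{index}: expected a mapping, got {type(entry).__name__}")
    try:
        name = str(entry["name"])
        group = int(entry["group"])
    except KeyError as exc:
        raise CatalogError(f"family entry #{index}: missing required field {exc.args[0]!r}") from None
    accessions = tuple(str(a).strip() for a in entry.get("accessions", []))
    patterns = tuple(str(p).strip().lower() for p in entry.get("name_patterns", []))
    sources = entry.get("sources", sorted(QUALIFYING_SOURCES))
    return RBDFamily(
        name=name,
        group=group,
        accessions=accessions,
        name_patterns=patterns,
        sources=frozenset(normalize_source(s) for s in sources),
    )


def load_catalog(config: Mapping | str | None = None) -> list[RBDFamily]:
    """Load and validate an RBD-family catalog.

    Parameters
    ----------
    config
        ``None`` for the built-in 17-family default, a path to a YAML file,
        or an already-parsed mapping with a top-level ``families`` list.

    Returns
    -------
    list of RBDFamily, in config order. Duplicate family names are rejected.
    """
    if config is None:
        text = resources.files("rbpcompendium.data").joinpath("default_catalog.yaml").read_text()
        config = yaml.safe_load(text)
    elif isinstance(config, str):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, Mapping) or "families" not in config:
        raise CatalogError("catalog config must be a mapping with a 'families' list")
    families = [_family_from_config(entry, i) for i, entry in enumerate(config["families"])]
    seen: set[str] = set()
    for fam in families:
        if fam.name in seen:
            raise CatalogError(f"duplicate family name {fam.name!r} in catalog config")
        seen.add(fam.name)
    return families


def family_group_map(catalog: Iterable[RBDFamily]) -> dict[str, int]:
    """Family name -> group tier for a validated catalog."""
    return {fam.name: fam.group for fam in catalog}


def match_gene_domains(
    hits: pd.DataFrame, catalog: Iterable[RBDFamily] | None = None
) -> dict[str, set[str]]:
    """Match per-gene domain evidence against the RBD catalog.

    A gene matches a family iff any of its hits (on any isoform) matches one
    of the family's accession patterns AND comes from one of the family's
    allowed source databases. Genes with no matching family are absent from
    the result, so the output's keys are exactly the putative RBP genes.

    Parameters
    ----------
    hits
        DataFrame with columns gene_id, protein_id, domain_accession,
        domain_name, source_db (as produced by ``io.read_domain_hits``).
    catalog
        Validated family list; defaults to the built-in catalog.

    Returns
    -------
    dict mapping gene_id -> set of matched family names.
    """
    if catalog is None:
        catalog = load_catalog()
    catalog = list(catalog)
    out: dict[str, set[str]] = {}
    if len(hits) == 0:
        return out
    # Deduplicate (accession, name, source) per gene: isoforms collapse to
    # gene level, and repeated hits cannot add families (monotonicity).
    dedup = hits.drop_duplicates(["gene_id", "domain_accession", "domain_name", "source_db"])
    for row in dedup.itertuples(index=False):
        for fam in catalog:
            if fam.matches(row.domain_accession, row.domain_name, row.source_db):
                out.setdefault(row.gene_id, set()).add(fam.name)
    return out
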