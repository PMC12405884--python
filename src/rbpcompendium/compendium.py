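"""Assemble the classified RBP compendium and resolve analysis categories.

A gene enters the compendium when it is live, protein-coding, and either
carries current domain evidence for one of the catalog families or was a
member of the legacy compendium (after its name survives the genome-build
merge). Genes whose domains span several group tiers keep the full
membership set for audit, but the exclusive assigned group follows the
precedence 1 > 2 > 3 > 4: the most sequence-specific tier wins.

Category resolution then reconciles the compendium with a transcription
factor (TF) list to form mutually exclusive analysis sets:

* group-1 genes that are also TFs stay RBPs only if they carry a CCCH
  zinc-finger domain (well-characterized RNA-binding regulators);
  otherwise they are counted as TFs,
* group-2 genes that are also TFs are counted as TFs,
* group 3 is by definition ambiguous between DNA and RNA binding, so
  putative TFs stay in group 3,
* group-4 TF overlaps stay group 4 (housekeeping RBP cores), flagged,
* TFs that are not RBPs form the exclusive TF set; everything else that is
  live and protein-coding is "other".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .catalog import RBDFamily, family_group_map, load_catalog
from .io import NameMapReport, apply_name_map

logger = logging.getLogger(__name__)

GROUP_PRECEDENCE = (1, 2, 3, 4)
ANALYSIS_CATEGORIES = ("group1", "group2", "group3", "group4", "tf", "other")


@dataclass
class CompendiumEntry:
    """One classified compendium row."""

    gene_id: str
    matched_families: frozenset[str]
    group_memberships: frozenset[int]
    assigned_group: int
    legacy_member: bool = False
    tf_overlap: bool = False
    analysis_category: str | None = None


def assign_group(
    families: Iterable[str],
    legacy_group: int | None = None,
    catalog: Iterable[RBDFamily] | None = None,
) -> tuple[frozenset[int], int]:
    """Map matched family names to group memberships and an exclusive group.

    Memberships are the image of the families under the catalog's
    family->group map, plus the legacy group when the gene has one; the
    assigned group is the minimum under the precedence 1 < 2 < 3 < 4.

    Raises ``ValueError`` when there is neither domain evidence nor a
    legacy group — such a gene is not a compendium member.
    """
    groups = family_group_map(catalog if catalog is not None else load_catalog())
    memberships = {groups[f] for f in families if f in groups}
    unknown = [f for f in families if f not in groups]
    if unknown:
        raise ValueError(f"families not in catalog: {sorted(unknown)}")
    if legacy_group is not None:
        memberships.add(int(legacy_group))
    if not memberships:
        raise ValueError("no domain evidence and no legacy group: not a compendium member")
    return frozenset(memberships), min(memberships)


def build_compendium(
    registry: pd.DataFrame,
    domain_matches: Mapping[str, set[str]],
    legacy: pd.DataFrame | None = None,
    name_map: Mapping[str, str] | None = None,
    catalog: Iterable[RBDFamily] | None = None,
) -> tuple[list[CompendiumEntry], NameMapReport]:
    """Build the compendium from domain matches plus the legacy member list.

    Parameters
    ----------
    registry
        Gene metadata table (gene_id, public_name, biotype, status).
    domain_matches
        gene_id -> matched family names, from ``catalog.match_gene_domains``.
    legacy
        Optional legacy compendium (gene_name, group); names are merged to
        the current build through ``name_map`` and the registry, and dead or
        transposon-origin genes are dropped.
    """
    catalog = list(catalog) if catalog is not None else load_catalog()
    legacy_groups: dict[str, int] = {}
    report = NameMapReport()
    if legacy is not None and len(legacy):
        report = apply_name_map(list(legacy["gene_name"]), dict(name_map or {}), registry)
        group_by_name = dict(zip(legacy["gene_name"], legacy["group"]))
        for name, gid in report.mapped.items():
            legacy_groups[gid] = min(int(group_by_name[name]), legacy_groups.get(gid, 4))

    eligible = registry[(registry["status"] == "live") & (registry["biotype"] == "protein_coding")]
    eligible_ids = set(eligible["gene_id"])
    skipped = sorted((set(domain_matches) | set(legacy_groups)) - eligible_ids)
    if skipped:
        logger.info("excluding %d non-live/non-coding genes from compendium", len(skipped))

    entries: list[CompendiumEntry] = []
    for gene_id in eligible["gene_id"]:
        families = frozenset(domain_matches.get(gene_id, set()))
        legacy_group = legacy_groups.get(gene_id)
        if not families and legacy_group is None:
            continue
        memberships, assigned = assign_group(families, legacy_group, catalog)
        entries.append(
            CompendiumEntry(
                gene_id=gene_id,
                matched_families=families,
                group_memberships=memberships,
                assigned_group=assigned,
                legacy_member=legacy_group is not None,
            )
        )
    return entries, report


def resolve_categories(
    entries: Iterable[CompendiumEntry],
    tf_gene_ids: set[str],
    tf_overlap_group4_stays: bool = True,
) -> list[CompendiumEntry]:
    """Fill each entry's exclusive analysis category against the TF list.

    Returns new entries (pure function of the inputs; input order is
    irrelevant). The resulting ``tf`` category never contains a compendium
    gene — TF/RBP overlaps are resolved into an RBP group or out of group 1
    and 2 into ``tf``.
    """
    resolved = []
    for e in entries:
        is_tf = e.gene_id in tf_gene_ids
        group = e.assigned_group
        if not is_tf:
            category = f"group{group}"
        elif group == 1:
            category = "group1" if "CCCH" in e.matched_families else "tf"
        elif group == 2:
            category = "tf"
        elif group == 3:
            category = "group3"
        else:  # group 4 housekeeping cores
            category = "group4" if tf_overlap_group4_stays else "tf"
        resolved.append(
            CompendiumEntry(
                gene_id=e.gene_id,
                matched_families=e.matched_families,
                group_memberships=e.group_memberships,
                assigned_group=group,
                legacy_member=e.legacy_member,
                tf_overlap=is_tf,
                analysis_category=category,
            )
        )
    return resolved


def category_map(
    registry: pd.DataFrame,
    entries: Iterable[CompendiumEntry],
    tf_gene_ids: set[str],
) -> pd.Series:
    """Assign every live protein-coding gene to one exclusive category.

    The categories {group1..group4, tf, other} partition the live
    protein-coding gene set: compendium genes keep their resolved category
    (genes resolved out of groups 1-2 count as ``tf``), remaining TFs are
    ``tf``, everything else is ``other``.
    """
    eligible = registry[(registry["status"] == "live") & (registry["biotype"] == "protein_coding")]
    cats = pd.Series("other", index=pd.Index(eligible["gene_id"], name="gene_id"), name="category")
    cats[cats.index.isin(tf_gene_ids)] = "tf"
    for e in entries:
        if e.analysis_category is None:
            raise ValueError("entries must be category-resolved; run resolve_categories first")
        if e.gene_id in cats.index:
            cats[e.gene_id] = e.analysis_category
    return cats


def entries_to_frame(entries: Iterable[CompendiumEntry]) -> pd.DataFrame:
    """Serialize entries to a flat table (sets as comma-joined sorted tokens)."""
    rows = [
        {
            "gene_id": e.gene_id,
            "matched_families": ",".join(sorted(e.matched_families)),
            "group_memberships": ",".join(str(g) for g in sorted(e.group_memberships)),
            "assigned_group": e.assigned_group,
            "legacy_member": e.legacy_member,
            "tf_overlap": e.tf_overlap,
            "analysis_category": e.analysis_category or "",
        }
        for e in entries
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "matched_families", "group_memberships", "assigned_group",
            "legacy_member", "tf_overlap", "analysis_category",
        ],
    ).sort_values("gene_id").reset_index(drop=True)


def frame_to_entries(df: pd.DataFrame) -> list[CompendiumEntry]:
    """Inverse of ``entries_to_frame``."""
    entries = []
    for row in df.itertuples(index=False):
        fams = frozenset(f for f in str(row.matched_families).split(",") if f)
        groups = frozenset(int(g) for g in str(row.group_memberships).split(",") if g)
        entries.append(
            CompendiumEntry(
                gene_id=row.gene_id,
                matched_families=fams,
                group_memberships=groups,
                assigned_group=int(row.assigned_group),
                legacy_member=bool(row.legacy_member),
                tf_overlap=bool(row.tf_overlap),
                analysis_category=str(row.analysis_category) or None,
            )
        )
    return entries


def diff_compendia(
    old: Iterable[CompendiumEntry], new: Iterable[CompendiumEntry]
) -> dict[int, dict[str, list[str]]]:
    """Per-group added/removed gene lists between two compendium versions."""
    old_by_group: dict[int, set[str]] = {g: set() for g in GROUP_PRECEDENCE}
    new_by_group: dict[int, set[str]] = {g: set() for g in GROUP_PRECEDENCE}
    for e in old:
        old_by_group[e.assigned_group].add(e.gene_id)
    for e in new:
        new_by_group[e.assigned_group].add(e.gene_id)
    return {
        g: {
            "added": sorted(new_by_group[g] - old_by_group[g]),
            "removed": sorted(old_by_group[g] - new_by_group[g]),
        }
        for g in GROUP_PRECEDENCE
    }


def group_sizes(entries: Iterable[CompendiumEntry]) -> dict[int, int]:
    """Number of compendium members per exclusive assigned group."""
    sizes = {g: 0 for g in GROUP_PRECEDENCE}
    for e in entries:
        sizes[e.assigned_group] += 1
    return sizes
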