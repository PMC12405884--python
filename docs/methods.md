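# Methods

This note documents the models and procedures implemented in
`rbpcompendium`, the defaults they ship with, and what the synthetic
benchmarks do and do not establish.

## Domain-rule RBP prediction

A proteome is classified from InterPro-style domain annotation dumps. The
catalog holds 17 RNA-binding-domain (RBD) families in four tiers:

| group | interpretation | families |
|---|---|---|
| 1 | gene- and RNA-sequence-specific | RRM, KH, PUF, CCCH, CCHC, DSRBD, RGG Box, La |
| 2 | gene-specific, RNA-nonspecific | Helicase, PAZ, PIWI, Argonaute, NTF2 |
| 3 | ambiguous DNA/RNA/protein binders | C2H2, SAM, Cold shock |
| 4 | non-gene-specific | Sm/Lsm |

A domain hit is evidence for a family only when its source database is one
of Pfam, SMART, Superfamily or ProSite; hits from any other source are
ignored. A gene matches a family when any of its protein isoforms carries
a qualifying hit, since classification is at the gene level. Matching is by
exact accession or by case-insensitive substring on the domain name; the
shipped accession lists are a curated approximation of how annotation
databases name each family and are user-overridable via a YAML catalog of
the same shape — the family set and tier structure are the fixed part, the
accession vocabulary is not.

Genes with domains in several tiers are assigned the *smallest* group
number (group memberships are retained for audit). The tie rule is a
design choice: tier 1 is the most sequence-specific interpretation, and an
exclusive assignment is required for the per-group set sizes to sum to the
compendium total — an invariant the package checks on every build.

Group 4 membership has a second, homology-based route that is not
computable from domain content alone (ribosomal proteins, tRNA
synthetases); the package models it as legacy-compendium membership:
group 4 = Sm/Lsm matches ∪ legacy group-4 members whose names survive the
genome-build merge.

### Legacy merge

Legacy compendium names are resolved against the current gene registry
through (in order) identity, an explicit old-name→id map, and unique
public names. Ambiguous names (one old name, several candidates) are
reported unmapped rather than guessed. Genes resolving to dead or
transposon-origin entries are dropped and logged; they never enter the
compendium.

### TF-overlap resolution

Analysis categories {group1..group4, tf, other} partition the live
protein-coding gene set. Overlaps between the RBP compendium and the TF
list resolve as: group-1 overlaps stay RBPs only with a CCCH domain
(CCCH zinc-finger proteins are well-characterized RNA-binding regulators
of early embryogenesis); group-2 overlaps count as TFs; group 3 keeps its
TFs (the tier is defined by DNA/RNA ambiguity); group-4 overlaps stay
group 4 with a `tf_overlap` flag (configurable — the rule for
housekeeping cores is genuinely open, and flagged retention keeps the
audit trail). The exclusive `tf` category therefore contains no gene of
any RBP group.

## Expression analytics

**Tau specificity.** Tau = Σᵢ(1 − xᵢ/maxⱼxⱼ)/(N − 1) over N conditions:
0 for uniform expression, 1 for single-condition expression. Tau is
undefined (NaN) for all-zero genes, and requires ≥ 2 conditions. Genes are
kept for Tau reporting only when they reach ≥ 5 TPM at some stage of a
whole-embryo time series (a detection filter, inclusive as printed); broad
expression is Tau < 0.4. Replicated atlases are collapsed to per-type
means before scoring.

**Marker calling.** Per (gene, cell type): log2 fold change of in-type vs
out-of-type mean expression with a pseudocount of 1 on both means, and a
two-sided Wilcoxon rank-sum test of in-type vs out-of-type values (normal
approximation with midranks; at the default 20-vs-140 column split the
exact distribution is unnecessary). P-values are Benjamini–Hochberg
corrected across *all* (gene, type) tests. A marker requires
log2FC ≥ 1.5 (inclusive) and adjusted p < 0.05 (strict). The rank-sum
statistic is a design choice where the upstream atlas procedure is
pluggable; the 1.5 threshold is in log2 units (≈ 2.8-fold).

**Temporal clustering.** Profiles are standardized per gene (mean 0, sd 1,
sample sd as in R's `scale`), pairwise distance is d = 1 − Pearson r, and
the tree (complete linkage by default, configurable and recorded in run
metadata) is cut at k = 10 clusters, after which the 2 smallest clusters
are dropped, leaving 8 — defaults matching the embryonic time-course
analysis this pipeline reproduces. Retained clusters are relabelled in
order of the peak time of their mean standardized profile, so labels are
comparable across runs. Zero-variance rows cannot enter the Pearson
distance and are excluded with a logged warning (cluster_id −1) rather
than failing the run. Standardization makes the clustering invariant to
per-row affine rescaling of the raw input.

**Pseudotime trends.** Per gene, log₂((last + 1)/(first + 1)) over ordered
pseudotime bins; "increase" at ≥ +1, "decrease" at ≤ −1, else "flat". The
±1 log2 threshold (a two-fold change) is a package default exposed as a
parameter — no numeric criterion is canonical, and intermediate bins are
deliberately ignored so the call matches the first-to-last contrast it
names.

**Maternal vs zygotic-only.** A gene is maternal when whole-embryo 1-cell
TPM ≥ 10 *or* single-cell 1-cell mean RPKM ≥ 20 (both inclusive); all
other genes are zygotic-only. The two matrices keep their declared units
and are never mixed; genes absent from one input count as 0 there, so the
calls partition the union of the inputs.

**Heatmap preparation.** log₂(x + 1), optionally row-centered, or row
z-scores; rows are ordered by hierarchical clustering of the transformed
matrix under the same correlation distance. The log2 modes are invertible
given the recorded pseudocount.

## Category statistics

**Flag proportions.** Per category × flag, a 2×2 chi-square of the
category against the all-protein-coding background (which includes the
category under test, the convention of proportion-bar comparisons against
"all genes"; an exclusive background is available). The statistic is the
classical Σ(O−E)²/E with 1 df and no continuity correction by default
(Yates optional and recorded); a zero expected count yields NaN with a
warning rather than a fabricated p. No multiplicity correction is applied
across the panel of categories × flags; each test is reported as-is.

**Half-life comparisons.** Per-category n and median over measured genes
only; pairwise two-sided Wilcoxon rank-sum tests. For pooled sample sizes
≤ 12 (configurable) the p-value is exact by full enumeration of the
C(n, n₁) midrank assignments — this handles ties, and two identical
samples give p = 1 exactly; larger samples use the normal approximation
with tie-corrected variance. The exact two-sided p is
P(|W − E[W]| ≥ |w − E[W]|), which coincides with the doubled one-sided
tail because the null distribution of the rank sum is symmetric.

**Median scaled expression.** Genes standardized as in clustering, then
the per-time-point median across the gene set; sets with fewer than two
usable genes are skipped with a warning.

## Synthetic data

Every input has a seeded generator that writes the same TSV schemas the
readers consume plus a ground-truth table. One scenario seed drives all
generators through deterministically derived sub-streams, so a scenario
is reproducible piecewise and whole-pipeline reruns are byte-identical.

* **Proteome** (default n = 500): genes are planted as group-1..4 RBPs
  (fractions 0.12/0.07/0.12/0.13), TF-only (0.15), background, and 5%
  dead/transposon; 10% of RBP genes also appear in the TF list and 10%
  carry a second domain from a different tier (truth = precedence
  winner). The composition compresses a ~20k-gene proteome with ~900 RBPs
  and ~900 TFs so every category is well-populated at n = 500.
  Disqualified-source hits and decoy domains are salted in; dead genes
  carry qualifying hits so removal is actually exercised. Planted truth
  (group and exclusive category) is computed at generation time from the
  planted role, independently of the classifier.
* **Cell-type atlas** (default 2000 genes × 8 types × 20 replicates):
  log-normal baseline (log2 mean 4, sd 1 across genes; residual sd 0.5),
  markers up-shifted by 3 log2 units in their one type; single-type
  "restricted" archetypes (markers of that type by construction, Tau → 1)
  and flat "broad" archetypes round out the Tau spectrum.
* **Time series**: four archetype curves over 12 time points — maternal
  decay, early peak, middle peak, late rise — plus Gaussian log2 noise
  (default sd 0.3), back-transformed to TPM.
* **Pseudotime**: log-linear ±3-log2 ramps or flat profiles over 8 bins,
  log2 noise sd 0.2.
* **Half-lives**: log-normal with median exactly the planted value
  (median = e^μ); defaults 45/30/35 min for group1/tf/other echo the
  embryonic contrast of long-lived sequence-specific RBP transcripts.

The generators emulate the *statistical* structure the analytics consume
— planted effects, noise, group composition — not real biology: there is
no lineage structure, no gene-length or library-size artifacts, no
correlated replicates, no dropout. Passing benchmarks therefore show the
pipeline recovers planted truth under its stated noise model, not that
real atlases meet these effect sizes.

## Benchmarks the test suite computes

On the default study conditions (fixed seeds): planted group and category
recovery is exact; Tau agrees with direct formula evaluation to 1e-12 on
1,000 random vectors; marker calling reaches sensitivity ≥ 0.95 at
FDR ≤ 0.05 with 20 replicates/type and a 3-log2 effect, and stays within
FDR ≤ 0.05 under a null effect; clustering of 4 × 50 archetype genes at
noise sd 0.3 recovers planted labels with adjusted Rand index ≥ 0.9, and
k = 10 with 2 dropped always leaves 8 retained clusters; chi-square,
exact rank-sum and BH agree with brute-force oracles; planted half-life
medians are recovered within 10% at n = 200/group and a 38-vs-55-minute
difference is detected at p < 0.05 with n = 100/group; pipeline reruns
are byte-identical. `scripts/acceptance.py` recomputes all of these from
scratch at a caller-supplied seed. Problem sizes are the package's own
defaults, chosen to make sampling error small relative to the planted
effects while keeping a full run interactive (seconds, one CPU).

## Known limitations

* The default accession lists are curated, not exhaustive; a proteome
  annotated with accessions outside them relies on the name-substring
  fallbacks. Supplying a tuned catalog YAML is the supported remedy.
* The multi-tier precedence rule (lowest group wins) is a documented
  convention; alternative tie-breaks would shift genes between groups.
* Marker calling assumes exchangeable replicate columns within a type;
  pseudo-replication in real single-cell data (cells from one embryo) is
  not modelled.
* The trend call uses only the first and last bins; non-monotone profiles
  with equal endpoints are "flat" by construction.
* Exact rank-sum enumeration is combinatorial; the default cap of 12
  pooled observations keeps it instantaneous, and beyond it the normal
  approximation is used even in the presence of heavy ties.
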