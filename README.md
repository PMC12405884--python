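# rbpcompendium

Build and characterize a compendium of predicted RNA-binding proteins
(RBPs) in *Caenorhabditis elegans*-style genomes, from protein-domain
annotation dumps and developmental expression atlases.

RBPs regulate splicing, localization, translation and turnover of RNAs,
but systems-level catalogs of them lag far behind those of transcription
factors (TFs). This package implements the full pipeline a worm-genomics
group would run to produce and analyze such a catalog:

1. **Domain-rule prediction** — scan InterPro-style domain dumps for 17
   RNA-binding-domain families (RRM, KH, PUF, CCCH, CCHC, DSRBD, RGG Box,
   La, Helicase, PAZ, PIWI, Argonaute, NTF2, C2H2, SAM, Cold shock,
   Sm/Lsm), accepting only Pfam/SMART/Superfamily/ProSite evidence, and
   tier the matches into 4 groups by binding specificity. Genes matching
   several tiers take the most sequence-specific one (min group), so
   per-group sizes always sum to the compendium total.
2. **Genome-build merge** — map a legacy compendium's gene names onto the
   current registry, dropping dead and transposon-origin genes.
3. **TF-overlap resolution** — reconcile the compendium with a TF list
   into exclusive analysis categories {group1..4, tf, other} that
   partition the protein-coding genome (group-1 overlaps stay RBPs only
   with a CCCH domain; group 3, the DNA/RNA-ambiguous tier, keeps its
   TFs).
4. **Expression analytics** — Tau specificity
   (Tau = Σᵢ(1 − x̂ᵢ)/(N − 1), x̂ᵢ = xᵢ/maxⱼxⱼ), cell-type marker calling
   (Wilcoxon rank-sum + Benjamini–Hochberg, log2FC ≥ 1.5, adj. p < 0.05),
   hierarchical time-course clustering (d = 1 − Pearson r, k = 10 with
   the 2 smallest clusters dropped), pseudotime trend calls
   (log₂((last+1)/(first+1)) vs ±1), and maternal/zygotic-only calls
   (1-cell TPM ≥ 10 or mean RPKM ≥ 20).
5. **Category statistics** — RNAi-phenotype/orthology flag proportions
   with 2×2 chi-square vs the all-protein-coding background, mRNA
   half-life medians with exact-or-asymptotic Wilcoxon rank-sum tests,
   and median scaled expression curves.

The analytics are scikit-learn-style estimators (`TauTransformer`,
`MarkerCaller`, `TemporalProfileClusterer`, `PseudotimeTrendClassifier`,
`MaternalClassifier`) that compose with sklearn pipelines; module-level
functions wrap them for tabular in/out. A seeded synthetic-data module
generates every input with planted ground truth, so the whole pipeline is
testable offline. See `docs/methods.md` for the models, defaults and
their rationale.

## Worked example

Simulate a 200-gene scenario and run the full pipeline:

```sh
rbpcompendium simulate scen_demo --seed 3 --n-genes 200
rbpcompendium run --config scen_demo/manifest.yaml --outdir demo_out
```

The run prints its summary (abridged):

```json
{
  "compendium": {"total": 92, "per_group": {"1": 24, "2": 14, "3": 24, "4": 30},
                 "legacy_dropped": 1, "legacy_unmapped": 0},
  "markers": {"n_marker_calls": 30, "per_type": {"type00": 4, "...": "..."}},
  "tau": {"n_scored": 200, "n_broad": 169},
  "clusters": {"k": 10, "n_drop": 2,
               "retained_sizes": {"0": 26, "1": 24, "2": 17, "3": 23,
                                  "4": 17, "5": 22, "6": 23, "7": 27}},
  "trends": {"increase": 50, "decrease": 50, "flat": 50},
  "half_life": {"group1": 49.8, "tf": 28.9, "other": 36.1, "...": "..."}
}
```

Reading it: 92 of the 200 simulated genes carry qualifying RBD evidence
(or survive the legacy merge), split 24/14/24/30 across the four tiers —
the per-group counts sum to the total by construction. One legacy name
resolved to a dead gene and was dropped. Marker calling recovered 30
(gene, cell-type) marker pairs across the 8 simulated types; 169 of 200
genes have broad expression (Tau < 0.4). Cutting the time-course tree at
k = 10 and dropping the 2 smallest clusters leaves exactly 8 retained
clusters, labelled by peak time. The planted 50/50/50
increase/decrease/flat pseudotime trends are recovered exactly, and the
per-category median half-lives (minutes) reflect the planted contrast —
long-lived group-1 RBP transcripts (planted 45, observed 49.8 at n = 24)
vs short-lived TF transcripts (planted 30, observed 28.9) — with the
deviation being sampling noise at these set sizes.

Stage outputs land in `demo_out/` as TSVs (`compendium.tsv`, `tau.tsv`,
`markers.tsv`, `clusters.tsv`, `trends.tsv`, `half_life_comparisons.tsv`,
...) next to `run_metadata.json`; reruns with the same manifest and seed
are byte-identical.

The same analyses are available from Python:

```python
from rbpcompendium import TauTransformer, load_catalog, match_gene_domains

tau = TauTransformer().fit_transform([[10.0, 5.0, 0.0]])  # -> [0.75]
families = match_gene_domains(hits_df, load_catalog())    # gene -> {families}
```

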