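# Default catalog of the 17 RNA-binding-domain families used for RBP prediction.
#
# Accession lists are a curated approximation: the family names and their
# group tiers are fixed, but the underlying databases name each family through
# several InterPro/Pfam/SMART/PROSITE entries, so each family carries exact
# accessions plus case-insensitive name-substring fallbacks. Both are
# user-overridable: pass your own YAML of this shape to load_catalog().
#
# Groups:
#   1 — gene- and RNA-sequence-specific binders
#   2 — gene-specific, RNA-nonspecific binders (small-RNA pathway machinery)
#   3 — ambiguous DNA/RNA/protein binders
#   4 — non-gene-specific binders (Sm/Lsm cores; housekeeping RBPs)
families:
  - name: RRM
    group: 1
    accessions: [IPR000504, IPR012677, IPR035979, PF00076, SM00360, PS50102]
    name_patterns: ["rna recognition motif", "rrm"]
    sources: [Pfam, SMART, Superfamily, ProSite]
  - name: KH
    group: 1
    accessions: [IPR004087, IPR004088, IPR036612, PF00013, SM00322, PS50084]
    name_patterns: ["k homology", "kh domain"]
    sources: [Pfam, SMART, Superfamily, ProSite]
  - name: PUF
    group: 1
    accessions: [IPR001313, IPR016024, PF00806, SM00025, PS50302]
    name_patterns: ["pumilio", "puf repeat"]
    sources: [Pfam, SMART, Superfamily, ProSite]
  - name: CCCH
    group: 1
    accessions: [IPR000571, IPR036855, PF00642, SM00356, PS50103]
    name_patterns: ["zinc finger ccch", "c3h1", "ccch-type"]
    sources: [Pfam, SMART, Superfamily, ProSite]
  - name: CCHC
    group: 1
    accessions: [IPR001878, IPR036875, PF00098, SM00343, PS50158]
    name_patterns: ["zinc knuckle", "cchc-type"]
    sources: [Pfam, SMART, Superfamily, ProSite]
  - name: DSRBD
    group: 1
    accessions: [IPR014720, IPR036389, PF00035, SM00358, PS50137]
    name_patterns: ["double-stranded rna-binding", "dsrbd", "dsrm"]
    sources: [Pfam, SMART, Superfamily, ProSite]
  - name: RGG Box
    group: 1
    accessions: [IPR010976]
    name_patterns: ["rgg box", "rgg-box", "rgg repeat"]
    sources: [Pfam, SMART, Superfamily, ProSite]
  - name: La
    group: 1
    accessions: [IPR006630, IPR002344, IPR045780, PF05383, SM00715, PS50961]
    name_patterns: ["la-type hth", "la domain", "la protein"]
    sources: [Pfam, SMART, Superfamily, ProSite]
  - name: Helicase
    group: 2
    accessions: [IPR011545, IPR001650, IPR014001, PF00270, PF00271, SM00487, SM00490, PS51192, PS51194]
    name_patterns: ["helicase"]
    sources: [Pfam, SMART, Superfamily, ProSite]
  - name: PAZ
    group: 2
    accessions: [IPR003100, IPR036085, PF02170, SM00949, PS50821]
    name_patterns: ["paz domain"]
    sources: [Pfam, SMART, Superfamily, ProSite]
  - name: PIWI
    group: 2
    accessions: [IPR003165, IPR036085, PF02171, SM00950, PS50822]
    name_patterns: ["piwi"]
    sources: [Pfam, SMART, Superfamily, ProSite]
  - name: Argonaute
    group: 2
    accessions: [IPR032474, IPR032473, IPR014811, PF16486, PF16487, PF08699]
    name_patterns: ["argonaute"]
    sources: [Pfam, SMART, Superfamily, ProSite]
  - name: NTF2
    group: 2
    accessions: [IPR002075, IPR032710, IPR018222, PF02136, PS50177]
    name_patterns: ["nuclear transport factor 2", "ntf2"]
    sources: [Pfam, SMART, Superfamily, ProSite]
  - name: C2H2
    group: 3
    accessions: [IPR013087, IPR036236, IPR007087, PF00096, SM00355, PS50157]
    name_patterns: ["zinc finger c2h2", "c2h2-type"]
    sources: [Pfam, SMART, Superfamily, ProSite]
  - name: SAM
    group: 3
    accessions: [IPR001660, IPR013761, PF00536, SM00454, PS50105]
    name_patterns: ["sterile alpha motif", "sam domain"]
    sources: [Pfam, SMART, Superfamily, ProSite]
  - name: Cold shock
    group: 3
    accessions: [IPR011129, IPR002059, IPR019844, PF00313, SM00357, PS51857]
    name_patterns: ["cold-shock", "cold shock"]
    sources: [Pfam, SMART, Superfamily, ProSite]
  - name: Sm/Lsm
    group: 4
    accessions: [IPR001163, IPR010920, IPR047575, PF01423, SM00651, PS52002]
    name_patterns: ["sm-like", "lsm domain", "sm domain", "sm protein"]
    sources: [Pfam, SMART, Superfamily, ProSite]
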