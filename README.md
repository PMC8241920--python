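# bgcbound

Integrated delimitation of fungal secondary-metabolite biosynthetic gene
cluster (BGC) boundaries from three independent lines of evidence:
motif-independent comparative genomics, differential transcription against a
pathway-regulator knockout, and gene-knockout metabolite profiling.

Tools that anchor BGC predictions on core-enzyme motifs (polyketide
synthases, NRPSs) are good at finding clusters but notoriously poor at
calling their edges — for the *Monascus ruber* M7 azaphilone pigment
(MonAzPs) locus, published delimitations range from a single gene to 21
genes. `bgcbound` implements, as a reusable and tested pipeline, the
combined procedure that resolves such cases: each evidence stream is
computed by its own module, and a rule-based consensus caller arbitrates
their disagreements at the cluster borders.

## The method

**Comparative genomics (seed / extend / trim).** Proteins of two annotated
loci are compared all-vs-all by Smith–Waterman local alignment (BLOSUM62,
affine gaps 11/1). Pair significance uses the Karlin–Altschul estimate
*E = K·m·n·e^(−λS)* (λ = 0.267, K = 0.041) with a cutoff of *e* < 10⁻¹⁰,
and each retained pair carries a normalized similarity
*s = SW(a,b) / min(SW(a,a), SW(b,b))* ∈ [0, 1]. The **seed** R₀ is the
longest run of genes contiguous in *both* genomes whose members pair in
consistent order (a partner mis-annotated as two fragment genes occupies
one position covering two). The seed is **extended** to a 35-gene candidate
window on each genome, then the window pair is **trimmed** by exhaustively
maximizing the cumulative score

CB = Σ (best partner similarity of each matched span gene) + (−0.3) × (# unmatched span genes, both sides),

with order-free matching inside the spans so non-syntenic partner clusters
are handled.

**Differential expression (ΔΔCT).** CT tables from wild type vs a
regulator-knockout strain are analyzed by the comparative-CT method
(technical replicates averaged, ΔCT against a reference gene per biological
replicate, fold change 2^(−ΔΔCT)), with one-way ANOVA (α = 0.05) across the
strains' per-replicate relative values. Genes are classed abolished
(fc ≤ 0.1), downregulated (fc ≤ 2/3), upregulated (fc ≥ 1.5), unchanged, or
not expressed.

**Knockout metabolite evidence.** Each knockout strain's compound table is
classified against wild type: *abolished* (all core pigments lost),
*shunt* (derailment products appear), *ratio_shift* (core ratios move more
than 2-fold), or *unchanged*.

**Consensus.** Members start as the comparative span; a border gene joins
only on functional knockout evidence (regulation alone never admits one);
an edge member is dropped only when its knockout is neutral *and* it is
transcriptionally unresponsive; interior members are always retained. This
precedence (knockout > comparative genomics > transcription) is what keeps
regulator-responsive but dispensable border genes out, and regulator-blind
interior genes in.

## Worked example

All inputs are generated by the seeded synthetic module (no downloads); the
`m7_atcc18224` fixture plants a 20-gene locus whose genome-B counterpart is
a 14-gene non-syntenic cluster, together with the matching expression and
knockout panels:

```bash
$ bgcbound run-all --fixture m7_atcc18224 --seed 42 --out demo
mrpigA..mrpigP (16 genes)
```

`demo/report.txt` shows the per-gene evidence matrix behind the call:

```
Consensus BGC call: mrpigA .. mrpigP (16 genes)

gene           cg   expression     knockout     tier
mrpigAup2      -    unchanged      unchanged    excluded
mrpigAup1      -    downregulated  unchanged    excluded
mrpigA         yes  abolished      abolished    strong
mrpigB         yes  -              -            retained-interior
mrpigC         yes  unchanged      -            retained-interior
...
mrpigO         yes  abolished      shunt        strong
mrpigP         yes  abolished      ratio_shift  strong
mrpigPdown1    -    downregulated  unchanged    excluded
mrpigPdown2    -    unchanged      unchanged    excluded

Excluded genes:
  mrpigAup2: ko-neutral
  mrpigAup1: regulated-but-ko-neutral
  mrpigPdown1: regulated-but-ko-neutral
  mrpigPdown2: ko-neutral
```

Reading the output: the comparative stage seeds on the high-similarity
mrpigG..mrpigK block, extends to 35 genes, and trims to the 16-gene span
mrpigA..mrpigP (CB = 6.08 here). The two flanking genes mrpigAup1 and
mrpigPdown1 are significantly downregulated in the regulator knockout
(e.g. mrpigAup1 fold change ≈ 0.35), yet their own knockouts leave the
pigment profile unchanged — so the consensus rules exclude them, with a
machine-readable reason. Conversely mrpigC/J/K/L escape the regulator
entirely (fold change ≈ 1) but sit deep inside the span and are retained.
Stage outputs (`homologs.tsv`, `expression.tsv`, `phenotypes.tsv`,
`report.json`) land next to the text report.

Every stage is also exposed on its own (`bgcbound simulate | homology |
boundary | expression | knockout | integrate`) and as library functions
(`bgcbound.predict_cluster`, `analyze_locus`, `evaluate_knockout_panel`,
`call_bgc`).

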