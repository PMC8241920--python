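# Methods

This note records the models behind each stage, the defaults and why they
hold, the choices made where the design was genuinely open, and what the
synthetic data does and does not establish.

## Comparative stage

### Alignment and pair filtering

Protein pairs are scored by optimal Smith–Waterman local alignment under
affine gaps; a gap of length L costs `gap_open + (L−1)·gap_extend`
(defaults 11/1, the BLASTP convention; matrix BLOSUM62). The alignment
engine is Biopython's `PairwiseAligner` in local mode, which returns the
true SW optimum including the empty alignment (score 0) for all-negative
comparisons; the test suite cross-checks it against an independent
pure-Python Gotoh dynamic program on hundreds of random pairs.

Two parameter families must not be confused: the residue-level gap costs
above, and the *gene-level* cluster-scoring penalties (gap −0.2, mismatch
−0.2, negative penalty −0.3) that act on whole genes during seeding and
trimming. Both sets are configurable and reported in every run's
provenance block.

Significance uses the Karlin–Altschul form `E = K·m·n·exp(−λS)` with the
ungapped BLOSUM62 constants λ = 0.267, K = 0.041 applied to the gapped
score. This is the standard approximation when only a threshold (here
*e* < 10⁻¹⁰) is prescribed rather than a full statistic; both constants are
configurable. At locus scale the comparison is exact all-vs-all — no
seeding heuristics.

Similarities are normalized as `s = SW(a,b) / min(SW(a,a), SW(b,b))`,
clipped to [0, 1]. Normalizing by the *smaller* self-score makes a
truncated fragment annotation score ~1 against its full-length partner
(the two-fragment mis-annotation case), and keeps `s` commensurate with
the unit-scale gene penalties. Published applications of this scoring do
not fully specify their normalization; this convention is a documented
package choice.

### Seed detection

The seed R₀ is the longest run of genes contiguous in both genomes whose
members pair in a consistent direction (forward or inverted). A genome-A
gene paired with several *consecutive* genome-B genes consumes all of them
(fragmented partner), counting as one A position. Ties on run length break
toward the larger summed normalized score, then the leftmost A position;
runs shorter than `min_seed_len` (default 3) are discarded. A plain
mutual-coverage definition (every gene in interval X has a partner in
interval Y and vice versa) was rejected: it would fuse any fully-partnered
but shuffled cluster into one giant "seed", erasing exactly the synteny
signal the seed is meant to capture.

Fragment consumption is greedy: if a gene's partners occupy positions
p, p+1, … they are all absorbed before the next A gene is matched. A
pathological layout where a fragment also pairs the next A gene could
mislead this; no realistic mis-annotation pattern does.

### Extension and trimming

The window totals `extension_total` genes *including* the seed (default
35); the flank budget splits evenly with any odd remainder upstream, and
truncates silently at contig ends. Both genomes are extended independently
around their seed genes.

Trimming searches *all* pairs of sub-spans of the two windows — about
630 × 630 at the default window size, evaluated exactly with prefix sums in
well under a second, so no dynamic-programming shortcut is needed. The
objective per span pair is

    CB = Σ_{a ∈ span_A} best_s(a, span_B)  +  p · #unmatched(span_A, span_B)

where `best_s` is the gene's best-scoring partner inside the opposing span
(order-free, so each pair counts once and a multi-partner gene contributes
its best partner), `p` is the negative penalty (−0.3), and unmatched genes
on *either* side are penalized. Order-free matching is deliberate: the
partner cluster may be non-syntenic, and membership — not order — is the
evidence. Score ties within 10⁻⁹ break toward the smaller combined span,
then the leftmost A start, then the leftmost B start; the tolerance keeps
the winner stable under floating-point summation order, and the preference
for smaller spans means a flanking gene must *earn* its inclusion.

Degenerate inputs: a window pair without a single cross-window match
raises a structured "no cluster evidence" error; a genome pair without a
qualifying seed yields a structured no-cluster result (CLI exit code 3),
not an exception.

## Expression stage

Relative expression follows the comparative-CT model with amplification
efficiency exactly 2 (no Pfaffl correction). Technical replicates are
averaged before any statistic — they share the biological sample and are
not independent. Each biological replicate contributes
ΔCT = CT_target − CT_reference; the fold change is 2^(−ΔΔCT) and
per-replicate relative values 2^(−(ΔCT − mean ΔCT_calibrator)) feed a
one-way fixed-effects ANOVA across the two strains (for two groups this is
the pooled t-test, t² = F, which the suite verifies numerically). With
both groups constant the ANOVA degenerates: p = 1 for equal means, 0
otherwise. Undetermined CT values are detection flags, never imputed: a
target undetermined in every calibrator replicate is *not_expressed*; one
lost only in the case strain is *abolished*; an undetermined reference is
a hard error.

Class cutoffs quantify the qualitative vocabulary of regulator-knockout
experiments: "almost completely abolished" → fc ≤ 0.1, "moderately
downregulated" → fc ∈ (0.1, 2/3], upregulated → fc ≥ 1.5, each requiring
p < α (default 0.05); everything else — including significant fold changes
inside (2/3, 1.5) — is unchanged. The planted effects in the expression
fixture (0.02 / 0.4 / 1.0) sit deep inside these bands. Per-gene testing
is deliberately uncorrected for multiplicity, matching how such panels are
conventionally read; the thresholds object accepts a different α if a
correction is applied upstream.

## Knockout stage

Phenotypes are computed from already-quantified compound tables (HPLC peak
processing is out of scope). The registry tags compounds 1–4 (monascin,
rubropunctatin, ankaflavin, monascorubrin) as core and 5–6 (acetyl-
monasfluols A/B) as shunt. The category rules, first match wins:
all core absent and no shunt → *abolished*; any shunt above floor →
*shunt*; all core present but a pairwise core ratio off by more than
2-fold → *ratio_shift*; otherwise *unchanged*. Shunt outranks ratio_shift
so a strain that both loses core pigments and accumulates derailment
products is never mislabeled. "Absent" means below 5 % of the wild-type
amount; the shunt floor is 5 % of the mean wild-type core amount; the
2-fold tolerances are inclusive, so an exactly 2-fold uniform change is
still *unchanged*. All thresholds are fractions of wild-type quantities,
making the categories invariant under rescaling of the units — the
underlying experimental readout is qualitative, and these numbers are its
explicit, configurable quantification.

## Consensus rules

The caller applies, in order: (R1) members = comparative span; (R2) an
adjacent gene joins only if its knockout category is functional
(abolished/shunt/ratio_shift) — transcriptional regulation alone never
admits a gene, and the walk stops at the first non-admitted gene per side;
(R3) an edge member is removed only if its knockout is neutral *and* its
expression is unchanged or not expressed, repeated to stability; (R4)
interior members are never removed. Missing evidence is represented
explicitly and never defaults to "unchanged", so absence of a knockout can
neither admit nor expel a gene. `ratio_shift` counts as supporting
evidence but is flagged `weak` in the confidence tier when it is the only
support. These rules make the borders knockout-dominated by construction:
a regulated-but-dispensable border gene is excluded (reason
`regulated-but-ko-neutral`), an unregulated interior gene is retained
(`retained-interior`).

## Synthetic data

The generators are pure functions of configuration and seed.

**Genome pairs.** Background proteins are uniform-random 250–450-mers —
adequate for the E-value null at locus scale and simpler to reason about
than composition-matched models. Planted orthologs are derived by
substituting a rounded count of positions, so the realized identity is
exact to rounding (±0.03 guaranteed). The `m7_atcc18224` fixture plants
the 20-gene locus with partners for mrpigA..mrpigP except mrpigF/O/L
(whose counterparts lie outside the partner cluster), splits the mrpigH
partner into two fragment genes, and uses the reported cross-species
identities where available (mrpigA 0.66 … mrpigB 0.46 … mrpigP 0.57;
0.60 where unstated). The partner cluster is arranged in shuffled blocks
([C D E] [M N] [G H I J K] [A B] [P]) so the high-identity G..K block is
the unique longest syntenic run — leaving the three unpartnered genes
inside the final span at −0.3 each, which the flanking matched genes
comfortably out-score. The `pm1_nonsyntenic` fixture plants 14 one-to-one
partners under a hand-verified permutation whose only 3-gene syntenic run
is the preserved seed block. At these identities every planted pair clears
*e* < 10⁻¹⁰ by orders of magnitude (a raw score of ~117 suffices at
300×300; identity 0.46 yields ~530) while unrelated 300-mers top out near
E ≈ 1 — hence the planted-recovery tests can demand exact truth recovery.

**CT tables.** Biological replicate noise (sd 0.3 CT) is modeled as a
*sample-level* shift shared by every gene of a (strain, replicate) —
RNA-input variation, which is precisely what the reference gene cancels —
with independent per-well technical noise (sd 0.15). Under this model the
planted classes are recovered essentially always at B = T = 3, and null
p-values are uniform. Modeling biological noise as independent per gene
would instead leave ~30 % of moderate (fc 0.4) effects non-significant at
n = 3; real per-gene biological variability therefore makes the fixture an
idealization: passing tests show the analysis is correct, not that three
replicates suffice for any real locus. Genes on one simulated plate share
the reference gene's noise, so independence-sensitive checks (e.g. the
p-uniformity KS test) must simulate one experiment per draw.

**Knockout profiles.** Wild-type amounts are fixed constants; mutants
follow per-phenotype templates with 5 % multiplicative (lognormal) noise,
far from every classification threshold — a 100-seed sweep classifies all
templates correctly.

What the fixtures do *not* emulate: sequence evolution with indels, codon
or composition bias, amplification-efficiency curves, chromatographic
signal processing, multi-contig assemblies, or genome-scale search (the
pipeline delimits a single locus per run by design).

## Problem sizes and runtime

Default fixtures use 40-gene genomes (1600 alignment pairs, ~4 s), 35-gene
windows (~400k span pairs, <1 s), 19-gene expression panels and 8-strain
knockout panels; the full test suite, including the brute-force oracle
comparisons (200 alignment pairs, 100 trim instances, 1000 null
experiments), runs in about half a minute.

## Known limitations

- E-values use ungapped constants on gapped scores; at the prescribed
  10⁻¹⁰ cutoff the approximation is inconsequential, but the absolute
  E-values should not be over-interpreted.
- The seed's greedy fragment absorption and the single-best-cluster scope
  are simplifications; multi-cluster scanning and >2-genome joint
  prediction are out of scope.
- The consensus caller can in principle walk beyond the comparative window
  edge if functional knockouts support it; no bundled scenario exercises
  this, and the behavior is a documented extrapolation of rule R2.
- Whether trimming inflection points at particular interior genes
  correspond to local CB maxima on the real proteomes cannot be checked
  against synthetic data; the fixtures make no claim about it.
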