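"""Comparative-genomics boundary prediction: seed, extend, trim.

The procedure delimits a biosynthetic gene cluster shared between two
genomes in three steps:

1. **Seed** — find the longest run of genes contiguous in *both* genomes
   whose members form cross-genome homolog pairs in consistent order
   (forward or inverted).  A genome-A gene paired with several consecutive
   genome-B genes (a fragmented partner annotation) occupies one A position
   covering those consecutive B positions.
2. **Extend** — grow the seed symmetrically to a fixed candidate-window
   size (default 35 genes counting the seed), truncating silently at
   contig ends, on each genome independently.
3. **Trim** — over all pairs of sub-spans of the two windows, maximize the
   cumulative score CB: each window-A gene contributes its best normalized
   similarity to a partner inside the opposing span, unmatched span genes
   on either side contribute the negative penalty.  Matching is order-free
   within the spans, so non-syntenic partner clusters are handled.

The exhaustive trim search is exact: a 35-gene window on each side yields
about 630 x 630 span pairs, which prefix sums evaluate in well under a
second.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Optional

from .core import GenomeTable, GeneRecord
from .homology import AlignmentParams, DEFAULT_PARAMS, HomologGraph, build_homolog_graph

_EPS = 1e-9  # score-tie tolerance for deterministic tie-breaking


class BoundaryError(ValueError):
    pass


class NoClusterEvidenceError(BoundaryError):
    """Raised when a window contains no cross-genome matched gene at all."""


@dataclass(frozen=True)
class ClusterScoringParams:
    """Gene-level scoring parameters for seeding and trimming.

    ``gap_penalty`` (a window gene with no partner anywhere) and
    ``mismatch_penalty`` (partners exist but all fall outside the opposing
    span) parameterize the graph/seed step; trimming applies the single
    ``negative_penalty`` to any unmatched span gene.
    """

    gap_penalty: float = -0.2
    mismatch_penalty: float = -0.2
    negative_penalty: float = -0.3
    extension_total: int = 35
    min_seed_len: int = 3

    def __post_init__(self) -> None:
        if self.gap_penalty >= 0 or self.mismatch_penalty >= 0 or self.negative_penalty >= 0:
            raise BoundaryError("penalties must be negative")
        if not (self.extension_total >= self.min_seed_len >= 1):
            raise BoundaryError("need extension_total >= min_seed_len >= 1")


DEFAULT_SCORING = ClusterScoringParams()


@dataclass
class SeedRegion:
    """The seed R0: contiguous, order-consistent ortholog run in both genomes."""

    genes_a: list[GeneRecord]
    genes_b: list[GeneRecord]
    pairs: list
    sum_score: float
    inverted: bool = False

    def __len__(self) -> int:
        return len(self.genes_a)


@dataclass
class ExtendedWindow:
    """The candidate windows around the seed on both genomes."""

    window_a: list[GeneRecord]
    window_b: list[GeneRecord]
    seed: SeedRegion


@dataclass
class BoundaryCall:
    """Trimmed spans on both genomes with the maximized cumulative score."""

    i_begin: str
    i_end: str
    j_begin: str
    j_end: str
    cb_score: float
    genes_a: list[GeneRecord]
    genes_b: list[GeneRecord]
    per_gene_contributions: dict[str, float]

    @property
    def n_genes_a(self) -> int:
        return len(self.genes_a)

    @property
    def n_genes_b(self) -> int:
        return len(self.genes_b)


def _partner_positions(graph: HomologGraph, genome_a: GenomeTable, genome_b: GenomeTable):
    """Map order_index in A -> {order_index in B: best norm_score}."""
    pos_b = {g.gene_id: g.order_index for g in genome_b.genes}
    out: dict[int, dict[int, float]] = {}
    for g in genome_a.genes:
        d: dict[int, float] = {}
        for p in graph.partners_of_a(g.gene_id):
            j = pos_b[p.gene_b]
            d[j] = max(d.get(j, 0.0), p.norm_score)
        if d:
            out[g.order_index] = d
    return out


def detect_seed(graph: HomologGraph, genome_a: GenomeTable, genome_b: GenomeTable,
                params: ClusterScoringParams = DEFAULT_SCORING) -> Optional[SeedRegion]:
    """Find the maximal order-consistent run of homolog pairs (the seed R0).

    Runs are grown gene by gene along genome A; each successive A gene must
    pair with the next B position(s) in the current direction, where a gene
    may consume several consecutive B positions when its partner is split
    into fragments.  The longest run (by A-gene count) wins; ties break by
    larger summed normalized score, then by leftmost A position.  Returns
    ``None`` when no run reaches ``min_seed_len``.
    """
    partners = _partner_positions(graph, genome_a, genome_b)
    if not partners:
        return None
    genes_a_by_idx = {g.order_index: g for g in genome_a.genes}
    genes_b_by_idx = {g.order_index: g for g in genome_b.genes}
    contig_a = {g.order_index: g.contig for g in genome_a.genes}
    contig_b = {g.order_index: g.contig for g in genome_b.genes}

    best = None  # (length, sum_score, -start) maximized
    seen_runs: set[tuple] = set()

    for ia0 in sorted(partners):
        for jb0 in sorted(partners[ia0]):
            for step in (1, -1):
                ia, jb = ia0, jb0
                a_idxs: list[int] = []
                b_idxs: list[int] = []
                while ia in partners and jb in partners[ia]:
                    if a_idxs and (contig_a[ia] != contig_a[a_idxs[0]]
                                   or contig_b[jb] != contig_b[b_idxs[0]]):
                        break
                    a_idxs.append(ia)
                    b_idxs.append(jb)
                    # a fragmented partner: consume further consecutive B hits
                    nxt = jb + step
                    while nxt in partners[ia] and contig_b.get(nxt) == contig_b[jb]:
                        b_idxs.append(nxt)
                        nxt += step
                    ia += 1
                    jb = nxt
                if len(a_idxs) < params.min_seed_len:
                    continue
                key = (a_idxs[0], a_idxs[-1], min(b_idxs), max(b_idxs), step)
                if key in seen_runs:
                    continue
                seen_runs.add(key)
                b_set = set(b_idxs)
                run_pairs = []
                ssum = 0.0
                for ia_ in a_idxs:
                    for jb_, s in partners[ia_].items():
                        if jb_ in b_set:
                            ssum += s
                            run_pairs.append((genes_a_by_idx[ia_].gene_id,
                                              genes_b_by_idx[jb_].gene_id, s))
                cand_key = (len(a_idxs), ssum, -a_idxs[0])
                if best is None or cand_key > best[0]:
                    best = (cand_key, a_idxs, sorted(b_idxs), run_pairs, ssum, step == -1)

    if best is None:
        return None
    _, a_idxs, b_idxs, run_pairs, ssum, inverted = best
    return SeedRegion(
        genes_a=[genes_a_by_idx[i] for i in a_idxs],
        genes_b=[genes_b_by_idx[j] for j in b_idxs],
        pairs=run_pairs,
        sum_score=ssum,
        inverted=inverted,
    )


def _extend_on(genome: GenomeTable, seed_genes: list[GeneRecord], total: int) -> list[GeneRecord]:
    contig = seed_genes[0].contig
    contig_genes = [g for g in genome.genes if g.contig == contig]
    lo = contig_genes[0].order_index
    first = seed_genes[0].order_index
    last = seed_genes[-1].order_index
    flank = max(0, total - (last - first + 1))
    up = flank - flank // 2          # odd remainder goes upstream
    down = flank // 2
    start = max(lo, first - up)
    end = min(contig_genes[-1].order_index, last + down)
    offset = lo
    return contig_genes[start - offset : end - offset + 1]


def extend_seed(seed: SeedRegion, genome_a: GenomeTable, genome_b: GenomeTable,
                params: ClusterScoringParams = DEFAULT_SCORING) -> ExtendedWindow:
    """Grow each genome's seed to the candidate-window size (default 35 genes).

    The flank budget (total minus seed length) is split evenly, odd remainder
    upstream; windows are silently truncated at contig ends.
    """
    return ExtendedWindow(
        window_a=_extend_on(genome_a, seed.genes_a, params.extension_total),
        window_b=_extend_on(genome_b, seed.genes_b, params.extension_total),
        seed=seed,
    )


def _span_score_tables(window_a, window_b, graph: HomologGraph):
    """Precompute structures for the exhaustive CB search."""
    na, nb = len(window_a), len(window_b)
    b_index = {g.gene_id: j for j, g in enumerate(window_b)}
    # scores[ia] = sorted list of (jb, norm) partners inside the window
    scores: list[list[tuple[int, float]]] = [[] for _ in range(na)]
    partner_a_of_b: list[list[int]] = [[] for _ in range(nb)]
    for ia, g in enumerate(window_a):
        for p in graph.partners_of_a(g.gene_id):
            jb = b_index.get(p.gene_b)
            if jb is not None:
                scores[ia].append((jb, p.norm_score))
                partner_a_of_b[jb].append(ia)
    for lst in scores:
        lst.sort()
    for lst in partner_a_of_b:
        lst.sort()
    return scores, partner_a_of_b


def trim_boundaries(window: ExtendedWindow, graph: HomologGraph,
                    params: ClusterScoringParams = DEFAULT_SCORING) -> BoundaryCall:
    """Exhaustive joint search for the span pair maximizing the cumulative score.

    CB(i-span, j-span) = sum over A-span genes of the best normalized score of
    a partner inside the j-span (order-free) plus ``negative_penalty`` for
    every span gene, on either side, with no partner inside the opposing span.
    Ties (within 1e-9) break toward the smaller combined span, then leftmost
    on A, then leftmost on B.
    """
    wa, wb = window.window_a, window.window_b
    na, nb = len(wa), len(wb)
    pen = params.negative_penalty
    scores, partner_a_of_b = _span_score_tables(wa, wb, graph)
    if not any(scores):
        raise NoClusterEvidenceError(
            "no homolog pair links the two windows: no cluster evidence"
        )

    # contribution of A gene ia given j-span [j1, j2]: best partner score, else penalty
    j_spans = [(j1, j2) for j1 in range(nb) for j2 in range(j1, nb)]
    # prefix sums over A genes for every j-span
    prefixes: dict[tuple[int, int], list[float]] = {}
    for (j1, j2) in j_spans:
        pref = [0.0] * (na + 1)
        for ia in range(na):
            best = None
            for jb, s in scores[ia]:
                if j1 <= jb <= j2 and (best is None or s > best):
                    best = s
            pref[ia + 1] = pref[ia] + (best if best is not None else pen)
        prefixes[(j1, j2)] = pref

    best_cb = None       # cb of the currently selected span pair
    best_key = None
    best_spans = None
    for i1 in range(na):
        for i2 in range(i1, na):
            # matched flags for B genes given this i-span
            mpref = [0] * (nb + 1)
            for jb in range(nb):
                lst = partner_a_of_b[jb]
                matched = bisect_right(lst, i2) > bisect_left(lst, i1)
                mpref[jb + 1] = mpref[jb] + (1 if matched else 0)
            for (j1, j2) in j_spans:
                pref = prefixes[(j1, j2)]
                a_part = pref[i2 + 1] - pref[i1]
                unmatched_b = (j2 - j1 + 1) - (mpref[j2 + 1] - mpref[j1])
                cb = a_part + pen * unmatched_b
                key = ((i2 - i1 + 1) + (j2 - j1 + 1), i1, j1)
                if (best_cb is None or cb > best_cb + _EPS
                        or (cb > best_cb - _EPS and key < best_key)):
                    best_cb = cb
                    best_key = key
                    best_spans = (i1, i2, j1, j2)

    i1, i2, j1, j2 = best_spans
    genes_a = wa[i1 : i2 + 1]
    genes_b = wb[j1 : j2 + 1]
    contributions: dict[str, float] = {}
    for ia in range(i1, i2 + 1):
        best = None
        for jb, s in scores[ia]:
            if j1 <= jb <= j2 and (best is None or s > best):
                best = s
        contributions[wa[ia].gene_id] = best if best is not None else pen
    for jb in range(j1, j2 + 1):
        lst = partner_a_of_b[jb]
        matched = bisect_right(lst, i2) > bisect_left(lst, i1)
        contributions[wb[jb].gene_id] = 0.0 if matched else pen
    return BoundaryCall(
        i_begin=genes_a[0].gene_id,
        i_end=genes_a[-1].gene_id,
        j_begin=genes_b[0].gene_id,
        j_end=genes_b[-1].gene_id,
        cb_score=best_cb,
        genes_a=genes_a,
        genes_b=genes_b,
        per_gene_contributions=contributions,
    )


@dataclass
class PredictionResult:
    """Outcome of the full comparative stage, with provenance."""

    found: bool
    reason: str = ""
    graph: Optional[HomologGraph] = None
    seed: Optional[SeedRegion] = None
    window: Optional[ExtendedWindow] = None
    call: Optional[BoundaryCall] = None
    params: dict = field(default_factory=dict)


def predict_cluster(genome_a: GenomeTable, genome_b: GenomeTable,
                    align_params: AlignmentParams = DEFAULT_PARAMS,
                    cluster_params: ClusterScoringParams = DEFAULT_SCORING) -> PredictionResult:
    """Full comparative stage: homolog graph -> seed -> extend -> trim."""
    provenance = {
        "alignment": dict(align_params.__dict__),
        "scoring": dict(cluster_params.__dict__),
    }
    graph = build_homolog_graph(genome_a, genome_b, align_params)
    seed = detect_seed(graph, genome_a, genome_b, cluster_params)
    if seed is None:
        return PredictionResult(found=False, reason="no seed region detected",
                                graph=graph, params=provenance)
    window = extend_seed(seed, genome_a, genome_b, cluster_params)
    call = trim_boundaries(window, graph, cluster_params)
    return PredictionResult(found=True, graph=graph, seed=seed, window=window,
                            call=call, params=provenance)


def boundary_report(result: PredictionResult) -> dict:
    """JSON-ready summary of a prediction."""
    if not result.found:
        return {"found": False, "reason": result.reason, "params": result.params}
    seed = result.seed
    call = result.call
    return {
        "found": True,
        "seed": {
            "genes_a": [g.gene_id for g in seed.genes_a],
            "genes_b": [g.gene_id for g in seed.genes_b],
            "sum_score": seed.sum_score,
            "inverted": seed.inverted,
        },
        "window": {
            "genes_a": [g.gene_id for g in result.window.window_a],
            "genes_b": [g.gene_id for g in result.window.window_b],
        },
        "call": {
            "i_begin": call.i_begin, "i_end": call.i_end,
            "j_begin": call.j_begin, "j_end": call.j_end,
            "cb_score": call.cb_score,
            "n_genes_a": call.n_genes_a, "n_genes_b": call.n_genes_b,
        },
        "params": result.params,
    }
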