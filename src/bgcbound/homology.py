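"""Cross-genome protein similarity: Smith-Waterman scores, normalization,
Karlin-Altschul E-values, and the filtered homolog-pair graph.

Raw scores come from optimal local alignment under affine gaps (a gap of
length L costs ``gap_open + (L-1) * gap_extend``).  Scores are normalized to
[0, 1] by the smaller of the two self-alignment scores, which keeps a
truncated fragment annotation commensurate with its full-length partner and
puts per-pair similarities on the same unit scale as the gene-level penalties
used during boundary trimming.  Significance uses the Karlin-Altschul form
E = K * m * n * exp(-lambda * S) with ungapped BLOSUM62 constants applied to
the gapped score — the standard approximation; both constants are
configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .core import GenomeTable, _sanitize_protein


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentParams:
    """Residue-level alignment and filtering parameters.

    Note the deliberate separation of concerns: the gene-level cluster-scoring
    penalties (gap -0.2, mismatch -0.2, negative -0.3) belong to the boundary
    module; the gap penalties here (11/1, BLASTP defaults) are residue-level
    alignment costs.
    """

    substitution_matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    karlin_lambda: float = 0.267
    karlin_k: float = 0.041
    evalue_threshold: float = 1.0e-10

    def __post_init__(self) -> None:
        if self.evalue_threshold <= 0:
            raise AlignmentError("evalue_threshold must be positive")
        if self.gap_open < self.gap_extend:
            raise AlignmentError("gap_open must be >= gap_extend")
        if self.karlin_lambda <= 0 or self.karlin_k <= 0:
            raise AlignmentError("Karlin-Altschul constants must be positive")


DEFAULT_PARAMS = AlignmentParams()


@lru_cache(maxsize=8)
def _aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    matrix = substitution_matrices.load(params.substitution_matrix)
    aligner = Align.PairwiseAligner(
        mode="local",
        substitution_matrix=matrix,
        open_gap_score=-(params.gap_open),
        extend_gap_score=-(params.gap_extend),
    )
    return aligner


def _prepare(seq: str, which: str) -> str:
    if not seq:
        raise AlignmentError(f"empty sequence for argument {which}")
    return _sanitize_protein(seq)


def smith_waterman(seq_a: str, seq_b: str, params: AlignmentParams = DEFAULT_PARAMS):
    """Optimal local alignment score and aligned spans.

    Returns ``(raw_score, ((a_start, a_end), (b_start, b_end)))`` with 0-based
    half-open spans of the best local alignment, or ``(0.0, None)`` when the
    optimal local alignment is empty (all-negative comparison).
    """
    a = _prepare(seq_a, "seq_a")
    b = _prepare(seq_b, "seq_b")
    aligner = _aligner(params)
    score = float(aligner.score(a, b))
    if score <= 0:
        return 0.0, None
    aln = next(iter(aligner.align(a, b)))
    a_start, a_end = int(aln.coordinates[0][0]), int(aln.coordinates[0][-1])
    b_start, b_end = int(aln.coordinates[1][0]), int(aln.coordinates[1][-1])
    return score, ((a_start, a_end), (b_start, b_end))


def sw_score(seq_a: str, seq_b: str, params: AlignmentParams = DEFAULT_PARAMS) -> float:
    """Raw local alignment score only (faster: skips traceback)."""
    a = _prepare(seq_a, "seq_a")
    b = _prepare(seq_b, "seq_b")
    return max(0.0, float(_aligner(params).score(a, b)))


def self_score(seq: str, params: AlignmentParams = DEFAULT_PARAMS) -> float:
    """SW score of a sequence against itself (the normalization denominator)."""
    return sw_score(seq, seq, params)


def normalized_score(seq_a: str, seq_b: str, params: AlignmentParams = DEFAULT_PARAMS) -> float:
    """Similarity s = SW(a,b) / min(SW(a,a), SW(b,b)), clipped to [0, 1]."""
    raw = sw_score(seq_a, seq_b, params)
    denom = min(self_score(seq_a, params), self_score(seq_b, params))
    if denom <= 0:
        return 0.0
    return min(1.0, raw / denom)


def evalue(raw_score: float, len_a: int, len_b: int,
           params: AlignmentParams = DEFAULT_PARAMS) -> float:
    """Karlin-Altschul expected number of chance alignments at score >= S.

    E = K * m * n * exp(-lambda * S); strictly decreasing in S and linear in
    the search-space product m * n.
    """
    if raw_score < 0:
        raise AlignmentError("raw_score must be non-negative")
    if len_a < 1 or len_b < 1:
        raise AlignmentError("sequence lengths must be >= 1")
    return params.karlin_k * len_a * len_b * math.exp(-params.karlin_lambda * raw_score)


@dataclass(frozen=True)
class HomologPair:
    """One filtered cross-genome protein-pair similarity (a dashed line)."""

    gene_a: str
    gene_b: str
    raw_score: float
    norm_score: float
    evalue: float


@dataclass
class HomologGraph:
    """The set of homolog pairs between genome A and genome B.

    One-to-many pairings are retained on purpose: a partner gene split into
    two fragment annotations pairs both fragments with the same genome-A gene.
    """

    genome_a_id: str
    genome_b_id: str
    pairs: list[HomologPair] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_a: dict[str, list[HomologPair]] = {}
        self._by_b: dict[str, list[HomologPair]] = {}
        for p in self.pairs:
            self._by_a.setdefault(p.gene_a, []).append(p)
            self._by_b.setdefault(p.gene_b, []).append(p)

    def __len__(self) -> int:
        return len(self.pairs)

    def partners_of_a(self, gene_a: str) -> list[HomologPair]:
        return list(self._by_a.get(gene_a, []))

    def partners_of_b(self, gene_b: str) -> list[HomologPair]:
        return list(self._by_b.get(gene_b, []))

    def pair_set(self) -> set[tuple[str, str]]:
        return {(p.gene_a, p.gene_b) for p in self.pairs}

    def swapped(self) -> "HomologGraph":
        """The same graph with genome roles exchanged."""
        return HomologGraph(
            genome_a_id=self.genome_b_id,
            genome_b_id=self.genome_a_id,
            pairs=[
                HomologPair(p.gene_b, p.gene_a, p.raw_score, p.norm_score, p.evalue)
                for p in self.pairs
            ],
        )


def build_homolog_graph(genome_a: GenomeTable, genome_b: GenomeTable,
                        params: AlignmentParams = DEFAULT_PARAMS) -> HomologGraph:
    """All-vs-all comparison of the two proteomes, filtered at the E-value cut.

    Every cross-genome gene pair whose local alignment satisfies
    e < evalue_threshold enters the graph with its raw and normalized score.
    No heuristic pre-filtering: inputs are locus-scale.
    """
    if not genome_a.proteome or not genome_b.proteome:
        raise AlignmentError("cannot build homolog graph from an empty proteome")
    aligner = _aligner(params)

    selfs: dict[tuple[str, str], float] = {}

    def self_of(genome: GenomeTable, gene_id: str) -> float:
        key = (genome.genome_id, gene_id)
        if key not in selfs:
            seq = _sanitize_protein(genome.protein(gene_id))
            selfs[key] = max(0.0, float(aligner.score(seq, seq)))
        return selfs[key]

    pairs: list[HomologPair] = []
    seqs_b = {g.gene_id: _sanitize_protein(genome_b.protein(g.gene_id)) for g in genome_b.genes}
    for ga in genome_a.genes:
        seq_a = _sanitize_protein(genome_a.protein(ga.gene_id))
        for gb in genome_b.genes:
            seq_b = seqs_b[gb.gene_id]
            raw = max(0.0, float(aligner.score(seq_a, seq_b)))
            e = evalue(raw, len(seq_a), len(seq_b), params)
            if e < params.evalue_threshold:
                denom = min(self_of(genome_a, ga.gene_id), self_of(genome_b, gb.gene_id))
                norm = min(1.0, raw / denom) if denom > 0 else 0.0
                pairs.append(HomologPair(ga.gene_id, gb.gene_id, raw, norm, e))
    return HomologGraph(genome_a.genome_id, genome_b.genome_id, pairs)


def write_graph(graph: HomologGraph, path) -> None:
    rows = [
        {"gene_a": p.gene_a, "gene_b": p.gene_b, "raw_score": p.raw_score,
         "norm_score": p.norm_score, "evalue": p.evalue}
        for p in graph.pairs
    ]
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "raw_score", "norm_score", "evalue"])
    with open(path, "w") as fh:
        fh.write(f"# genome_a={graph.genome_a_id}\tgenome_b={graph.genome_b_id}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_graph(path) -> HomologGraph:
    with open(path) as fh:
        header = fh.readline().strip()
        meta = dict(kv.split("=", 1) for kv in header.lstrip("# ").split("\t"))
        df = pd.read_csv(fh, sep="\t")
    pairs = [
        HomologPair(str(r.gene_a), str(r.gene_b), float(r.raw_score),
                    float(r.norm_score), float(r.evalue))
        for r in df.itertuples()
    ]
    return HomologGraph(meta["genome_a"], meta["genome_b"], pairs)
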