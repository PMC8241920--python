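"""Independent oracles and toy-instance builders for the test suite.

Everything here is deliberately written from the definitions, without
using the package's own implementations: a three-matrix Gotoh local
aligner, an exhaustive span-pair enumeration for the cumulative-score
trim, and a brute-force syntenic-block finder for seed detection.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

from bgcbound.boundary import ClusterScoringParams, ExtendedWindow, SeedRegion
from bgcbound.core import GeneRecord, GenomeTable
from bgcbound.homology import HomologGraph, HomologPair

NEG_INF = float("-inf")


@lru_cache(maxsize=4)
def _matrix_dict(name: str) -> dict:
    m = substitution_matrices.load(name)
    return {(a, b): float(m[a, b]) for a in m.alphabet for b in m.alphabet}


def gotoh_local_score(seq_a: str, seq_b: str, matrix: str = "BLOSUM62",
                      gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Brute-force affine-gap local alignment (Gotoh three-matrix DP).

    A gap of length L costs gap_open + (L - 1) * gap_extend.  The empty
    alignment scores 0, so the result is never negative.
    """
    sub = _matrix_dict(matrix)
    n, m = len(seq_a), len(seq_b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]      # best ending in a match/mismatch or fresh start
    E = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in seq_a (consuming seq_b)
    F = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in seq_b (consuming seq_a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            s = sub[(seq_a[i - 1], seq_b[j - 1])]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def exhaustive_trim(window: ExtendedWindow, graph: HomologGraph,
                    params: ClusterScoringParams):
    """Direct enumeration of every span pair, straight from the CB definition.

    Returns (cb, (i1, i2, j1, j2)) with the same tie-breaking convention as
    the implementation: ties within 1e-9 prefer the smaller combined span,
    then the leftmost A start, then the leftmost B start.
    """
    wa, wb = window.window_a, window.window_b
    pen = params.negative_penalty
    bpos = {g.gene_id: j for j, g in enumerate(wb)}
    sc: dict[tuple[int, int], float] = {}
    for ia, g in enumerate(wa):
        for p in graph.partners_of_a(g.gene_id):
            jb = bpos.get(p.gene_b)
            if jb is not None:
                sc[(ia, jb)] = max(sc.get((ia, jb), NEG_INF), p.norm_score)
    best = None
    for i1 in range(len(wa)):
        for i2 in range(i1, len(wa)):
            for j1 in range(len(wb)):
                for j2 in range(j1, len(wb)):
                    cb = 0.0
                    for ia in range(i1, i2 + 1):
                        vals = [sc[(ia, jb)] for jb in range(j1, j2 + 1)
                                if (ia, jb) in sc]
                        cb += max(vals) if vals else pen
                    for jb in range(j1, j2 + 1):
                        if not any((ia, jb) in sc for ia in range(i1, i2 + 1)):
                            cb += pen
                    key = ((i2 - i1 + 1) + (j2 - j1 + 1), i1, j1)
                    if (best is None or cb > best[0] + 1e-9
                            or (cb > best[0] - 1e-9 and key < best[1])):
                        best = (cb, key, (i1, i2, j1, j2))
    return best[0], best[2]


def max_block_oracle(partner_of: dict[int, int]) -> int:
    """Longest contiguous A-interval whose one-to-one partners occupy
    consecutive B positions in a constant direction (brute force)."""
    idxs = sorted(partner_of)
    best = 0
    for i in idxs:
        for j in idxs:
            if j < i or any(k not in partner_of for k in range(i, j + 1)):
                continue
            bs = [partner_of[k] for k in range(i, j + 1)]
            diffs = {b2 - b1 for b1, b2 in zip(bs, bs[1:])}
            if len(bs) == 1 or diffs in ({1}, {-1}):
                best = max(best, len(bs))
    return best


# ---------------------------------------------------------------------------
# toy-instance builders
# ---------------------------------------------------------------------------

def make_genome(genome_id: str, n: int, prefix: str = "g") -> GenomeTable:
    """A genome of n placeholder genes (single-residue proteins)."""
    genes = []
    proteome = {}
    for i in range(n):
        gid = f"{prefix}{i:02d}"
        pid = f"{genome_id}.{gid}"
        genes.append(GeneRecord(gene_id=gid, genome_id=genome_id, contig="c1",
                                start=1 + 100 * i, end=50 + 100 * i, strand="+",
                                protein_id=pid))
        proteome[pid] = "M"
    return GenomeTable(genome_id=genome_id, genes=genes, proteome=proteome)


def make_graph(pairs: list[tuple[str, str, float]],
               a_id: str = "A", b_id: str = "B") -> HomologGraph:
    return HomologGraph(a_id, b_id, [
        HomologPair(ga, gb, 100.0 * s, s, 1e-30) for ga, gb, s in pairs
    ])


def random_window_instance(rng: np.random.Generator, max_side: int = 12):
    """A random trim instance: two windows and a random homolog graph."""
    na = int(rng.integers(2, max_side + 1))
    nb = int(rng.integers(2, max_side + 1))
    ga = make_genome("A", na, prefix="a")
    gb = make_genome("B", nb, prefix="b")
    density = float(rng.uniform(0.1, 0.6))
    pairs = []
    for i in range(na):
        for j in range(nb):
            if rng.random() < density:
                s = float(np.round(rng.uniform(0.2, 1.0), 3))
                pairs.append((f"a{i:02d}", f"b{j:02d}", s))
    if not pairs:  # guarantee at least one matched gene
        pairs.append(("a00", "b00", 0.8))
    graph = make_graph(pairs)
    seed = SeedRegion(genes_a=[ga.genes[0]], genes_b=[gb.genes[0]],
                      pairs=[], sum_score=0.0)
    window = ExtendedWindow(window_a=list(ga.genes), window_b=list(gb.genes),
                            seed=seed)
    return window, graph
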