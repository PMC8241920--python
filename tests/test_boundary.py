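"""Seed detection, window extension and cumulative-score boundary trimming."""

import numpy as np
import pytest

from bgcbound.boundary import (BoundaryError, ClusterScoringParams, ExtendedWindow,
                               NoClusterEvidenceError, SeedRegion, detect_seed,
                               extend_seed, predict_cluster, trim_boundaries)
from bgcbound.homology import HomologGraph
from bgcbound.simulate import GenomePairConfig, PartnerSpec, generate_genome_pair

from helpers import (exhaustive_trim, make_genome, make_graph, max_block_oracle,
                     random_window_instance)

DEFAULTS = ClusterScoringParams()


def _window(genome_a, genome_b, a_ids=None, b_ids=None):
    wa = [g for g in genome_a.genes if a_ids is None or g.gene_id in a_ids]
    wb = [g for g in genome_b.genes if b_ids is None or g.gene_id in b_ids]
    seed = SeedRegion(genes_a=[wa[0]], genes_b=[wb[0]], pairs=[], sum_score=0.0)
    return ExtendedWindow(window_a=wa, window_b=wb, seed=seed)


class TestDetectSeed:
    def test_empty_graph_gives_none(self):
        ga, gb = make_genome("A", 6, "a"), make_genome("B", 6, "b")
        graph = HomologGraph("A", "B", [])
        assert detect_seed(graph, ga, gb) is None

    def test_longer_of_two_blocks_wins(self):
        """Blocks of 3 and 5 contiguous ortholog pairs: the 5-block is the seed."""
        ga, gb = make_genome("A", 14, "a"), make_genome("B", 14, "b")
        # block 1: a01..a03 -> b10..b12 ; block 2: a06..a10 -> b02..b06
        pairs = [(f"a{i:02d}", f"b{10 + i - 1:02d}", 0.9) for i in (1, 2, 3)]
        pairs += [(f"a{i:02d}", f"b{i - 4:02d}", 0.5) for i in range(6, 11)]
        graph = make_graph(pairs)
        seed = detect_seed(graph, ga, gb)
        assert [g.gene_id for g in seed.genes_a] == [f"a{i:02d}" for i in range(6, 11)]
        partner_of = {i: i - 4 for i in range(6, 11)}
        partner_of.update({i: 10 + i - 1 for i in (1, 2, 3)})
        assert len(seed) == max_block_oracle(partner_of) == 5

    def test_inverted_runs_are_detected(self):
        ga, gb = make_genome("A", 8, "a"), make_genome("B", 8, "b")
        pairs = [(f"a{i:02d}", f"b{6 - i:02d}", 0.7) for i in range(1, 5)]
        graph = make_graph(pairs)
        seed = detect_seed(graph, ga, gb)
        assert seed is not None and seed.inverted
        assert len(seed) == 4

    def test_blocks_below_min_seed_len_ignored(self):
        ga, gb = make_genome("A", 6, "a"), make_genome("B", 6, "b")
        graph = make_graph([("a01", "b01", 0.9), ("a02", "b02", 0.9)])
        assert detect_seed(graph, ga, gb) is None

    def test_m7_seed_spans_g_to_k_with_split_partner(self, m7_prediction):
        seed = m7_prediction.seed
        assert [g.gene_id for g in seed.genes_a] == \
            ["mrpigG", "mrpigH", "mrpigI", "mrpigJ", "mrpigK"]
        assert len(seed.genes_b) == 6  # the mrpigH partner is two fragments
        assert {g.gene_id for g in seed.genes_b} == {
            "TM_mrpigG", "TM_mrpigH_f1", "TM_mrpigH_f2",
            "TM_mrpigI", "TM_mrpigJ", "TM_mrpigK"}


class TestExtendSeed:
    def _seeded(self, n, seed_span):
        genome = make_genome("A", n, "a")
        seed_genes = genome.genes[seed_span[0]: seed_span[1] + 1]
        return genome, SeedRegion(genes_a=seed_genes, genes_b=seed_genes,
                                  pairs=[], sum_score=0.0)

    def test_five_gene_seed_extends_to_35_gene_window(self):
        genome, seed = self._seeded(60, (20, 24))
        window = extend_seed(seed, genome, genome)
        idx = [g.order_index for g in window.window_a]
        assert len(idx) == 35 and idx[0] == 5 and idx[-1] == 39

    def test_window_truncated_at_contig_start(self):
        genome, seed = self._seeded(60, (2, 6))
        window = extend_seed(seed, genome, genome)
        idx = [g.order_index for g in window.window_a]
        assert idx[0] == 0 and idx[-1] == 21 and len(idx) == 22

    def test_odd_flank_remainder_goes_upstream(self):
        genome, seed = self._seeded(60, (20, 23))  # 4-gene seed
        window = extend_seed(seed, genome, genome)
        idx = [g.order_index for g in window.window_a]
        assert len(idx) == 35
        assert 20 - idx[0] == 16 and idx[-1] - 23 == 15


class TestTrimBoundaries:
    def test_saturated_windows_keep_everything(self):
        ga, gb = make_genome("A", 5, "a"), make_genome("B", 5, "b")
        pairs = [(f"a{i:02d}", f"b{i:02d}", 1.0) for i in range(5)]
        call = trim_boundaries(_window(ga, gb), make_graph(pairs), DEFAULTS)
        assert call.n_genes_a == call.n_genes_b == 5
        assert call.cb_score == pytest.approx(5.0)

    def test_negative_interior_gene_bridged_when_worth_it(self):
        """Contributions +0.5, -0.3, +0.9: the whole span scores CB = 1.1."""
        ga, gb = make_genome("A", 3, "a"), make_genome("B", 2, "b")
        graph = make_graph([("a00", "b00", 0.5), ("a02", "b01", 0.9)])
        window = _window(ga, gb)
        call = trim_boundaries(window, graph, DEFAULTS)
        assert call.cb_score == pytest.approx(1.1)
        assert (call.i_begin, call.i_end) == ("a00", "a02")
        cb, spans = exhaustive_trim(window, graph, DEFAULTS)
        assert call.cb_score == pytest.approx(cb)

    def test_window_without_any_match_is_an_error(self):
        ga, gb = make_genome("A", 3, "a"), make_genome("B", 3, "b")
        with pytest.raises(NoClusterEvidenceError):
            trim_boundaries(_window(ga, gb), HomologGraph("A", "B", []), DEFAULTS)

    def test_matches_exhaustive_span_enumeration(self):
        """>= 100 random windows (<= 12 genes/side) against the brute force."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            window, graph = random_window_instance(rng)
            call = trim_boundaries(window, graph, DEFAULTS)
            cb, (i1, i2, j1, j2) = exhaustive_trim(window, graph, DEFAULTS)
            assert call.cb_score == pytest.approx(cb, abs=1e-9)
            assert (call.i_begin, call.i_end) == (
                window.window_a[i1].gene_id, window.window_a[i2].gene_id)
            assert (call.j_begin, call.j_end) == (
                window.window_b[j1].gene_id, window.window_b[j2].gene_id)

    def test_m7_trim_excludes_flanking_genes(self, m7_prediction):
        call = m7_prediction.call
        assert (call.i_begin, call.i_end) == ("mrpigA", "mrpigP")
        assert call.n_genes_a == 16
        span_ids = {g.gene_id for g in call.genes_a}
        assert {"mrpigAup1", "mrpigAup2", "mrpigPdown1", "mrpigPdown2"}.isdisjoint(span_ids)

    def test_pm1_partner_span_covers_planted_cluster(self, pm1_pair, pm1_prediction):
        call = pm1_prediction.call
        planted = set(pm1_pair.cluster_genes_b)
        assert {g.gene_id for g in call.genes_b} == planted
        assert call.n_genes_b == 14

    def test_cb_beats_random_alternative_spans(self, m7_prediction):
        window = m7_prediction.window
        graph = m7_prediction.graph
        best = m7_prediction.call.cb_score
        rng = np.random.default_rng(13)
        na, nb = len(window.window_a), len(window.window_b)
        for _ in range(50):
            i = sorted(rng.integers(0, na, 2))
            j = sorted(rng.integers(0, nb, 2))
            sub = ExtendedWindow(window_a=window.window_a[i[0]: i[1] + 1],
                                 window_b=window.window_b[j[0]: j[1] + 1],
                                 seed=window.seed)
            cb, _ = exhaustive_trim_whole_span(sub, graph, DEFAULTS)
            assert best >= cb - 1e-9

    def test_harsher_penalty_never_widens_the_span(self, m7_prediction):
        window, graph = m7_prediction.window, m7_prediction.graph
        prev = None
        for pen in (-0.1, -0.2, -0.3, -0.5, -0.8, -1.2):
            call = trim_boundaries(window, graph,
                                   ClusterScoringParams(negative_penalty=pen))
            width = call.n_genes_a + call.n_genes_b
            if prev is not None:
                assert width <= prev
            prev = width

    def test_cb_at_least_seed_sum_for_positive_seed_scores(self, m7_prediction):
        seed = m7_prediction.seed
        assert all(s > 0 for *_, s in seed.pairs)
        assert m7_prediction.call.cb_score >= seed.sum_score - 1e-9


def exhaustive_trim_whole_span(window, graph, params):
    """CB of one fixed span pair (the whole sub-window), by the definition."""
    wa, wb = window.window_a, window.window_b
    pen = params.negative_penalty
    bpos = {g.gene_id: j for j, g in enumerate(wb)}
    sc = {}
    for ia, g in enumerate(wa):
        for p in graph.partners_of_a(g.gene_id):
            jb = bpos.get(p.gene_b)
            if jb is not None:
                sc[(ia, jb)] = max(sc.get((ia, jb), -1.0), p.norm_score)
    cb = 0.0
    for ia in range(len(wa)):
        vals = [sc[(ia, jb)] for jb in range(len(wb)) if (ia, jb) in sc]
        cb += max(vals) if vals else pen
    for jb in range(len(wb)):
        if not any((ia, jb) in sc for ia in range(len(wa))):
            cb += pen
    return cb, None


class TestPredictCluster:
    def test_m7_end_to_end_recovers_sixteen_genes(self, m7_prediction):
        assert m7_prediction.found
        assert m7_prediction.call.n_genes_a == 16

    def test_unrelated_genomes_report_no_cluster(self):
        a = generate_genome_pair(GenomePairConfig(
            genome_a_id="X", genome_b_id="Y", n_genes_a=8, n_genes_b=8,
            cluster=[], seed=21))
        result = predict_cluster(a.genome_a, a.genome_b)
        assert not result.found
        assert "no seed" in result.reason

    def test_shuffled_copy_recovers_planted_cluster(self):
        pair = generate_genome_pair(GenomePairConfig(
            genome_a_id="P", genome_b_id="Q", n_genes_a=16, n_genes_b=16,
            cluster=[(f"c{i}", PartnerSpec("single", 0.8)) for i in range(6)],
            partner_order=("block_shuffled", 3), length_range=(250, 300), seed=3))
        result = predict_cluster(pair.genome_a, pair.genome_b)
        assert result.found
        assert {g.gene_id for g in result.call.genes_a} == set(pair.cluster_genes_a)
        assert {g.gene_id for g in result.call.genes_b} == set(pair.cluster_genes_b)

    def test_invalid_params_rejected(self):
        with pytest.raises(BoundaryError):
            ClusterScoringParams(negative_penalty=0.3)
        with pytest.raises(BoundaryError):
            ClusterScoringParams(extension_total=2, min_seed_len=3)
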