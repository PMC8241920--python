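"""Shared fixtures: the named synthetic datasets and their pipeline stages.

The comparative stage (all-vs-all protein alignment) is the expensive
part, so genome pairs and their predictions are session-scoped.
"""

import pytest

from bgcbound import simulate
from bgcbound.boundary import predict_cluster
from bgcbound.simulate import GenomePairConfig, PartnerSpec, generate_genome_pair


@pytest.fixture(scope="session")
def m7_pair():
    return simulate.fixture_m7_atcc18224(seed=42)


@pytest.fixture(scope="session")
def m7_prediction(m7_pair):
    return predict_cluster(m7_pair.genome_a, m7_pair.genome_b)


@pytest.fixture(scope="session")
def pm1_pair():
    return simulate.fixture_pm1_nonsyntenic(seed=7)


@pytest.fixture(scope="session")
def pm1_prediction(pm1_pair):
    return predict_cluster(pm1_pair.genome_a, pm1_pair.genome_b)


@pytest.fixture(scope="session")
def fig2b_table():
    return simulate.fixture_fig2b(seed=0)


@pytest.fixture(scope="session")
def fig4_panel():
    return simulate.fixture_fig4(seed=0)


def small_recovery_pair(seed: int):
    """A compact genome pair with planted identities spanning 0.4-0.9,
    cheap enough to rebuild across many seeds."""
    identities = [0.4, 0.5, 0.6, 0.7, 0.8, 0.9]
    cluster = [(f"pg{i}", PartnerSpec("single", ident))
               for i, ident in enumerate(identities)]
    config = GenomePairConfig(
        genome_a_id="recA", genome_b_id="recB",
        n_genes_a=12, n_genes_b=12,
        cluster=cluster, partner_order="syntenic",
        length_range=(250, 350), seed=seed,
    )
    return generate_genome_pair(config)


@pytest.fixture(scope="session")
def recovery_pair():
    return small_recovery_pair(seed=1)
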