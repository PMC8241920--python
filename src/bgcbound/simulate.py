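"""Seeded generators for every input the pipeline consumes.

Genome pairs with planted orthology and synteny structure, qPCR CT tables
with planted regulation classes, and knockout metabolite profiles — plus
the named fixtures used throughout the test suite and the worked example:

``m7_atcc18224``
    Genome A carries the 20-gene pigment locus (mrpigAup2..mrpigPdown2)
    between background flanks; genome B carries a 14-gene non-syntenic
    partner cluster.  Orthologs exist for mrpigA..mrpigP except mrpigF,
    mrpigO and mrpigL; the mrpigH partner is split into two consecutive
    fragment annotations.  Planted identities follow the reported pairwise
    protein identities between the two species where stated (mrpigA 0.66,
    mrpigB 0.46, ... mrpigP 0.57) and default to 0.60 elsewhere.
``pm1_nonsyntenic``
    Fourteen partnered cluster genes whose genome-B copies are
    block-shuffled, preserving a single 3-gene syntenic block for seeding.
``fig2b``
    A CT table for wild type vs the regulator knockout with planted
    regulation classes (six abolished, six moderately downregulated, six
    unchanged, one silent gene).
``fig4``
    Metabolite profiles for the wild type and seven knockout strains
    (core-pigment loss, shunt-product accumulation, ratio shift, and four
    unchanged border knockouts).

Every generator is a pure function of its configuration and seed.
Biological replicate noise in the CT generator is a sample-level shift
shared by all genes of a replicate (RNA-input variation, which the
reference gene cancels); technical noise is independent per well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import GeneRecord, GenomeTable

AA20 = "ACDEFGHIKLMNPQRSTVWY"


class SimulationError(ValueError):
    pass


def _rng(seed: Union[int, np.random.Generator]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def random_protein(length: int, seed: Union[int, np.random.Generator]) -> str:
    rng = _rng(seed)
    return "".join(rng.choice(list(AA20), size=length))


def mutate_to_identity(protein: str, target_identity: float,
                       seed: Union[int, np.random.Generator]) -> str:
    """Substitute residues at random positions to hit a target identity.

    The number of substituted positions is round((1 - target) * L), so the
    realized identity is exact up to rounding; a sequence too short to land
    within +/-0.03 of the target is an error.  Length is always preserved.
    """
    if not (0.2 <= target_identity <= 1.0):
        raise SimulationError("target_identity must lie in [0.2, 1.0]")
    L = len(protein)
    n_mut = round((1.0 - target_identity) * L)
    achieved = 1.0 - n_mut / L if L else 1.0
    if L == 0 or abs(achieved - target_identity) > 0.03:
        raise SimulationError(
            f"cannot reach identity {target_identity} within 0.03 on a {L}-mer"
        )
    if n_mut == 0:
        return protein
    rng = _rng(seed)
    positions = rng.choice(L, size=n_mut, replace=False)
    out = list(protein)
    for pos in positions:
        choices = [c for c in AA20 if c != out[pos]]
        out[pos] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


# ---------------------------------------------------------------------------
# genome pairs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PartnerSpec:
    """How a cluster gene is mirrored in genome B.

    kind: 'none' (unpartnered), 'single' (one ortholog at the given
    identity), or 'split' (the ortholog is mis-annotated as two consecutive
    fragment genes covering its front and back halves).
    """

    kind: str
    identity: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("none", "single", "split"):
            raise SimulationError(f"unknown partner kind {self.kind!r}")
        if self.kind != "none" and not (0.3 <= (self.identity or 0) <= 1.0):
            raise SimulationError("planted identity must lie in [0.3, 1.0]")


@dataclass
class GenomePairConfig:
    genome_a_id: str
    genome_b_id: str
    n_genes_a: int
    n_genes_b: int
    cluster: list[tuple[str, PartnerSpec]]
    #: 'syntenic', ('block_shuffled', preserved_len), or an explicit
    #: permutation of partner-unit indices (A order -> B order)
    partner_order: Union[str, tuple, Sequence[int]] = "syntenic"
    length_range: tuple[int, int] = (250, 450)
    seed: int = 0


@dataclass
class GenomePair:
    """A generated genome pair plus the planted truth for tests."""

    genome_a: GenomeTable
    genome_b: GenomeTable
    truth: dict[str, list[str]]          # gene_a -> planted partner gene ids in B
    cluster_genes_a: list[str]
    cluster_genes_b: list[str]
    config: GenomePairConfig = None


def _max_syntenic_run(b_order: Sequence[int]) -> int:
    """Longest run of A-consecutive units at B-consecutive positions
    (forward or inverted)."""
    pos = {unit: j for j, unit in enumerate(b_order)}
    units = sorted(pos)
    best = 1 if units else 0
    for d in (1, -1):
        run = 1
        for k in range(1, len(units)):
            u_prev, u = units[k - 1], units[k]
            if u == u_prev + 1 and pos[u] == pos[u_prev] + d:
                run += 1
                best = max(best, run)
            else:
                run = 1
    return best


def _block_shuffled_order(n_units: int, preserved_len: int) -> list[int]:
    """Deterministic permutation keeping one preserved block of the given
    length and breaking every other syntenic run down to length < preserved."""
    if preserved_len > n_units:
        raise SimulationError("preserved block longer than the cluster")
    mid = (n_units - preserved_len) // 2
    block = list(range(mid, mid + preserved_len))
    rest = [u for u in range(n_units) if u not in block]
    # pairwise swaps leave only reversed 2-runs, then interleave the halves
    swapped = []
    for i in range(0, len(rest) - 1, 2):
        swapped.extend([rest[i + 1], rest[i]])
    if len(rest) % 2:
        swapped.append(rest[-1])
    half = len(swapped) // 2
    order = swapped[:half] + block + swapped[half:]
    if _max_syntenic_run(order) != preserved_len:
        raise SimulationError(
            "block-shuffled order failed to preserve a unique block; "
            "supply an explicit permutation"
        )
    return order


def _gene_records(genome_id: str, names_proteins: list[tuple[str, str]]) -> GenomeTable:
    genes = []
    proteome = {}
    for i, (name, prot) in enumerate(names_proteins):
        pid = f"{genome_id}.p.{name}"
        start = 1 + 2000 * i
        genes.append(GeneRecord(
            gene_id=name, genome_id=genome_id, contig="contig1",
            start=start, end=start + 3 * len(prot), strand="+", protein_id=pid,
        ))
        proteome[pid] = prot
    return GenomeTable(genome_id=genome_id, genes=genes, proteome=proteome)


def generate_genome_pair(config: GenomePairConfig) -> GenomePair:
    """Plant a cluster with the configured orthology into two genomes.

    Background genes are independent random proteins (uniform residue
    frequencies); cluster genes sit contiguously in genome A; partner
    copies are placed in genome B in the configured order, a split partner
    emitting two consecutive fragment genes covering its halves.
    """
    rng = _rng(config.seed)
    lo, hi = config.length_range

    cluster_a: list[tuple[str, str]] = []
    units: list[list[tuple[str, str]]] = []   # per partnered A gene, B genes
    unit_sources: list[str] = []
    truth: dict[str, list[str]] = {}
    for name, spec in config.cluster:
        length = int(rng.integers(lo, hi + 1))
        prot = random_protein(length, rng)
        cluster_a.append((name, prot))
        if spec.kind == "none":
            truth[name] = []
            continue
        partner = mutate_to_identity(prot, spec.identity, rng)
        if spec.kind == "single":
            b_name = f"{config.genome_b_id}_{name}"
            units.append([(b_name, partner)])
        else:  # split
            half = len(partner) // 2
            b1, b2 = f"{config.genome_b_id}_{name}_f1", f"{config.genome_b_id}_{name}_f2"
            units.append([(b1, partner[:half]), (b2, partner[half:])])
        unit_sources.append(name)
        truth[name] = [g for g, _ in units[-1]]

    order = config.partner_order
    if order == "syntenic":
        b_order = list(range(len(units)))
    elif isinstance(order, tuple) and order and order[0] == "block_shuffled":
        b_order = _block_shuffled_order(len(units), int(order[1]))
    else:
        b_order = list(order)
        if sorted(b_order) != list(range(len(units))):
            raise SimulationError("partner_order permutation does not cover all units")

    n_bg_a = config.n_genes_a - len(cluster_a)
    cluster_b_flat = [gp for u in b_order for gp in units[u]]
    n_bg_b = config.n_genes_b - len(cluster_b_flat)
    if n_bg_a < 0 or n_bg_b < 0:
        raise SimulationError("n_genes smaller than the planted cluster")

    def backgrounds(prefix: str, n: int) -> list[tuple[str, str]]:
        return [
            (f"{prefix}{i:03d}", random_protein(int(rng.integers(lo, hi + 1)), rng))
            for i in range(n)
        ]

    bg_a = backgrounds(f"{config.genome_a_id}_bg", n_bg_a)
    bg_b = backgrounds(f"{config.genome_b_id}_bg", n_bg_b)
    half_a, half_b = n_bg_a // 2, n_bg_b // 2
    genes_a = bg_a[:half_a] + cluster_a + bg_a[half_a:]
    genes_b = bg_b[:half_b] + cluster_b_flat + bg_b[half_b:]

    return GenomePair(
        genome_a=_gene_records(config.genome_a_id, genes_a),
        genome_b=_gene_records(config.genome_b_id, genes_b),
        truth=truth,
        cluster_genes_a=[n for n, _ in cluster_a],
        cluster_genes_b=[n for n, _ in cluster_b_flat],
        config=config,
    )


# ---------------------------------------------------------------------------
# named genome fixtures
# ---------------------------------------------------------------------------

#: reported cross-species protein identities where stated; 0.60 otherwise
M7_IDENTITIES = {
    "mrpigA": 0.66, "mrpigB": 0.46, "mrpigC": 0.70, "mrpigD": 0.63,
    "mrpigE": 0.70, "mrpigG": 0.71, "mrpigH": 0.65, "mrpigI": 0.60,
    "mrpigJ": 0.58, "mrpigK": 0.58, "mrpigM": 0.60, "mrpigN": 0.65,
    "mrpigP": 0.57,
}

_M7_UNPARTNERED = {"mrpigF", "mrpigO", "mrpigL"}
_M7_FLANKS = {"mrpigAup2", "mrpigAup1", "mrpigPdown1", "mrpigPdown2"}
_M7_SPLIT = "mrpigH"

# partner units in A order: A B C D E | G H I J K | M N | P  (13 units)
# B arrangement: [C D E] [M N] [G H I J K] [A B] [P] — non-syntenic blocks,
# the high-identity G..K block is the unique longest syntenic run.
_M7_B_ORDER = [2, 3, 4, 10, 11, 5, 6, 7, 8, 9, 0, 1, 12]


def m7_cluster_layout() -> list[tuple[str, PartnerSpec]]:
    from .core import MRPIG_LOCUS

    layout = []
    for name in MRPIG_LOCUS:
        if name in _M7_FLANKS or name in _M7_UNPARTNERED:
            layout.append((name, PartnerSpec("none")))
        elif name == _M7_SPLIT:
            layout.append((name, PartnerSpec("split", M7_IDENTITIES[name])))
        else:
            layout.append((name, PartnerSpec("single", M7_IDENTITIES[name])))
    return layout


def fixture_m7_atcc18224(seed: int = 42) -> GenomePair:
    """The 20-gene pigment locus vs a 14-gene non-syntenic partner cluster."""
    config = GenomePairConfig(
        genome_a_id="M7",
        genome_b_id="TM",
        n_genes_a=40,
        n_genes_b=40,
        cluster=m7_cluster_layout(),
        partner_order=_M7_B_ORDER,
        seed=seed,
    )
    return generate_genome_pair(config)


# hand-verified permutation: unique preserved 3-block (units 5,6,7), every
# other syntenic run has length <= 2
_PM1_B_ORDER = [4, 2, 0, 12, 10, 5, 6, 7, 1, 13, 11, 3, 9, 8]

_PM1_IDENTITIES = [0.62, 0.70, 0.55, 0.66, 0.75, 0.80, 0.78, 0.72,
                   0.58, 0.65, 0.60, 0.68, 0.73, 0.57]


def fixture_pm1_nonsyntenic(seed: int = 7) -> GenomePair:
    """Fourteen partnered genes, block-shuffled partner cluster in genome B."""
    cluster = [
        (f"g{i + 1:02d}", PartnerSpec("single", _PM1_IDENTITIES[i]))
        for i in range(14)
    ]
    config = GenomePairConfig(
        genome_a_id="m7locus",
        genome_b_id="PM1",
        n_genes_a=40,
        n_genes_b=40,
        cluster=cluster,
        partner_order=_PM1_B_ORDER,
        seed=seed,
    )
    return generate_genome_pair(config)


# ---------------------------------------------------------------------------
# CT tables
# ---------------------------------------------------------------------------

@dataclass
class ExpressionDesign:
    """Planted per-gene fold changes for a two-strain qPCR experiment."""

    fold_changes: dict[str, float]
    not_expressed: set[str] = field(default_factory=set)
    strain_case: str = "dmrpigB"
    strain_calibrator: str = "M7"
    ref_gene: str = "GAPDH"
    n_bio: int = 3
    n_tech: int = 3
    bio_noise_sd: float = 0.3     # sample-level CT shift per (strain, bio rep)
    tech_noise_sd: float = 0.15   # independent per well
    ref_base_ct: float = 20.0
    target_base_range: tuple[float, float] = (22.0, 26.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bio < 2:
            raise SimulationError("need at least two biological replicates")
        if self.bio_noise_sd < 0 or self.tech_noise_sd < 0:
            raise SimulationError("noise sds must be non-negative")


def generate_ct_table(design: ExpressionDesign) -> pd.DataFrame:
    """Simulate the CT table for the calibrator and case strains.

    The case strain's target CT is shifted by -log2(true fold change);
    the reference gene has fold change 1 by construction.  Genes flagged
    not_expressed are undetermined (NaN) in both strains.
    """
    rng = _rng(design.seed)
    genes = list(design.fold_changes)
    lo, hi = design.target_base_range
    base_ct = {g: float(rng.uniform(lo, hi)) for g in genes}
    base_ct[design.ref_gene] = design.ref_base_ct
    all_genes = genes + [design.ref_gene]

    rows = []
    for strain in (design.strain_calibrator, design.strain_case):
        is_case = strain == design.strain_case
        for b in range(1, design.n_bio + 1):
            sample_shift = rng.normal(0.0, design.bio_noise_sd)
            for gene in all_genes:
                silent = gene in design.not_expressed
                if gene == design.ref_gene:
                    effect = 0.0
                else:
                    fc = design.fold_changes[gene]
                    effect = -math.log2(fc) if is_case else 0.0
                for t in range(1, design.n_tech + 1):
                    noise = rng.normal(0.0, design.tech_noise_sd)
                    ct = float("nan") if silent else base_ct[gene] + effect + sample_shift + noise
                    rows.append({"strain": strain, "gene": gene, "bio_rep": b,
                                 "tech_rep": t, "ct": ct})
    return pd.DataFrame(rows, columns=["strain", "gene", "bio_rep", "tech_rep", "ct"])


#: planted regulation structure of the regulator-knockout experiment;
#: mrpigB itself (deleted in the case strain) is not assayed.  The identity
#: of two of the six moderately downregulated genes is not fully enumerated
#: in the source data; mrpigF and mrpigG are the assumed pair.
FIG2B_CLASSES = {
    "abolished": ("mrpigA", "mrpigH", "mrpigM", "mrpigN", "mrpigO", "mrpigP"),
    "downregulated": ("mrpigD", "mrpigE", "mrpigF", "mrpigG", "mrpigAup1", "mrpigPdown1"),
    "unchanged": ("mrpigAup2", "mrpigC", "mrpigJ", "mrpigK", "mrpigL", "mrpigPdown2"),
    "not_expressed": ("mrpigI",),
}

FIG2B_FOLD_CHANGES = {"abolished": 0.02, "downregulated": 0.4, "unchanged": 1.0,
                      "not_expressed": 1.0}


def fig2b_design(seed: int = 0) -> ExpressionDesign:
    fold = {}
    for cls, genes in FIG2B_CLASSES.items():
        for g in genes:
            fold[g] = FIG2B_FOLD_CHANGES[cls]
    return ExpressionDesign(
        fold_changes=fold,
        not_expressed=set(FIG2B_CLASSES["not_expressed"]),
        seed=seed,
    )


def fixture_fig2b(seed: int = 0) -> pd.DataFrame:
    """The CT table emulating the regulator-knockout expression experiment."""
    return generate_ct_table(fig2b_design(seed))


# ---------------------------------------------------------------------------
# knockout metabolite profiles
# ---------------------------------------------------------------------------

WT_AMOUNTS = {1: 1.0, 2: 0.8, 3: 0.9, 4: 0.7, 5: 0.0, 6: 0.0}

#: per-phenotype compound templates (arbitrary units)
PHENOTYPE_TEMPLATES = {
    "abolished": {1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0, 5: 0.0, 6: 0.0},
    "shunt": {1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0, 5: 0.5, 6: 0.4},
    # yields shifted toward the yellow pigments (compounds 1 and 3)
    "ratio_shift": {1: 2.0, 2: 0.2, 3: 1.8, 4: 0.18, 5: 0.0, 6: 0.0},
    "unchanged": dict(WT_AMOUNTS),
}


@dataclass
class KnockoutPanelConfig:
    """Which strains to simulate and which phenotype template each follows."""

    strains: list[tuple[str, str]]       # (strain, template name)
    wt_strain: str = "M7"
    noise_sd: float = 0.05               # multiplicative (lognormal sigma)


FIG4_STRAINS = [
    ("dmrpigAup2", "unchanged"),
    ("dmrpigAup1", "unchanged"),
    ("dmrpigA", "abolished"),
    ("dmrpigO", "shunt"),
    ("dmrpigP", "ratio_shift"),
    ("dmrpigPdown1", "unchanged"),
    ("dmrpigPdown2", "unchanged"),
]

#: knockout strain -> deleted gene (for evidence integration)
FIG4_STRAIN_GENES = {
    "dmrpigAup2": "mrpigAup2",
    "dmrpigAup1": "mrpigAup1",
    "dmrpigA": "mrpigA",
    "dmrpigO": "mrpigO",
    "dmrpigP": "mrpigP",
    "dmrpigPdown1": "mrpigPdown1",
    "dmrpigPdown2": "mrpigPdown2",
}


def generate_knockout_profiles(config: KnockoutPanelConfig, seed: int):
    """Wild-type profile (fixed template amounts) plus noisy mutant profiles."""
    from .knockout import MetaboliteProfile

    rng = _rng(seed)
    wt = MetaboliteProfile(strain=config.wt_strain, amounts=dict(WT_AMOUNTS))
    mutants = []
    for strain, template in config.strains:
        if template not in PHENOTYPE_TEMPLATES:
            raise SimulationError(f"unknown phenotype template {template!r}")
        amounts = {
            cid: a * float(np.exp(rng.normal(0.0, config.noise_sd))) if a > 0 else 0.0
            for cid, a in PHENOTYPE_TEMPLATES[template].items()
        }
        mutants.append(MetaboliteProfile(strain=strain, amounts=amounts))
    return wt, mutants


def fixture_fig4(seed: int = 0):
    """The eight-strain knockout panel (wild type + seven mutants)."""
    return generate_knockout_profiles(KnockoutPanelConfig(strains=FIG4_STRAINS), seed)


def write_profiles(wt, mutants, path) -> None:
    rows = []
    for prof in [wt] + list(mutants):
        for cid in sorted(prof.amounts):
            rows.append({"strain": prof.strain, "compound": cid,
                         "amount": prof.amounts[cid]})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_ct_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
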