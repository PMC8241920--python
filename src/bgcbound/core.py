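"""Domain types for annotated genomes and the Monascus azaphilone pigment locus.

A genome enters the pipeline as an ordered table of gene models plus the
deduced proteome (protein FASTA).  All downstream reasoning — seed detection,
window extension, boundary trimming — operates on *gene ranks* (order along
the contig), never on nucleotide coordinates, so this module is the single
place where coordinates are turned into ranks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: the 20 standard residues plus X for ambiguous/unknown positions
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

GENE_TABLE_COLUMNS = ["genome_id", "gene_id", "contig", "start", "end", "strand", "protein_id"]


class GenomeError(ValueError):
    """Raised for malformed or inconsistent genome inputs."""


@dataclass(frozen=True)
class GeneRecord:
    """One gene model: 1-based inclusive coordinates, strand, protein link.

    ``order_index`` is the 0-based rank of the gene by (contig, start); it is
    assigned by :class:`GenomeTable` / :func:`load_genome`, never by callers.
    """

    gene_id: str
    genome_id: str
    contig: str
    start: int
    end: int
    strand: str
    protein_id: str
    order_index: int = -1

    def __post_init__(self) -> None:
        if self.start < 1:
            raise GenomeError(f"gene {self.gene_id}: start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise GenomeError(f"gene {self.gene_id}: end {self.end} < start {self.start}")
        if self.strand not in ("+", "-"):
            raise GenomeError(f"gene {self.gene_id}: strand must be '+' or '-'")


def _sanitize_protein(seq: str) -> str:
    """Uppercase and map non-standard residues (B, Z, J, U, O, *, ...) to X."""
    seq = seq.upper().rstrip("*")
    return "".join(c if c in AA_ALPHABET else "X" for c in seq)


@dataclass
class GenomeTable:
    """An ordered gene list with its companion proteome.

    Genes are kept sorted by (contig, start) and order_index is the global
    0-based rank under that sort.  Strand is ignored for ordering: the
    comparative method reasons about gene ranks, not transcriptional
    orientation.
    """

    genome_id: str
    genes: list[GeneRecord]
    proteome: dict[str, str]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise GenomeError(f"duplicate gene_id {g.gene_id!r} in genome {self.genome_id}")
            seen.add(g.gene_id)
        ordered = sorted(self.genes, key=lambda g: (g.contig, g.start))
        self.genes = [replace(g, order_index=i) for i, g in enumerate(ordered)]
        for g in self.genes:
            if g.protein_id not in self.proteome:
                raise GenomeError(
                    f"gene {g.gene_id!r} references protein {g.protein_id!r} "
                    f"absent from the proteome of {self.genome_id}"
                )
        clean = {}
        for pid, seq in self.proteome.items():
            s = _sanitize_protein(seq)
            if not s:
                raise GenomeError(f"protein {pid!r} in genome {self.genome_id} is empty")
            clean[pid] = s
        self.proteome = clean
        self._by_id = {g.gene_id: g for g in self.genes}

    def __len__(self) -> int:
        return len(self.genes)

    def gene(self, gene_id: str) -> GeneRecord:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise GenomeError(f"gene {gene_id!r} not found in genome {self.genome_id}") from None

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def protein(self, gene_id: str) -> str:
        return self.proteome[self.gene(gene_id).protein_id]

    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]


def load_genome(gene_table_path, fasta_path) -> GenomeTable:
    """Read a gene table (TSV) and proteome (FASTA) into a validated GenomeTable.

    The TSV must carry the columns genome_id, gene_id, contig, start, end,
    strand, protein_id.  Every gene must reference a sequence present in the
    FASTA; missing or duplicate entries are hard errors naming the offender.
    """
    df = pd.read_csv(gene_table_path, sep="\t", dtype=str)
    missing = [c for c in GENE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise GenomeError(f"gene table {gene_table_path} lacks columns: {missing}")
    if df.empty:
        raise GenomeError(f"gene table {gene_table_path} is empty")
    genome_ids = df["genome_id"].unique()
    if len(genome_ids) != 1:
        raise GenomeError(f"gene table mixes genome_ids {sorted(genome_ids)}")
    proteome = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    genes = [
        GeneRecord(
            gene_id=row.gene_id,
            genome_id=row.genome_id,
            contig=row.contig,
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
            protein_id=row.protein_id,
        )
        for row in df.itertuples()
    ]
    return GenomeTable(genome_id=str(genome_ids[0]), genes=genes, proteome=proteome)


def write_genome(genome: GenomeTable, gene_table_path, fasta_path) -> None:
    """Serialize a GenomeTable back to TSV + FASTA (inverse of load_genome)."""
    rows = [
        {
            "genome_id": g.genome_id,
            "gene_id": g.gene_id,
            "contig": g.contig,
            "start": g.start,
            "end": g.end,
            "strand": g.strand,
            "protein_id": g.protein_id,
        }
        for g in genome.genes
    ]
    pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS).to_csv(gene_table_path, sep="\t", index=False)
    records = [
        SeqRecord(Seq(seq), id=pid, description="")
        for pid, seq in genome.proteome.items()
    ]
    SeqIO.write(records, str(fasta_path), "fasta")


def span_genes(genome: GenomeTable, from_gene: str, to_gene: str) -> list[GeneRecord]:
    """Inclusive ordered list of genes between two same-contig endpoints."""
    a = genome.gene(from_gene)
    b = genome.gene(to_gene)
    if a.contig != b.contig:
        raise GenomeError(
            f"genes {from_gene!r} ({a.contig}) and {to_gene!r} ({b.contig}) "
            "lie on different contigs"
        )
    if a.order_index > b.order_index:
        raise GenomeError(f"gene {from_gene!r} does not precede {to_gene!r}")
    return genome.genes[a.order_index : b.order_index + 1]


# ---------------------------------------------------------------------------
# The canonical M. ruber M7 azaphilone pigment locus
# ---------------------------------------------------------------------------

_CLUSTER_LETTERS = "ABCDEFGHIJKLMNOP"  # mrpigA ... mrpigP, 16 genes

_ANNOTATIONS = {
    "mrpigAup2": "hypothetical protein (outside BGC)",
    "mrpigAup1": "hypothetical protein (outside BGC)",
    "mrpigA": "non-reducing polyketide synthase (core)",
    "mrpigB": "Zn(II)2Cys6 pathway-specific transcriptional regulator",
    "mrpigC": "C11-ketoreductase",
    "mrpigD": "4-O-acyltransferase",
    "mrpigE": "NADPH-dependent oxidoreductase",
    "mrpigF": "FAD-dependent monooxygenase",
    "mrpigG": "dehydrogenase",
    "mrpigH": "FAD-dependent oxidoreductase",
    "mrpigI": "transcription factor, no apparent pigment role",
    "mrpigJ": "fatty acid synthase alpha subunit",
    "mrpigK": "fatty acid synthase beta subunit",
    "mrpigL": "ankyrin repeat protein, no pigment role",
    "mrpigM": "acyl transferase",
    "mrpigN": "FAD-dependent monooxygenase",
    "mrpigO": "deacetylase",
    "mrpigP": "MFS transporter",
    "mrpigPdown1": "hypothetical protein (outside BGC)",
    "mrpigPdown2": "hypothetical protein (outside BGC)",
}


@dataclass(frozen=True)
class LocusRegistry:
    """Ordered gene names of the canonical pigment locus with annotations.

    The locus runs mrpigAup2, mrpigAup1, mrpigA..mrpigP, mrpigPdown1,
    mrpigPdown2 — 20 genes in all; the biosynthetic cluster proper is the
    16-gene run mrpigA..mrpigP.
    """

    names: tuple[str, ...]
    annotations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise GenomeError("locus registry contains duplicate names")

    @property
    def cluster_names(self) -> tuple[str, ...]:
        """The mrpigA..mrpigP sub-list (the 16-gene BGC)."""
        i = self.names.index("mrpigA")
        j = self.names.index("mrpigP")
        return self.names[i : j + 1]

    def annotation(self, name: str) -> str:
        return self.annotations.get(name, "")

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)


def mrpig_locus() -> LocusRegistry:
    """The 20-gene mrpigAup2..mrpigPdown2 locus registry."""
    names = (
        ["mrpigAup2", "mrpigAup1"]
        + [f"mrpig{c}" for c in _CLUSTER_LETTERS]
        + ["mrpigPdown1", "mrpigPdown2"]
    )
    return LocusRegistry(names=tuple(names), annotations=dict(_ANNOTATIONS))


#: module-level singleton used throughout the package
MRPIG_LOCUS = mrpig_locus()
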