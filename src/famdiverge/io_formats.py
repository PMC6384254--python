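"""Readers and writers for the file dialects the pipeline touches.

External files use the community conventions: FASTA wrapped at 60 columns,
GFF3 with 1-based inclusive coordinates, and a flat tab-separated gene
catalog (one row per gene) that carries the census data — species, insect
order, family label (``treh`` or ``ath``), scaffold placement and the
comma-joined transcript identifiers.  All downstream modules consume only
the in-memory types defined here; interval arithmetic elsewhere is 0-based
half-open, and the converters in this module are the only crossing points.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from famdiverge.errors import FormatError, ValidationError

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
ALIGNED_PROTEIN_ALPHABET = PROTEIN_ALPHABET | {"-"}

_ALPHABETS: Mapping[str, frozenset] = {
    "nucleotide": NUCLEOTIDE_ALPHABET,
    "protein": PROTEIN_ALPHABET,
    "aligned-protein": ALIGNED_PROTEIN_ALPHABET,
}

FAMILIES = ("treh", "ath")

GENE_TABLE_COLUMNS = (
    "species",
    "order",
    "family",
    "gene_id",
    "scaffold",
    "start",
    "end",
    "strand",
    "transcript_ids",
)


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence over a declared alphabet.

    ``alphabet`` is one of ``nucleotide`` (A,C,G,T,N), ``protein``
    (20 residues + X) or ``aligned-protein`` (protein + the gap ``-``).
    """

    id: str
    residues: str
    alphabet: str = "nucleotide"

    def __post_init__(self) -> None:
        if self.alphabet not in _ALPHABETS:
            raise ValidationError(f"unknown alphabet {self.alphabet!r}")
        allowed = _ALPHABETS[self.alphabet]
        for pos, ch in enumerate(self.residues):
            if ch not in allowed:
                raise ValidationError(
                    f"illegal character {ch!r} at position {pos} in record "
                    f"{self.id!r} (alphabet {self.alphabet})"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene of the catalog.

    Coordinates are 1-based inclusive on the scaffold, as in GFF3.
    """

    gene_id: str
    species: str
    order_name: str
    family: str
    scaffold_id: str
    start: int
    end: int
    strand: str
    transcript_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(
                f"gene {self.gene_id!r}: unknown family label {self.family!r}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"gene {self.gene_id!r}: invalid span {self.start}..{self.end}"
            )
        if not self.transcript_ids:
            raise ValidationError(f"gene {self.gene_id!r}: no transcripts")


@dataclass(frozen=True)
class TranscriptRecord:
    """One transcript: ordered exon intervals (1-based inclusive) on a scaffold.

    Exons are stored ascending by start regardless of strand; orientation is
    applied when the coding sequence is assembled.
    """

    transcript_id: str
    gene_id: str
    exons: tuple[tuple[int, int], ...]
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"transcript {self.transcript_id!r}: bad strand {self.strand!r}"
            )
        if not self.exons:
            raise ValidationError(f"transcript {self.transcript_id!r}: no exons")
        prev_end = 0
        for start, end in self.exons:
            if end < start:
                raise ValidationError(
                    f"transcript {self.transcript_id!r}: exon end {end} < start {start}"
                )
            if start <= prev_end:
                raise ValidationError(
                    f"transcript {self.transcript_id!r}: exons overlap or unsorted"
                )
            prev_end = end


@dataclass
class GeneCatalog:
    """Genes plus (optionally) their transcript structures."""

    genes: list[GeneRecord] = field(default_factory=list)
    transcripts: dict[str, TranscriptRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValidationError(f"duplicate gene id {g.gene_id!r} in catalog")
            seen.add(g.gene_id)

    def gene(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


def to_half_open(start_1based: int, end_1based: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval to 0-based half-open."""
    return start_1based - 1, end_1based


def to_one_based(start0: int, end0: int) -> tuple[int, int]:
    """Convert a 0-based half-open interval to 1-based inclusive."""
    return start0 + 1, end0


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, alphabet: str = "nucleotide") -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Record order is preserved and residues are upper-cased.  Duplicate ids
    and characters outside the declared alphabet are hard errors.  Gaps are
    legal only under the ``aligned-protein`` alphabet.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"FASTA file not found: {path}")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq).upper(), alphabet))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records wrapped at 60 columns (standard FASTA convention)."""
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description="") for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=60)
        writer.write_file(bio)


def fasta_string(records: Iterable[SequenceRecord]) -> str:
    """FASTA text (60-column wrap) as a string, for in-memory round trips."""
    buf = io.StringIO()
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description="") for r in records
    ]
    SeqIO.FastaIO.FastaWriter(buf, wrap=60).write_file(bio)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: str | Path) -> GeneCatalog:
    """Ingest gene/mRNA/exon features of a GFF3 file.

    Coordinates stay 1-based inclusive.  Strand propagates from the gene to
    its transcripts; mRNAs whose ``Parent`` does not name a gene in the file
    are rejected as orphans.  The catalog-level attributes ``species``,
    ``order`` and ``family`` are read from the gene attributes when present
    (the gene-catalog TSV is the authoritative carrier otherwise).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"GFF3 file not found: {path}")
    db = gffutils.create_db(
        str(path), dbfn=":memory:", keep_order=True, merge_strategy="error"
    )
    gene_ids = {f.id for f in db.features_of_type("gene")}

    transcripts: dict[str, TranscriptRecord] = {}
    genes: list[GeneRecord] = []
    for mrna in db.features_of_type("mRNA"):
        parents = mrna.attributes.get("Parent", [])
        if not parents or parents[0] not in gene_ids:
            raise FormatError(f"orphan mRNA {mrna.id!r}: Parent missing or unknown")
    for gene in db.features_of_type("gene"):
        if gene.end < gene.start:
            raise FormatError(f"gene {gene.id!r}: end < start")
        tx_ids: list[str] = []
        for mrna in db.children(gene, featuretype="mRNA", order_by="start"):
            exons = []
            for exon in db.children(mrna, featuretype="exon", order_by="start"):
                if exon.end < exon.start:
                    raise FormatError(f"exon of {mrna.id!r}: end < start")
                exons.append((exon.start, exon.end))
            transcripts[mrna.id] = TranscriptRecord(
                transcript_id=mrna.id,
                gene_id=gene.id,
                exons=tuple(sorted(exons)),
                strand=gene.strand,
            )
            tx_ids.append(mrna.id)
        if not tx_ids:
            raise FormatError(f"gene {gene.id!r} has no mRNA children")
        attrs = gene.attributes
        genes.append(
            GeneRecord(
                gene_id=gene.id,
                species=attrs.get("species", ["unknown"])[0],
                order_name=attrs.get("order", ["unknown"])[0],
                family=attrs.get("family", ["treh"])[0],
                scaffold_id=gene.seqid,
                start=gene.start,
                end=gene.end,
                strand=gene.strand,
                transcript_ids=tuple(tx_ids),
            )
        )
    genes.sort(key=lambda g: (g.species, g.gene_id))
    return GeneCatalog(genes=genes, transcripts=transcripts)


# ---------------------------------------------------------------------------
# Gene-catalog TSV
# ---------------------------------------------------------------------------

def read_gene_table(path: str | Path) -> list[GeneRecord]:
    """Read the flat gene-catalog TSV (one row per gene).

    Expected header columns: ``species, order, family, gene_id, scaffold,
    start, end, strand, transcript_ids`` with transcript ids comma-joined.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"gene table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in GENE_TABLE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"gene table {path} is missing column {col!r}")
    records: list[GeneRecord] = []
    for row in df.itertuples(index=False):
        if row.family not in FAMILIES:
            raise FormatError(
                f"gene {row.gene_id!r}: unknown family label {row.family!r}"
            )
        records.append(
            GeneRecord(
                gene_id=row.gene_id,
                species=row.species,
                order_name=row.order,
                family=row.family,
                scaffold_id=row.scaffold,
                start=int(row.start),
                end=int(row.end),
                strand=row.strand,
                transcript_ids=tuple(str(row.transcript_ids).split(",")),
            )
        )
    GeneCatalog(genes=records)  # enforces gene-id uniqueness
    return records


def write_gene_table(records: Sequence[GeneRecord], path: str | Path) -> None:
    """Write the gene catalog with deterministic (species, gene_id) ordering."""
    rows = [
        {
            "species": g.species,
            "order": g.order_name,
            "family": g.family,
            "gene_id": g.gene_id,
            "scaffold": g.scaffold_id,
            "start": g.start,
            "end": g.end,
            "strand": g.strand,
            "transcript_ids": ",".join(g.transcript_ids),
        }
        for g in sorted(records, key=lambda g: (g.species, g.gene_id))
    ]
    pd.DataFrame(rows, columns=list(GENE_TABLE_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )
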