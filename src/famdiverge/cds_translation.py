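"""Coding-sequence assembly and translation.

Exon intervals from the annotation are spliced into a coding nucleotide
sequence in transcript orientation; an open reading frame is then chosen
among the three forward frames (longest ATG..stop, deterministic
tie-breaking) and translated with the standard genetic code.  Forward
frames suffice because :func:`assemble_cds` already orients minus-strand
transcripts by reverse complementation.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from famdiverge.errors import ValidationError
from famdiverge.io_formats import SequenceRecord, TranscriptRecord, to_half_open


class NoOrfError(ValidationError):
    """No ATG..stop open reading frame exists in any forward frame."""


@dataclass(frozen=True)
class OrfCall:
    """A chosen open reading frame on an assembled CDS.

    ``nt_span`` is 0-based half-open on the assembled CDS and covers the
    start codon through the last sense codon (the stop codon is excluded),
    so its length is exactly ``3 * len(protein)``.
    """

    frame: int
    nt_span: tuple[int, int]
    protein: str

    def __post_init__(self) -> None:
        start, end = self.nt_span
        if (end - start) % 3 != 0:
            raise ValidationError("ORF span length not divisible by 3")
        if (end - start) // 3 != len(self.protein):
            raise ValidationError("ORF protein length inconsistent with span")


def assemble_cds(
    transcript: TranscriptRecord, scaffold_seq: SequenceRecord
) -> SequenceRecord:
    """Splice exons into the coding sequence, oriented 5'->3'.

    For minus-strand transcripts the exons (stored in ascending scaffold
    order) are concatenated and the result reverse-complemented.
    """
    n = len(scaffold_seq.residues)
    parts: list[str] = []
    for start1, end1 in transcript.exons:
        s0, e0 = to_half_open(start1, end1)
        if s0 < 0 or e0 > n:
            raise ValidationError(
                f"exon {start1}..{end1} of {transcript.transcript_id!r} "
                f"outside scaffold bounds (length {n})"
            )
        parts.append(scaffold_seq.residues[s0:e0])
    cds = "".join(parts)
    if transcript.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    return SequenceRecord(transcript.transcript_id, cds, "nucleotide")


def translate(nt: SequenceRecord | str, frame: int) -> str:
    """Standard-code translation of one forward frame.

    The trailing partial codon is dropped; internal stops render as ``*``;
    any codon containing N that cannot be resolved translates to ``X``.
    """
    if frame not in (0, 1, 2):
        raise ValidationError(f"frame must be 0, 1 or 2, got {frame}")
    seq = nt.residues if isinstance(nt, SequenceRecord) else nt
    sub = seq[frame:]
    sub = sub[: len(sub) - len(sub) % 3]
    if not sub:
        return ""
    return str(Seq(sub).translate())


def find_orf(cds: SequenceRecord) -> OrfCall:
    """Longest ATG..stop open reading frame over the three forward frames.

    Ties break by smaller frame index, then leftmost start.  Raises
    :class:`NoOrfError` when no complete ORF exists (callers may fall back
    to a frame-0 full translation and log the fact).
    """
    if len(cds.residues) < 3:
        raise ValidationError("CDS shorter than one codon")
    best: OrfCall | None = None
    for frame in range(3):
        aa = translate(cds, frame)
        pos = 0
        while True:
            m = aa.find("M", pos)
            if m == -1:
                break
            stop = aa.find("*", m)
            if stop == -1:
                break
            protein = aa[m:stop]
            nt_start = frame + 3 * m
            call = OrfCall(frame, (nt_start, nt_start + 3 * len(protein)), protein)
            if best is None or len(call.protein) > len(best.protein):
                best = call
            # later Ms before this stop yield shorter ORFs; skip past the stop
            pos = stop + 1
    if best is None:
        raise NoOrfError(f"no ATG..stop open reading frame in {cds.id!r}")
    return best
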