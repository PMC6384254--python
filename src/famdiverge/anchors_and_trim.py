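"""Anchor-domain location and alignment trimming.

Trehalase proteins carry seven short conserved domains (six discrete motifs
plus the glycine-rich GGGEYE region).  Each anchor is located per sequence
in the degapped row by a fewest-mismatch degenerate scan, mapped back
through the gaps to alignment columns, and the per-sequence column
intervals are reduced to a single alignment-level interval by modal vote.
The alignment is then trimmed to the region spanned by the outermost
located anchors — inclusive of both anchor spans — before any distance or
conservation computation.

Sequences in which an anchor cannot be located within the mismatch budget
are flagged, not dropped: divergent paralogs stay in the trimmed alignment.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from famdiverge.errors import ValidationError
from famdiverge.io_formats import SequenceRecord, read_fasta, write_fasta
from famdiverge.motif_scan import MotifPattern, best_match, compile_pattern

#: The seven conserved trehalase anchor domains, N- to C-terminal.
TREH_ANCHOR_SPECS: tuple[tuple[str, str], ...] = (
    ("d1_VIVPGGR", "VIVPGGR"),
    ("d2_QWDYPNAWPP", "QWDYPNAWPP"),
    ("d3_DSKTFVDM", "DSKTFVDM"),
    ("d4_RSQPPL", "RSQPPL"),
    ("d5_PRPESYREDY", "PRPESYREDY"),
    ("d6_ELKAA", "ELKAA"),
    ("d7_GGGEYE", "GGGEYE"),
)

DEFAULT_MISMATCH_BUDGET = 1


@dataclass(frozen=True)
class ProteinAlignment:
    """Aligned amino-acid rows (gap character ``-``), all equal width."""

    rows: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValidationError("alignment has no rows")
        width = len(self.rows[0][1])
        for rid, seq in self.rows:
            if len(seq) != width:
                raise ValidationError(f"row {rid!r} has width {len(seq)} != {width}")
        if len({rid for rid, _ in self.rows}) != len(self.rows):
            raise ValidationError("duplicate row ids in alignment")

    @property
    def width(self) -> int:
        return len(self.rows[0][1])

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(rid for rid, _ in self.rows)

    def row(self, rid: str) -> str:
        for r, seq in self.rows:
            if r == rid:
                return seq
        raise KeyError(rid)

    def slice_columns(self, start: int, end: int) -> "ProteinAlignment":
        if not (0 <= start <= end <= self.width):
            raise ValidationError(f"column slice [{start},{end}) out of bounds")
        return ProteinAlignment(
            tuple((rid, seq[start:end]) for rid, seq in self.rows)
        )

    @classmethod
    def from_records(cls, records: Sequence[SequenceRecord]) -> "ProteinAlignment":
        return cls(tuple((r.id, r.residues) for r in records))

    def to_records(self) -> list[SequenceRecord]:
        return [
            SequenceRecord(rid, seq, "aligned-protein") for rid, seq in self.rows
        ]

    @classmethod
    def read(cls, path: str | Path) -> "ProteinAlignment":
        return cls.from_records(read_fasta(path, "aligned-protein"))

    def write(self, path: str | Path) -> None:
        write_fasta(self.to_records(), path)


@dataclass
class DomainAnchor:
    """One conserved domain located on an alignment.

    ``column_interval`` is the alignment-level (modal) 0-based half-open
    column interval, or None when the anchor could be located in fewer than
    half of the rows.  ``per_sequence_hits`` maps sequence id to
    ``(ungapped_interval, mismatches)``; ids missing the anchor map to None.
    """

    name: str
    motif: str
    column_interval: tuple[int, int] | None = None
    per_sequence_hits: dict = field(default_factory=dict)

    @property
    def located_ids(self) -> list[str]:
        return [k for k, v in self.per_sequence_hits.items() if v is not None]


def degap(aligned: str) -> str:
    return aligned.replace("-", "")


def ungapped_to_columns(aligned: str, start: int, end: int) -> tuple[int, int]:
    """Map a 0-based half-open interval on the degapped row to columns.

    The returned column interval covers exactly the residues of the
    ungapped interval: the number of non-gap characters left of the start
    column equals ``start``.
    """
    if start >= end:
        raise ValidationError("empty interval cannot be mapped")
    positions = [i for i, ch in enumerate(aligned) if ch != "-"]
    if end > len(positions):
        raise ValidationError("ungapped interval beyond sequence length")
    return positions[start], positions[end - 1] + 1


def locate_anchor(
    aligned_row: str, motif: str | MotifPattern, max_mismatch: int
) -> tuple[tuple[int, int], int] | None:
    """Best (fewest-mismatch, then leftmost) occurrence in the degapped row.

    Returns ``(ungapped_interval, mismatches)`` or None (anchor missing).
    """
    pattern = motif if isinstance(motif, MotifPattern) else compile_pattern(motif)
    hit = best_match(degap(aligned_row), pattern, max_mismatch)
    if hit is None:
        return None
    return hit.interval, hit.mismatches


def locate_anchors(
    msa: ProteinAlignment,
    anchor_specs: Sequence[tuple[str, str]] = TREH_ANCHOR_SPECS,
    max_mismatch: int = DEFAULT_MISMATCH_BUDGET,
) -> list[DomainAnchor]:
    """Locate every anchor in every row and vote the alignment-level columns.

    The alignment-level interval of an anchor is the modal per-sequence
    column interval (most frequent ``(start, end)`` pair; ties break to the
    leftmost pair).  Anchors located in fewer than 50% of rows get no
    alignment-level interval.
    """
    anchors: list[DomainAnchor] = []
    for name, spec in anchor_specs:
        pattern = compile_pattern(spec, name)
        hits: dict = {}
        col_intervals: list[tuple[int, int]] = []
        for rid, seq in msa.rows:
            located = locate_anchor(seq, pattern, max_mismatch)
            hits[rid] = located
            if located is not None:
                (s, e), _mm = located
                col_intervals.append(ungapped_to_columns(seq, s, e))
        anchor = DomainAnchor(name=name, motif=spec, per_sequence_hits=hits)
        if len(col_intervals) * 2 >= len(msa.rows) and col_intervals:
            counts = Counter(col_intervals)
            top = max(counts.values())
            anchor.column_interval = min(
                iv for iv, c in counts.items() if c == top
            )
        anchors.append(anchor)
    return anchors


def trim_alignment(
    msa: ProteinAlignment, anchors: Sequence[DomainAnchor]
) -> ProteinAlignment:
    """Trim to the columns spanned by the outermost located anchors.

    Keeps columns from the start of the leftmost alignment-level anchor
    interval through the end of the rightmost one (both anchor spans
    included); row order is unchanged.
    """
    if len(msa.rows) < 2:
        raise ValidationError("trimming requires an alignment of >= 2 rows")
    located = [a for a in anchors if a.column_interval is not None]
    if len(located) < 2:
        raise ValidationError(
            "fewer than two anchors could be located at the alignment level "
            "(each needs hits in >= 50% of rows); inspect the alignment"
        )
    start = min(a.column_interval[0] for a in located)
    end = max(a.column_interval[1] for a in located)
    return msa.slice_columns(start, end)


def shift_anchors(
    anchors: Sequence[DomainAnchor], offset: int
) -> list[DomainAnchor]:
    """Re-express anchor column intervals after removing ``offset`` columns."""
    out = []
    for a in anchors:
        iv = None
        if a.column_interval is not None:
            iv = (a.column_interval[0] - offset, a.column_interval[1] - offset)
        out.append(
            DomainAnchor(a.name, a.motif, iv, dict(a.per_sequence_hits))
        )
    return out


def anchor_report(anchors: Sequence[DomainAnchor]) -> pd.DataFrame:
    """Long-format anchor report: sequence, anchor, span, mismatches, located."""
    rows = []
    for anchor in anchors:
        for rid, hit in anchor.per_sequence_hits.items():
            if hit is None:
                rows.append(
                    {
                        "sequence": rid,
                        "anchor": anchor.name,
                        "start": pd.NA,
                        "end": pd.NA,
                        "mismatches": pd.NA,
                        "located": False,
                    }
                )
            else:
                (s, e), mm = hit
                rows.append(
                    {
                        "sequence": rid,
                        "anchor": anchor.name,
                        "start": s,
                        "end": e,
                        "mismatches": mm,
                        "located": True,
                    }
                )
    return pd.DataFrame(
        rows, columns=["sequence", "anchor", "start", "end", "mismatches", "located"]
    )
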