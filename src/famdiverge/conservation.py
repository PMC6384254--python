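"""Consensus construction and p-distance conservation profiling.

The conservation signal painted onto the family tree is, per anchor domain
and per sequence, the p-distance (proportion of differing compared
columns) between the sequence and the majority-rule consensus of the
trimmed alignment, restricted to that domain's columns.  Gaps and the
ambiguity residue X are treated as non-information: comparisons use
pairwise deletion, and a domain with no comparable columns yields a
missing value rather than an extreme one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from famdiverge.anchors_and_trim import DomainAnchor, ProteinAlignment
from famdiverge.errors import ValidationError


@dataclass(frozen=True)
class ConservationMatrix:
    """Per-sequence, per-anchor p-distance to consensus (NaN = missing)."""

    table: pd.DataFrame  # index: sequence ids, columns: anchor names

    def __post_init__(self) -> None:
        vals = self.table.to_numpy(dtype=float)
        ok = ((vals >= 0) & (vals <= 1)) | (vals != vals)  # NaN passes
        if not ok.all():
            raise ValidationError("conservation values must lie in [0,1] or be NaN")

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="sequence", float_format="%.6f")

    def to_itol_annotation(self, path) -> None:
        """iTOL-compatible heat-strip table keyed by leaf label."""
        with open(path, "w") as fh:
            fh.write("DATASET_HEATMAP\nSEPARATOR TAB\nDATASET_LABEL\tdomain p-distance\n")
            fh.write("FIELD_LABELS\t" + "\t".join(self.table.columns) + "\nDATA\n")
            for rid, row in self.table.iterrows():
                cells = ["" if math.isnan(v) else f"{v:.6f}" for v in row]
                fh.write(rid + "\t" + "\t".join(cells) + "\n")


def consensus(msa: ProteinAlignment) -> str:
    """Majority-rule consensus: per column the most frequent non-gap residue.

    Residue ties break lexicographically; an all-gap column yields ``-``.
    """
    if len(msa.rows) < 2:
        raise ValidationError("consensus requires >= 2 rows")
    out = []
    seqs = [seq for _, seq in msa.rows]
    for j in range(msa.width):
        counts: dict[str, int] = {}
        for seq in seqs:
            ch = seq[j]
            if ch != "-":
                counts[ch] = counts.get(ch, 0) + 1
        if not counts:
            out.append("-")
        else:
            best = max(counts.values())
            out.append(min(ch for ch, c in counts.items() if c == best))
    return "".join(out)


def p_distance(a: str, b: str) -> float:
    """Proportion of differing compared columns (pairwise deletion).

    Only columns where both sequences carry a non-gap, non-X residue are
    compared; with zero comparable columns the distance is missing (NaN).
    """
    if len(a) != len(b):
        raise ValidationError(f"length mismatch: {len(a)} vs {len(b)}")
    compared = 0
    diff = 0
    for x, y in zip(a, b):
        if x in "-X" or y in "-X":
            continue
        compared += 1
        if x != y:
            diff += 1
    if compared == 0:
        return math.nan
    return diff / compared


def domain_conservation(
    msa: ProteinAlignment, anchors: Sequence[DomainAnchor]
) -> ConservationMatrix:
    """Per-sequence, per-anchor p-distance to the alignment consensus.

    The cell for a sequence flagged anchor-missing (or for an anchor with no
    alignment-level interval) is missing, never 1.0.
    """
    cons = consensus(msa)
    data: dict[str, list[float]] = {}
    for anchor in anchors:
        col: list[float] = []
        for rid, seq in msa.rows:
            if (
                anchor.column_interval is None
                or anchor.per_sequence_hits.get(rid) is None
            ):
                col.append(math.nan)
            else:
                s, e = anchor.column_interval
                col.append(p_distance(seq[s:e], cons[s:e]))
        data[anchor.name] = col
    table = pd.DataFrame(data, index=list(msa.ids))
    return ConservationMatrix(table)
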