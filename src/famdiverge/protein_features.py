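"""Protein physicochemistry and membrane-topology heuristics.

Physicochemistry: molecular weight as the sum of average residue masses
plus one water, and isoelectric point by bisection of the Henderson-
Hasselbalch net charge with a configurable pKa set (EMBOSS values by
default, Expasy/Bjellqvist as an alternative).

Topology: the shipped signal-peptide and transmembrane predictors are
documented sliding-window hydropathy heuristics (Kyte-Doolittle scale), a
deliberately simple stand-in behind a pluggable interface — calls from
external predictors can be imported from TSV and substituted for the
heuristic on a per-protein basis.  An isoform is classified membrane-bound
when it carries at least one transmembrane segment outside the N-terminal
signal region, and soluble otherwise — the split used for the
soluble/membrane census of the family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from famdiverge.errors import ValidationError

WATER_MASS = 18.0153

#: Average residue masses (Da): amino-acid mass minus one water.
AVERAGE_RESIDUE_MASS: Mapping[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
_MEAN_RESIDUE_MASS = sum(AVERAGE_RESIDUE_MASS.values()) / len(AVERAGE_RESIDUE_MASS)

#: pKa sets for the ionizable groups: termini plus D, E, C, Y, H, K, R.
PKA_SETS: Mapping[str, Mapping[str, float]] = {
    "emboss": {
        "Nterm": 8.6, "Cterm": 3.6,
        "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
        "H": 6.5, "K": 10.8, "R": 12.5,
    },
    "expasy": {
        "Nterm": 9.094, "Cterm": 3.55,
        "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0,
        "H": 5.98, "K": 10.0, "R": 12.0,
    },
}

#: Kyte-Doolittle hydropathy scale.
KYTE_DOOLITTLE: Mapping[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5, "X": 0.0,
}

TM_WINDOW = 19
DEFAULT_KD_THRESHOLD = 1.6
SIGNAL_MAX_START = 5      # signal-like segment must start within first 5 residues
SIGNAL_MAX_END = 45       # ... and end before residue 45
SIGNAL_MIN_PROTEIN = 30   # shorter proteins are not evaluated for a signal


@dataclass(frozen=True)
class PhysChem:
    """Isoelectric point, average molecular weight (Da) and length (aa)."""

    pI: float
    mw: float
    length: int

    def __post_init__(self) -> None:
        if not (0 < self.pI < 14) or self.mw <= 0 or self.length <= 0:
            raise ValidationError("physicochemical values out of range")


@dataclass(frozen=True)
class TopologyCall:
    """Signal-peptide and transmembrane-segment calls for one protein."""

    has_signal_peptide: bool
    signal_cleavage: int | None
    tm_segments: tuple[tuple[int, int], ...]
    classification: str = field(default="soluble")

    def __post_init__(self) -> None:
        prev_end = -1
        for s, e in self.tm_segments:
            if e - s < 15:
                raise ValidationError("transmembrane segment shorter than 15 residues")
            if s <= prev_end:
                raise ValidationError("overlapping transmembrane segments")
            prev_end = e
        if self.classification not in ("soluble", "membrane_bound"):
            raise ValidationError(f"bad classification {self.classification!r}")


def molecular_weight(protein: str) -> float:
    """Average molecular weight in Da (residue masses + one water).

    The ambiguity residue X contributes the mean of the twenty residue
    masses.
    """
    if not protein:
        raise ValidationError("cannot compute molecular weight of empty protein")
    total = WATER_MASS
    for ch in protein:
        if ch == "X":
            total += _MEAN_RESIDUE_MASS
        elif ch in AVERAGE_RESIDUE_MASS:
            total += AVERAGE_RESIDUE_MASS[ch]
        else:
            raise ValidationError(f"unknown residue {ch!r}")
    return total


def net_charge(protein: str, ph: float, pka_set: str = "emboss") -> float:
    """Henderson-Hasselbalch net charge at the given pH."""
    pka = PKA_SETS[pka_set]

    def positive(pk: float) -> float:
        return 1.0 / (1.0 + 10 ** (ph - pk))

    def negative(pk: float) -> float:
        return -1.0 / (1.0 + 10 ** (pk - ph))

    charge = positive(pka["Nterm"]) + negative(pka["Cterm"])
    for res in "DECY":
        charge += protein.count(res) * negative(pka[res])
    for res in "HKR":
        charge += protein.count(res) * positive(pka[res])
    return charge


def isoelectric_point(protein: str, pka_set: str = "emboss") -> float:
    """pI by bisection of the net charge on [0, 14].

    Iterated to interval convergence (far beyond |charge| < 1e-4), so the
    result matches the sign change of the titration curve even where it is
    nearly flat.
    """
    if not protein:
        raise ValidationError("cannot compute pI of empty protein")
    lo, hi = 0.0, 14.0
    for _ in range(60):
        mid = (lo + hi) / 2.0
        if net_charge(protein, mid, pka_set) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def _qualifying_window_starts(protein: str, threshold: float) -> list[bool]:
    n = len(protein)
    scores = [KYTE_DOOLITTLE.get(ch, 0.0) for ch in protein]
    quals = []
    if n < TM_WINDOW:
        return quals
    window_sum = sum(scores[:TM_WINDOW])
    quals.append(window_sum / TM_WINDOW >= threshold)
    for i in range(1, n - TM_WINDOW + 1):
        window_sum += scores[i + TM_WINDOW - 1] - scores[i - 1]
        quals.append(window_sum / TM_WINDOW >= threshold)
    return quals


def predict_topology(
    protein: str, kd_threshold: float = DEFAULT_KD_THRESHOLD
) -> TopologyCall:
    """Hydropathy stand-in for signal-peptide / transmembrane prediction.

    A transmembrane-like segment is a maximal run of positions in which
    every 19-residue window has mean Kyte-Doolittle hydropathy at or above
    the threshold.  A segment starting within the first 5 residues and
    ending before residue 45 of a protein of at least 30 residues is
    reported as the signal peptide (cleavage at its end) and kept separate
    from the downstream transmembrane segments.
    """
    quals = _qualifying_window_starts(protein, kd_threshold)
    segments: list[tuple[int, int]] = []
    i = 0
    while i < len(quals):
        if quals[i]:
            j = i
            while j + 1 < len(quals) and quals[j + 1]:
                j += 1
            segments.append((i, j + TM_WINDOW))
            i = j + 1
        i += 1
    # runs of qualifying windows separated by a short dip still cover
    # overlapping residue stretches; report those as one segment
    merged: list[tuple[int, int]] = []
    for s, e in segments:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    segments = merged

    signal: tuple[int, int] | None = None
    if len(protein) >= SIGNAL_MIN_PROTEIN and segments:
        first = segments[0]
        if first[0] < SIGNAL_MAX_START and first[1] < SIGNAL_MAX_END:
            signal = first
            segments = segments[1:]
    call = TopologyCall(
        has_signal_peptide=signal is not None,
        signal_cleavage=signal[1] if signal else None,
        tm_segments=tuple(segments),
        classification="membrane_bound" if segments else "soluble",
    )
    return call


def classify_solubility(call: TopologyCall) -> str:
    """Membrane-bound iff >= 1 TM segment outside the signal region."""
    return "membrane_bound" if call.tm_segments else "soluble"


def physchem(protein: str, pka_set: str = "emboss") -> PhysChem:
    return PhysChem(
        pI=isoelectric_point(protein, pka_set),
        mw=molecular_weight(protein),
        length=len(protein),
    )


def feature_table(
    proteins: Sequence[tuple[str, str]],
    pka_set: str = "emboss",
    kd_threshold: float = DEFAULT_KD_THRESHOLD,
    external_calls: Mapping[str, TopologyCall] | None = None,
) -> pd.DataFrame:
    """Per-protein feature table: id, length, mw, pI, n_tm, signal, class.

    ``external_calls`` (e.g. imported from real signal-peptide /
    transmembrane predictors via :func:`read_topology_tsv`) override the
    hydropathy heuristic per protein id.
    """
    rows = []
    for pid, seq in proteins:
        pc = physchem(seq, pka_set)
        call = (external_calls or {}).get(pid) or predict_topology(seq, kd_threshold)
        rows.append(
            {
                "id": pid,
                "length": pc.length,
                "mw": round(pc.mw, 2),
                "pI": round(pc.pI, 3),
                "n_tm": len(call.tm_segments),
                "signal_peptide": call.has_signal_peptide,
                "classification": classify_solubility(call),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["id", "length", "mw", "pI", "n_tm", "signal_peptide", "classification"],
    )


def read_topology_tsv(path: str | Path) -> dict[str, TopologyCall]:
    """Import externally computed topology calls.

    Columns: ``id``, ``signal`` (true/false), ``cleavage`` (int or empty),
    ``tm_intervals`` (semicolon-joined ``start-end`` 0-based half-open, may
    be empty).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    calls: dict[str, TopologyCall] = {}
    for row in df.itertuples(index=False):
        tm: list[tuple[int, int]] = []
        if row.tm_intervals:
            for part in row.tm_intervals.split(";"):
                s, e = part.split("-")
                tm.append((int(s), int(e)))
        has_signal = str(row.signal).strip().lower() in ("true", "1", "yes")
        calls[row.id] = TopologyCall(
            has_signal_peptide=has_signal,
            signal_cleavage=int(row.cleavage) if str(row.cleavage).strip() else None,
            tm_segments=tuple(tm),
            classification="membrane_bound" if tm else "soluble",
        )
    return calls


def write_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
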