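"""Degenerate consensus-motif compilation and scanning.

The motif syntax is the compact notation used for the trehalase and
acid-trehalase consensus motifs: literal residues, ``X`` for "any residue",
and ``[A/B/C]`` for an alternative set.  The panel below covers the six
discrete acid-trehalase (ATH) motifs — a transmembrane span, the
cAMP-dependent phosphorylation site RRXS, an EF-hand-like Ca2+-binding
motif, the two trehalase signature motifs, and the GPI membrane-anchor
motif — plus the glycine-rich region probe GGGEYE.

Patterns are compiled to explicit position-wise allowed-residue sets (no
regex pass-through) so every scan is auditable and an independent
brute-force oracle can replicate it position by position.
"""

from __future__ import annotations

from dataclasses import dataclass

from famdiverge.errors import ValidationError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: The six acid-trehalase consensus motifs, in fixed panel order.
ATH_MOTIF_SPECS: tuple[tuple[str, str], ...] = (
    ("tm_span", "LFFFFFFFLCFSFTTSML"),
    ("camp_site", "RRXS"),
    ("ef_like", "DTXGDXQITIXD"),
    ("signature_1", "PGGRFXEXYXWDXY"),
    ("signature_2", "QWDXPX[G/A]W[P/A/S]P"),
    ("gpi_anchor", "CRTNYGYSAA"),
)

#: Probe used to seed the glycine-rich region measurement.
GLYCINE_RICH_PROBE = "GGGEYE"


@dataclass(frozen=True)
class MotifPattern:
    """A compiled degenerate motif: one allowed-residue set per position."""

    name: str
    spec: str
    positions: tuple[frozenset, ...]

    @property
    def length(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class MotifMatch:
    """One occurrence of a pattern: 0-based half-open residue interval."""

    pattern_name: str
    sequence_id: str
    interval: tuple[int, int]
    mismatches: int


def compile_pattern(spec: str, name: str | None = None) -> MotifPattern:
    """Parse a degenerate motif spec into position-wise residue sets.

    ``X`` expands to all 20 residues; ``[G/A]`` to the listed alternatives.
    """
    if not spec:
        raise ValidationError("empty motif spec")
    positions: list[frozenset] = []
    i = 0
    while i < len(spec):
        ch = spec[i]
        if ch == "[":
            end = spec.find("]", i)
            if end == -1:
                raise ValidationError(f"unclosed alternative set in {spec!r}")
            residues = [r for r in spec[i + 1 : end].split("/") if r]
            if not residues:
                raise ValidationError(f"empty alternative set in {spec!r}")
            for r in residues:
                if len(r) != 1 or r not in AMINO_ACIDS:
                    raise ValidationError(f"invalid residue {r!r} in {spec!r}")
            positions.append(frozenset(residues))
            i = end + 1
        elif ch == "X":
            positions.append(frozenset(AMINO_ACIDS))
            i += 1
        elif ch in AMINO_ACIDS:
            positions.append(frozenset(ch))
            i += 1
        else:
            raise ValidationError(f"illegal character {ch!r} in motif spec {spec!r}")
    return MotifPattern(name or spec, spec, tuple(positions))


def scan(
    protein: str,
    pattern: MotifPattern,
    max_mismatch: int = 0,
    sequence_id: str = "",
) -> list[MotifMatch]:
    """All occurrences with at most ``max_mismatch`` mismatched positions.

    Matches are returned ascending by offset, then mismatch count.  An
    ambiguous ``X`` in the *protein* never satisfies a literal position.
    """
    L = pattern.length
    hits: list[MotifMatch] = []
    for off in range(len(protein) - L + 1):
        mm = 0
        for j, allowed in enumerate(pattern.positions):
            if protein[off + j] not in allowed:
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            hits.append(MotifMatch(pattern.name, sequence_id, (off, off + L), mm))
    return hits


def best_match(
    protein: str, pattern: MotifPattern, max_mismatch: int
) -> MotifMatch | None:
    """Fewest-mismatch occurrence, ties broken leftmost; None when absent."""
    hits = scan(protein, pattern, max_mismatch)
    if not hits:
        return None
    return min(hits, key=lambda h: (h.mismatches, h.interval[0]))


def compiled_ath_panel() -> tuple[MotifPattern, ...]:
    """The six ATH motifs compiled, in fixed panel order."""
    return tuple(compile_pattern(spec, name) for name, spec in ATH_MOTIF_SPECS)


def ath_motif_profile(
    protein: str, budget: int = 0
) -> dict[str, dict]:
    """Presence of each of the six ATH motifs at budget 0 and at ``budget``.

    Returns, per motif (fixed order: tm_span, camp_site, ef_like,
    signature_1, signature_2, gpi_anchor), whether an exact occurrence
    exists, whether one exists within the configured mismatch budget, and
    the leftmost best offset (or None).
    """
    profile: dict[str, dict] = {}
    for pattern in compiled_ath_panel():
        exact = best_match(protein, pattern, 0)
        budgeted = exact if budget == 0 else best_match(protein, pattern, budget)
        profile[pattern.name] = {
            "present_exact": exact is not None,
            "present_budget": budgeted is not None,
            "offset": budgeted.interval[0] if budgeted else None,
            "mismatches": budgeted.mismatches if budgeted else None,
        }
    return profile


def glycine_rich_extent(protein: str) -> int:
    """Length of the glycine-rich region seeded at GGGEYE, 0 when absent.

    The probe is located with mismatch budget 1 (best occurrence, leftmost
    on ties); the region then grows one residue at a time on either side.
    A candidate boundary residue is accepted when the window of up to five
    residues extending outward from the current edge (candidate included)
    contains at least 40% glycine — so growth stops as soon as the sequence
    beyond the edge is no longer glycine-enriched.
    """
    probe = compile_pattern(GLYCINE_RICH_PROBE, "glycine_rich")
    seed = best_match(protein, probe, 1)
    if seed is None:
        return 0
    start, end = seed.interval

    def gly_frac(segment: str) -> float:
        return segment.count("G") / len(segment) if segment else 0.0

    while start > 0 and gly_frac(protein[max(0, start - 5) : start]) >= 0.4:
        start -= 1
    while end < len(protein) and gly_frac(protein[end : end + 5]) >= 0.4:
        end += 1
    return end - start
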