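"""Micro-synteny and colinearity of scaffold neighborhoods.

For each focal (treh/ath) gene, the neighborhood is the ordered, stranded
list of orthogroup labels of up to k genes on each side of the focal gene
on its scaffold.  Synteny between two neighborhoods is the number of
shared orthogroup labels (set intersection).  Colinearity is scored by the
longest common subsequence of the label orders — subsequence rather than
substring, because conserved order is routinely interrupted by lineage-
specific insertions — taking the better of the two orientations of the
second neighborhood, with strands flipped on reversal so that whole-block
inversions score as perfectly colinear.  Orthogroup labels are an input
column; the module never infers orthology itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from famdiverge.errors import ValidationError

DEFAULT_WINDOW_K = 5


@dataclass(frozen=True)
class ScaffoldNeighborhood:
    """Ordered, stranded orthogroup labels flanking one focal gene."""

    species: str
    scaffold_id: str
    focal_gene_id: str
    neighbors: tuple[tuple[str, str], ...]  # (orthogroup label, strand)

    def labels(self) -> tuple[str, ...]:
        return tuple(lbl for lbl, _ in self.neighbors)


@dataclass(frozen=True)
class SyntenyResult:
    """Pairwise comparison of two neighborhoods (or two species)."""

    species_a: str
    species_b: str
    shared_count: int
    colinear_run: int
    orientation_agreement: float

    def __post_init__(self) -> None:
        if not (0 <= self.colinear_run <= self.shared_count):
            raise ValidationError("colinear run cannot exceed shared count")


def extract_neighborhood(
    scaffold_genes: Sequence[tuple[str, str, str]],
    focal_gene_id: str,
    k: int = DEFAULT_WINDOW_K,
    species: str = "",
    scaffold_id: str = "",
) -> ScaffoldNeighborhood:
    """Up to k genes on each side of the focal gene, in scaffold order.

    ``scaffold_genes`` lists (gene_id, orthogroup label, strand) in
    coordinate order for one scaffold; truncation at scaffold ends is
    silent.  The focal gene itself is excluded from the neighbors.
    """
    idx = [i for i, (gid, _, _) in enumerate(scaffold_genes) if gid == focal_gene_id]
    if not idx:
        raise ValidationError(
            f"focal gene {focal_gene_id!r} not on scaffold {scaffold_id!r}"
        )
    i = idx[0]
    upstream = scaffold_genes[max(0, i - k) : i]
    downstream = scaffold_genes[i + 1 : i + 1 + k]
    return ScaffoldNeighborhood(
        species=species,
        scaffold_id=scaffold_id,
        focal_gene_id=focal_gene_id,
        neighbors=tuple((og, strand) for _, og, strand in upstream + downstream),
    )


def shared_neighbors(a: ScaffoldNeighborhood, b: ScaffoldNeighborhood) -> int:
    """Size of the intersection of orthogroup label sets (multiplicity ignored)."""
    return len(set(a.labels()) & set(b.labels()))


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def _lcs_pairs(
    a: Sequence[tuple[str, str]], b: Sequence[tuple[str, str]]
) -> list[tuple[int, int]]:
    """Longest common subsequence of the label orders, one fixed traceback.

    Returns matched (index in a, index in b) pairs.  Traceback prefers the
    diagonal, then skipping in a, then in b — deterministic.
    """
    n, m = len(a), len(b)
    L = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n - 1, -1, -1):
        for j in range(m - 1, -1, -1):
            if a[i][0] == b[j][0]:
                L[i][j] = 1 + L[i + 1][j + 1]
            else:
                L[i][j] = max(L[i + 1][j], L[i][j + 1])
    pairs: list[tuple[int, int]] = []
    i = j = 0
    while i < n and j < m:
        if a[i][0] == b[j][0] and L[i][j] == 1 + L[i + 1][j + 1]:
            pairs.append((i, j))
            i += 1
            j += 1
        elif L[i + 1][j] >= L[i][j + 1]:
            i += 1
        else:
            j += 1
    return pairs


def colinearity_score(
    a: ScaffoldNeighborhood, b: ScaffoldNeighborhood
) -> tuple[int, float]:
    """(colinear run, orientation agreement), inversion-aware.

    The run is the LCS length of the neighbor orders, taking the better of
    b as given and b reversed with strands flipped (ties prefer the forward
    orientation).  Orientation agreement is the fraction of LCS-matched
    pairs whose relative strand is consistent in the chosen orientation;
    1.0 when the run is empty.
    """
    forward = list(b.neighbors)
    reverse = [(lbl, _flip(s)) for lbl, s in reversed(b.neighbors)]
    scores = []
    for candidate in (forward, reverse):
        pairs = _lcs_pairs(list(a.neighbors), candidate)
        agree = sum(
            1 for i, j in pairs if a.neighbors[i][1] == candidate[j][1]
        )
        agreement = agree / len(pairs) if pairs else 1.0
        scores.append((len(pairs), agreement))
    # on run-length ties the better orientation agreement wins, which makes
    # the score invariant under reversal-with-strand-flip of either input
    return max(scores)


def compare(a: ScaffoldNeighborhood, b: ScaffoldNeighborhood) -> SyntenyResult:
    run, agreement = colinearity_score(a, b)
    shared = shared_neighbors(a, b)
    return SyntenyResult(a.species, b.species, shared, min(run, shared), agreement)


def pairwise_synteny_matrix(
    neighborhoods: Mapping[str, Sequence[ScaffoldNeighborhood]],
) -> pd.DataFrame:
    """Symmetric per-species-pair best synteny.

    For species pairs with several focal scaffolds the reported entry is
    the maximum shared count over neighborhood pairs together with its
    colinearity (ties resolved by input order).  Species without focal
    neighborhoods yield missing rows.
    """
    species = sorted(neighborhoods)
    rows = []
    for i, sa in enumerate(species):
        for sb in species[i + 1 :]:
            best: SyntenyResult | None = None
            for na in neighborhoods[sa]:
                for nb in neighborhoods[sb]:
                    res = compare(na, nb)
                    if best is None or res.shared_count > best.shared_count:
                        best = res
            if best is None:
                rows.append(
                    {
                        "species_a": sa, "species_b": sb,
                        "shared": pd.NA, "colinear_run": pd.NA,
                        "orientation_agreement": pd.NA,
                    }
                )
            else:
                rows.append(
                    {
                        "species_a": sa, "species_b": sb,
                        "shared": best.shared_count,
                        "colinear_run": best.colinear_run,
                        "orientation_agreement": best.orientation_agreement,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["species_a", "species_b", "shared", "colinear_run",
                 "orientation_agreement"],
    )


def intersection_across_species(
    neighborhoods: Mapping[str, Sequence[ScaffoldNeighborhood]],
) -> int:
    """Orthogroups present in every species' pooled neighborhoods.

    Complements the pairwise matrix: the count of neighbor orthogroups
    shared by *all* species simultaneously.
    """
    pools = [
        set().union(*(set(n.labels()) for n in nbhds)) if nbhds else set()
        for nbhds in neighborhoods.values()
    ]
    if not pools:
        return 0
    common = pools[0]
    for p in pools[1:]:
        common &= p
    return len(common)


# ---------------------------------------------------------------------------
# TSV dialect: one row per neighbor, grouped by (species, scaffold, focal)
# ---------------------------------------------------------------------------

NEIGHBORHOOD_COLUMNS = (
    "species", "scaffold", "focal_gene", "position", "orthogroup", "strand"
)


def read_neighborhoods(path: str | Path) -> dict[str, list[ScaffoldNeighborhood]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in NEIGHBORHOOD_COLUMNS:
        if col not in df.columns:
            raise ValidationError(f"neighborhoods file missing column {col!r}")
    df["position"] = df["position"].astype(int)
    out: dict[str, list[ScaffoldNeighborhood]] = {}
    for (species, scaffold, focal), grp in df.groupby(
        ["species", "scaffold", "focal_gene"], sort=True
    ):
        grp = grp.sort_values("position", kind="mergesort")
        nb = ScaffoldNeighborhood(
            species=species,
            scaffold_id=scaffold,
            focal_gene_id=focal,
            neighbors=tuple(zip(grp["orthogroup"], grp["strand"])),
        )
        out.setdefault(species, []).append(nb)
    return out


def write_neighborhoods(
    neighborhoods: Mapping[str, Sequence[ScaffoldNeighborhood]], path: str | Path
) -> None:
    rows = []
    for species in sorted(neighborhoods):
        for nb in neighborhoods[species]:
            for pos, (og, strand) in enumerate(nb.neighbors):
                rows.append(
                    {
                        "species": species,
                        "scaffold": nb.scaffold_id,
                        "focal_gene": nb.focal_gene_id,
                        "position": pos,
                        "orthogroup": og,
                        "strand": strand,
                    }
                )
    pd.DataFrame(rows, columns=list(NEIGHBORHOOD_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )
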