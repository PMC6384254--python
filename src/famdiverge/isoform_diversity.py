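"""Isoform counting and per-order / per-species census tables.

Two isoform notions are counted.  *Sensu stricto*: distinct complete
protein sequences among a gene's (or species') transcript products.
*Sensu lato*: distinct concatenations of the conserved functional-domain
substrings only — two proteins differing exclusively outside the domains
are the same isoform sensu lato.  For trehalases the domain set is the
seven anchor domains; for acid trehalases, the six ATH consensus motifs.

The order-level summary mirrors the family census table: counts of
species, genes and transcripts, the derived ratios (kept as exact integer
quotients until formatting, printed with '.' decimal separator and nine
decimals), mean physicochemistry over isoforms sensu stricto, and the
soluble / transmembrane percentages.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import pandas as pd

from famdiverge.anchors_and_trim import TREH_ANCHOR_SPECS
from famdiverge.errors import ValidationError
from famdiverge.io_formats import GeneRecord
from famdiverge.motif_scan import (
    ATH_MOTIF_SPECS,
    MotifPattern,
    best_match,
    compile_pattern,
)

MISSING_DOMAIN_TOKEN = "<missing>"


def domain_signature(
    protein: str,
    patterns: Sequence[MotifPattern],
    max_mismatch: int = 1,
) -> tuple[str, ...]:
    """Concatenable domain substrings of a protein (placeholder if absent)."""
    sig = []
    for pattern in patterns:
        hit = best_match(protein, pattern, max_mismatch)
        if hit is None:
            sig.append(MISSING_DOMAIN_TOKEN)
        else:
            s, e = hit.interval
            sig.append(protein[s:e])
    return tuple(sig)


def compiled_domain_panel(family: str = "treh") -> tuple[MotifPattern, ...]:
    specs = TREH_ANCHOR_SPECS if family == "treh" else ATH_MOTIF_SPECS
    return tuple(compile_pattern(spec, name) for name, spec in specs)


def count_isoforms(
    proteins: Sequence[str],
    mode: str = "sensu_stricto",
    patterns: Sequence[MotifPattern] | None = None,
    max_mismatch: int = 1,
) -> int:
    """Number of distinct isoforms among the given protein sequences."""
    if mode == "sensu_stricto":
        return len(set(proteins))
    if mode == "sensu_lato":
        if patterns is None:
            patterns = compiled_domain_panel("treh")
        return len({domain_signature(p, patterns, max_mismatch) for p in proteins})
    raise ValidationError(f"unknown isoform mode {mode!r}")


@dataclass(frozen=True)
class OrderSummary:
    """One census row for an insect order.

    Ratios are exact rationals of the integer counts; physicochemistry
    fields are None when no protein features were supplied.
    """

    order_name: str
    n_species: int
    n_genes: int
    n_transcripts: int
    t_per_g: Fraction | None
    genes_per_species: Fraction | None
    isoforms_s: int | None
    isoforms_l: int | None
    isoforms_s_per_species: Fraction | None
    isoforms_l_per_species: Fraction | None
    mean_pI: float | None
    mean_mw: float | None
    mean_len: float | None
    pct_soluble: float | None
    pct_tm: float | None


def format_ratio(value: Fraction | None, decimals: int = 9) -> str:
    """Format an exact ratio with '.' decimal separator and fixed decimals."""
    if value is None:
        return ""
    return f"{float(value):.{decimals}f}"


def _species_counts(genes: Sequence[GeneRecord]) -> pd.DataFrame:
    rows = [
        {
            "species": g.species,
            "order": g.order_name,
            "n_genes": 1,
            "n_transcripts": len(g.transcript_ids),
        }
        for g in genes
    ]
    df = pd.DataFrame(rows)
    return (
        df.groupby(["order", "species"], as_index=False)[["n_genes", "n_transcripts"]]
        .sum()
        .sort_values(["order", "species"], kind="mergesort")
        .reset_index(drop=True)
    )


def summarize_species(
    genes: Sequence[GeneRecord],
    isoforms: Mapping[str, tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Per-species rows: genes, transcripts, isoforms S and L.

    ``isoforms`` maps species name to (sensu stricto, sensu lato) counts;
    species without protein data get missing isoform cells.
    """
    if not genes:
        return pd.DataFrame(
            columns=["species", "order", "n_genes", "n_transcripts",
                     "isoforms_s", "isoforms_l"]
        )
    df = _species_counts(genes)
    iso = isoforms or {}
    df["isoforms_s"] = [
        iso.get(sp, (None, None))[0] for sp in df["species"]
    ]
    df["isoforms_l"] = [
        iso.get(sp, (None, None))[1] for sp in df["species"]
    ]
    return df[["species", "order", "n_genes", "n_transcripts", "isoforms_s", "isoforms_l"]]


def summarize_order(
    genes: Sequence[GeneRecord],
    order_name: str,
    features: pd.DataFrame | None = None,
    isoforms: Mapping[str, tuple[int, int]] | None = None,
) -> OrderSummary:
    """Census row for one order (see :class:`OrderSummary`).

    ``features`` is a per-isoform (sensu stricto) table with columns
    ``order``, ``pI``, ``mw``, ``length`` and ``classification``; means are
    unweighted over its rows for this order.  Ratios are exact quotients;
    an order with zero genes reports them missing, not zero.
    """
    selected = [g for g in genes if g.order_name == order_name]
    species = sorted({g.species for g in selected})
    n_species = len(species)
    n_genes = len(selected)
    n_transcripts = sum(len(g.transcript_ids) for g in selected)

    iso = isoforms or {}
    have_iso = all(sp in iso for sp in species) and species
    iso_s = sum(iso[sp][0] for sp in species) if have_iso else None
    iso_l = sum(iso[sp][1] for sp in species) if have_iso else None

    mean_pI = mean_mw = mean_len = pct_sol = pct_tm = None
    if features is not None and len(features):
        sub = features[features["order"] == order_name]
        if len(sub):
            mean_pI = float(sub["pI"].mean())
            mean_mw = float(sub["mw"].mean())
            mean_len = float(sub["length"].mean())
            pct_sol = 100.0 * float((sub["classification"] == "soluble").mean())
            pct_tm = 100.0 * float((sub["n_tm"] >= 1).mean()) if "n_tm" in sub else (
                100.0 - pct_sol
            )

    def ratio(num: int | None, den: int) -> Fraction | None:
        if num is None or den == 0:
            return None
        return Fraction(num, den)

    return OrderSummary(
        order_name=order_name,
        n_species=n_species,
        n_genes=n_genes,
        n_transcripts=n_transcripts,
        t_per_g=ratio(n_transcripts, n_genes),
        genes_per_species=ratio(n_genes, n_species),
        isoforms_s=iso_s,
        isoforms_l=iso_l,
        isoforms_s_per_species=ratio(iso_s, n_species),
        isoforms_l_per_species=ratio(iso_l, n_species),
        mean_pI=mean_pI,
        mean_mw=mean_mw,
        mean_len=mean_len,
        pct_soluble=pct_sol,
        pct_tm=pct_tm,
    )


def order_summary_table(
    genes: Sequence[GeneRecord],
    features: pd.DataFrame | None = None,
    isoforms: Mapping[str, tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Census table, one row per order present in the catalog."""
    orders = sorted({g.order_name for g in genes})
    rows = []
    for order in orders:
        s = summarize_order(genes, order, features, isoforms)
        rows.append(
            {
                "order": s.order_name,
                "n_species": s.n_species,
                "n_genes": s.n_genes,
                "n_transcripts": s.n_transcripts,
                "t_per_g": format_ratio(s.t_per_g),
                "genes_per_species": format_ratio(s.genes_per_species),
                "isoforms_s": s.isoforms_s,
                "isoforms_l": s.isoforms_l,
                "isoforms_s_per_species": format_ratio(s.isoforms_s_per_species),
                "isoforms_l_per_species": format_ratio(s.isoforms_l_per_species),
                "mean_pI": "" if s.mean_pI is None else f"{s.mean_pI:.3f}",
                "mean_mw": "" if s.mean_mw is None else f"{s.mean_mw:.2f}",
                "mean_len": "" if s.mean_len is None else f"{s.mean_len:.2f}",
                "pct_soluble": "" if s.pct_soluble is None else f"{s.pct_soluble:.8f}",
                "pct_tm": "" if s.pct_tm is None else f"{s.pct_tm:.8f}",
            }
        )
    return pd.DataFrame(rows)
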