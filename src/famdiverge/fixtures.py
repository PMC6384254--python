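"""Packaged census fixture for the five-order trehalase gene count table.

The per-order totals (species, genes, transcripts) are the published
order-level census of the family:

    Hemiptera    7 species  54 genes  93 transcripts
    Lepidoptera  3 species   9 genes  11 transcripts
    Hymenoptera 15 species  32 genes  93 transcripts
    Coleoptera   4 species  29 genes  51 transcripts
    Diptera     11 species  36 genes  49 transcripts

(160 genes and 40 species in total.)  The per-species rows underneath are a
SYNTHETIC allocation: the published per-species list does not sum to the
order-level totals for every order, so per-species gene and transcript
counts are scaled to the order totals by the largest-remainder method using
the per-species list as weights (each species keeps at least one gene, and
transcripts are repaired to be at least the gene count).  For Coleoptera
the per-species list sums exactly, so those rows — including the 11 genes
of *Aethina tumida* — are preserved verbatim.  Only the order-level totals
(and the Coleoptera rows) should be treated as real census data.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from famdiverge.io_formats import GeneRecord

# order -> (total_genes, total_transcripts,
#           [(species, gene_weight, transcript_weight), ...])
_ORDER_DATA: dict[str, tuple[int, int, list[tuple[str, int, int]]]] = {
    "Diptera": (36, 49, [
        ("Aedes albopictus", 2, 15),
        ("Culex quinquefasciatus", 2, 2),
        ("Drosophila melanogaster", 1, 7),
        ("Drosophila miranda", 2, 3),
        ("Drosophila pseudoobscura", 2, 3),
        ("Drosophila virilis", 2, 3),
        ("Bactrocera oleae", 3, 6),
        ("Bactrocera dorsalis", 2, 2),
        ("Bactrocera cucurbitae", 2, 3),
        ("Ceratitis capitata", 2, 6),
        ("Musca domestica", 2, 4),
    ]),
    "Coleoptera": (29, 51, [
        ("Tribolium castaneum", 6, 12),
        ("Dendroctonus ponderosae", 5, 13),
        ("Aethina tumida", 11, 12),
        ("Anoplophora glabripennis", 7, 14),
    ]),
    "Hymenoptera": (32, 93, [
        ("Apis mellifera", 2, 10),
        ("Apis dorsata", 2, 2),
        ("Apis florea", 3, 6),
        ("Bombus terrestris", 2, 10),
        ("Bombus impatiens", 2, 9),
        ("Nasonia vitripennis", 2, 4),
        ("Ceratosolen solmsi", 2, 2),
        ("Fopius arisanus", 3, 7),
        ("Microplitis demolitor", 2, 8),
        ("Megachile rotundata", 2, 9),
        ("Solenopsis invicta", 2, 8),
        ("Acromyrmex echinatior", 2, 3),
        ("Camponotus floridanus", 2, 4),
        ("Cerapachys biroi", 2, 9),
        ("Harpegnathos saltator", 2, 3),
    ]),
    "Lepidoptera": (9, 11, [
        ("Bombyx mori", 3, 3),
        ("Plutella xylostella", 6, 8),
        ("Papilio machaon", 4, 4),
    ]),
    "Hemiptera": (54, 93, [
        ("Cimex lectularius", 3, 5),
        ("Halyomorpha halys", 8, 17),
        ("Diaphorina citri", 6, 13),
        ("Bemisia tabaci", 9, 17),
        ("Diuraphis noxia", 9, 12),
        ("Acyrthosiphon pisum", 14, 23),
        ("Myzus persicae", 9, 9),
    ]),
}


def largest_remainder(
    weights: list[tuple[str, int]], total: int, minimum: int = 0
) -> dict[str, int]:
    """Apportion ``total`` integer units proportionally to the weights.

    Floors the exact quotas (respecting ``minimum``) and distributes the
    remainder by largest fractional part, ties broken by name.
    """
    wsum = sum(w for _, w in weights)
    quotas = {name: w * total / wsum for name, w in weights}
    alloc = {name: max(minimum, int(quotas[name])) for name, _ in weights}
    remaining = total - sum(alloc.values())
    if remaining < 0:
        # over-allocation can only come from the minimum; shave the largest
        for name in sorted(alloc, key=lambda n: (-alloc[n], n)):
            while remaining < 0 and alloc[name] > minimum:
                alloc[name] -= 1
                remaining += 1
        return alloc
    order = sorted(
        (name for name, _ in weights),
        key=lambda n: (-(quotas[n] - int(quotas[n])), n),
    )
    for i in range(remaining):
        alloc[order[i % len(order)]] += 1
    return alloc


def _species_code(species: str) -> str:
    genus, rest = species.split(" ", 1)
    return (genus[0] + rest[:3]).capitalize()


def build_table2_catalog() -> list[GeneRecord]:
    """Build the census-fixture gene catalog (see module docstring)."""
    records: list[GeneRecord] = []
    for order in sorted(_ORDER_DATA):
        total_genes, total_tx, species_rows = _ORDER_DATA[order]
        gene_alloc = largest_remainder(
            [(s, g) for s, g, _ in species_rows], total_genes, minimum=1
        )
        tx_alloc = largest_remainder(
            [(s, t) for s, _, t in species_rows], total_tx, minimum=0
        )
        # repair: every gene carries at least one transcript
        deficits = sorted(s for s, *_ in species_rows)
        changed = True
        while changed:
            changed = False
            for sp in deficits:
                while tx_alloc[sp] < gene_alloc[sp]:
                    donor = max(
                        sorted(tx_alloc),
                        key=lambda s: (tx_alloc[s] - gene_alloc[s], s),
                    )
                    if tx_alloc[donor] - gene_alloc[donor] <= 0:
                        raise RuntimeError("infeasible transcript allocation")
                    tx_alloc[donor] -= 1
                    tx_alloc[sp] += 1
                    changed = True
        for species, *_ in species_rows:
            code = _species_code(species)
            n_genes = gene_alloc[species]
            n_tx = tx_alloc[species]
            per_gene = [1] * n_genes
            for i in range(n_tx - n_genes):
                per_gene[i % n_genes] += 1
            offset = 1000
            for gi in range(n_genes):
                gene_id = f"{code}_treh{gi + 1:02d}"
                tx_ids = tuple(
                    f"{gene_id}.t{ti + 1}" for ti in range(per_gene[gi])
                )
                records.append(
                    GeneRecord(
                        gene_id=gene_id,
                        species=species,
                        order_name=order,
                        family="treh",
                        scaffold_id=f"{code}_scaffold{gi + 1}",
                        start=offset,
                        end=offset + 4999,
                        strand="+" if gi % 2 == 0 else "-",
                        transcript_ids=tx_ids,
                    )
                )
                offset += 10000
    records.sort(key=lambda g: (g.species, g.gene_id))
    return records


def table2_counts_path() -> Path:
    """Path of the packaged census-fixture TSV."""
    return Path(resources.files("famdiverge") / "data" / "table2_counts.tsv")
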