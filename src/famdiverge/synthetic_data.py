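"""Ground-truth-labeled synthetic gene-family datasets.

The generator emulates the statistical structure the analysis assumes:

* genes arise by a birth-death process along a five-order species tree,
  with order-specific duplication rates (gene families expand differently
  per insect order);
* every trehalase protein is a scaffold of the seven conserved anchor
  domains embedded in divergent background sequence, evolving by per-site
  substitution at per-domain rates inside the anchors and a higher
  background rate outside (substitutions uniform over the 19 alternative
  residues);
* transcript variants differ at the N/C termini only, never inside the
  anchor domains;
* signal peptides and transmembrane segments are planted as hydrophobic
  runs in dedicated N-/C-terminal zones at configured probabilities; the
  non-plant background is drawn from hydrophilic residues so that, at zero
  topology noise, the hydropathy classifier's calls are exactly the
  planted labels;
* acid-trehalase (ath) genes are intronless, single-isoform, and carry all
  six ATH consensus motifs planted at recorded offsets;
* scaffold neighborhoods share an order-level block of orthogroups, with
  logged per-species rearrangements (inversion, insertion, translocation).

Sequences never gain indels, so the per-gene representative proteins are
emitted as a ready (gapless) alignment whose coordinates equal the planted
domain coordinates.  All randomness flows through one seeded numpy
Generator; the same seed reproduces every output byte for byte.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

from famdiverge.anchors_and_trim import TREH_ANCHOR_SPECS
from famdiverge.errors import ValidationError
from famdiverge.io_formats import (
    GeneRecord,
    SequenceRecord,
    write_fasta,
    write_gene_table,
)
from famdiverge.synteny_colinearity import (
    ScaffoldNeighborhood,
    write_neighborhoods,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Kyte-Doolittle-hydrophilic residues used for background sequence.
HYDROPHILIC = "DEGHKNPQRSTWY"
HYDROPHOBIC = "LIVF"
NUCLEOTIDES = "ACGT"

#: One codon per amino acid (standard code), for reverse translation.
CODON_OF = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}

#: Concrete anchor-domain instances planted in the ancestral protein.
ANCHOR_INSTANCES = tuple((name, spec) for name, spec in TREH_ANCHOR_SPECS)

#: Concrete ATH motif instances (degenerate positions fixed to a residue).
ATH_INSTANCES = (
    ("tm_span", "LFFFFFFFLCFSFTTSML"),
    ("camp_site", "RRAS"),
    ("ef_like", "DTAGDAQITIAD"),
    ("signature_1", "PGGRFAEAYAWDAY"),
    ("signature_2", "QWDAPAGWPP"),
    ("gpi_anchor", "CRTNYGYSAA"),
)

SIGNAL_ZONE_LEN = 21
TM_ZONE_LEN = 25
PAD = 12
MAX_TRIM = 8


@dataclass
class SimulationConfig:
    """All knobs of the generator; a fixed seed reproduces every byte."""

    seed: int = 7
    #: (order name, number of species, expected genes per species)
    orders: tuple = (
        ("Coleoptera", 3, 4.0),
        ("Diptera", 3, 4.0),
        ("Hemiptera", 3, 4.0),
        ("Hymenoptera", 3, 4.0),
        ("Lepidoptera", 3, 4.0),
    )
    species_tree: str | None = None  # newick override; built from orders if None
    loss_rate: float = 0.0
    #: per-site substitution rate per unit branch length, per anchor domain
    domain_rates: tuple = (0.01, 0.02, 0.03, 0.04, 0.05, 0.06, 0.08)
    background_rate: float = 0.30
    tx_min: int = 1
    tx_max: int = 4
    tx_probs: tuple = (0.45, 0.30, 0.15, 0.10)
    p_signal: float = 0.4
    p_tm: float = 0.35
    topology_noise: float = 0.0
    neighborhood_k: int = 5
    shared_block_size: int = 5
    p_inversion: float = 0.3
    p_insertion: float = 0.3
    p_translocation: float = 0.2
    ath_per_species: int = 1

    def validate(self) -> None:
        if self.loss_rate < 0 or self.background_rate < 0:
            raise ValidationError("rates must be non-negative")
        if any(r < 0 for r in self.domain_rates) or len(self.domain_rates) != 7:
            raise ValidationError("need 7 non-negative domain rates")
        if abs(sum(self.tx_probs) - 1.0) > 1e-9:
            raise ValidationError("transcript-count probabilities must sum to 1")
        if len(self.tx_probs) != self.tx_max - self.tx_min + 1:
            raise ValidationError("tx_probs length must match tx_min..tx_max")
        for p in (self.p_signal, self.p_tm, self.topology_noise,
                  self.p_inversion, self.p_insertion, self.p_translocation):
            if not (0 <= p <= 1):
                raise ValidationError("probabilities must lie in [0,1]")
        if self.neighborhood_k < 0 or self.shared_block_size < 0:
            raise ValidationError("neighborhood sizes must be non-negative")
        if self.shared_block_size > 2 * self.neighborhood_k:
            raise ValidationError("shared block cannot exceed the 2k window")


def default_config(seed: int = 7) -> SimulationConfig:
    """Moderate 15-species preset used throughout the test-bench runs."""
    return SimulationConfig(seed=seed)


def insect_like_config(seed: int = 7) -> SimulationConfig:
    """Demo preset: five orders with the species counts of the published
    census and duplication rates tuned so order-level gene totals match its
    magnitudes (54/9/32/29/36) in expectation."""
    return SimulationConfig(
        seed=seed,
        orders=(
            ("Coleoptera", 4, 29 / 4),
            ("Diptera", 11, 36 / 11),
            ("Hemiptera", 7, 54 / 7),
            ("Hymenoptera", 15, 32 / 15),
            ("Lepidoptera", 3, 9 / 3),
        ),
    )


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------

def build_species_tree(orders: Sequence[tuple]) -> str:
    """Ultrametric newick: order crowns of depth 0.5 on 0.5-length stems.

    Species are named ``<Order>_sp<i>``; every root-to-tip path has length
    1.0 and every within-order path from the order ancestor has length 0.5.
    """

    def ladder(tips: list[str], heights: list[float]) -> str:
        if len(tips) == 2:
            return f"({tips[0]}:{heights[0]:.6f},{tips[1]}:{heights[0]:.6f})"
        inner = ladder(tips[1:], heights[1:])
        edge = heights[0] - heights[1]
        return f"({tips[0]}:{heights[0]:.6f},{inner}:{edge:.6f})"

    crowns = []
    for order, n_species, _ in orders:
        tips = [f"{order}_sp{i + 1}" for i in range(n_species)]
        if len(tips) == 1:
            crowns.append(f"{tips[0]}:1.0")
        else:
            n = len(tips)
            heights = [0.5 * (n - 1 - j) / (n - 1) for j in range(n - 1)]
            heights[0] = 0.5
            crowns.append(f"{ladder(tips, heights)}:0.5")
    return "(" + ",".join(crowns) + ");"


# ---------------------------------------------------------------------------
# sequence layout and evolution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinLayout:
    """Fixed coordinates of the ancestral-protein architecture."""

    length: int
    signal_zone: tuple[int, int]
    tm_zone: tuple[int, int]
    domain_intervals: tuple[tuple[str, int, int], ...]


def _make_layout() -> ProteinLayout:
    pos = 1  # position 0 is the immutable initiator Met
    signal_zone = (pos, pos + SIGNAL_ZONE_LEN)
    pos = signal_zone[1] + PAD
    domains = []
    for name, instance in ANCHOR_INSTANCES:
        domains.append((name, pos, pos + len(instance)))
        pos += len(instance) + PAD
    tm_zone = (pos, pos + TM_ZONE_LEN)
    pos = tm_zone[1] + PAD
    return ProteinLayout(pos, signal_zone, tm_zone, tuple(domains))


LAYOUT = _make_layout()


def _background(rng: np.random.Generator, n: int, noise: float) -> str:
    residues = rng.choice(list(HYDROPHILIC), size=n)
    if noise > 0:
        mask = rng.random(n) < noise
        residues[mask] = rng.choice(list(AMINO_ACIDS), size=int(mask.sum()))
    return "".join(residues)


def ancestral_protein(rng: np.random.Generator, noise: float = 0.0) -> str:
    """The root trehalase: M + hydrophilic background + the 7 anchors."""
    chars = list("M" + _background(rng, LAYOUT.length - 1, noise))
    for (name, s, e), (_, instance) in zip(LAYOUT.domain_intervals, ANCHOR_INSTANCES):
        chars[s:e] = instance
    return "".join(chars)


def evolve_sequence(
    parent: str,
    domain_intervals: Sequence[tuple[str, int, int]],
    domain_probs: dict,
    background_prob: float,
    rng: np.random.Generator,
    log: dict | None = None,
) -> str:
    """Per-site substitution: domain probability inside each interval,
    background probability elsewhere; substitutions uniform over the 19
    alternative residues.  Position 0 (initiator Met) never mutates.

    ``log`` (optional) accumulates, per domain name and for "background",
    the number of sites drawn, realized substitutions, and the first two
    moments of the per-site probabilities — the material for binomial
    recovery checks.
    """
    n = len(parent)
    probs = np.full(n, background_prob)
    probs[0] = 0.0
    region = np.zeros(n, dtype=int)  # 0 = background, i+1 = domain i
    for i, (_, s, e) in enumerate(domain_intervals):
        probs[s:e] = domain_probs[domain_intervals[i][0]]
        region[s:e] = i + 1
    hits = rng.random(n) < probs
    chars = list(parent)
    for idx in np.nonzero(hits)[0]:
        current = chars[idx]
        alternatives = [a for a in AMINO_ACIDS if a != current]
        chars[idx] = alternatives[rng.integers(0, len(alternatives))]
    if log is not None:
        names = ["background"] + [name for name, _, _ in domain_intervals]
        for code, name in enumerate(names):
            sel = region == code
            if name == "background":
                sel[0] = False
            entry = log.setdefault(
                name, {"sites": 0, "subs": 0, "sum_p": 0.0, "sum_pq": 0.0}
            )
            p = probs[sel]
            entry["sites"] += int(sel.sum())
            entry["subs"] += int(hits[sel].sum())
            entry["sum_p"] += float(p.sum())
            entry["sum_pq"] += float((p * (1 - p)).sum())
    return "".join(chars)


# ---------------------------------------------------------------------------
# birth-death gene evolution along the species tree
# ---------------------------------------------------------------------------

def _evolve_edge(
    proteins: list[str],
    t: float,
    dup_rate: float,
    loss_rate: float,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    log: dict,
) -> list[str]:
    """Evolve a set of gene lineages along one species-tree edge."""
    domain_probs_of = lambda dt: {
        name: -math.expm1(-rate * dt)
        for (name, _, _), rate in zip(LAYOUT.domain_intervals, cfg.domain_rates)
    }

    def bg_prob(dt: float) -> float:
        return -math.expm1(-cfg.background_rate * dt)

    def run(protein: str, remaining: float) -> list[str]:
        total = dup_rate + loss_rate
        wait = rng.exponential(1.0 / total) if total > 0 else math.inf
        if wait >= remaining:
            return [
                evolve_sequence(
                    protein, LAYOUT.domain_intervals, domain_probs_of(remaining),
                    bg_prob(remaining), rng, log,
                )
            ]
        evolved = evolve_sequence(
            protein, LAYOUT.domain_intervals, domain_probs_of(wait),
            bg_prob(wait), rng, log,
        )
        if rng.random() < dup_rate / total:
            left = run(evolved, remaining - wait)
            right = run(evolved, remaining - wait)
            return left + right
        return []  # loss

    out: list[str] = []
    for protein in proteins:
        out.extend(run(protein, t))
    return out


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    """In-memory result of a simulation plus its ground truth."""

    config: SimulationConfig
    gene_records: list[GeneRecord]
    scaffolds: list[SequenceRecord]
    protein_records: list[SequenceRecord]        # all transcript variants
    alignment_records: list[SequenceRecord]      # gene representatives + outgroup
    neighborhoods: dict[str, list[ScaffoldNeighborhood]]
    gff3_text: str
    ground_truth: dict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "gene_table": outdir / "gene_table.tsv",
            "scaffolds": outdir / "scaffolds.fasta",
            "proteins": outdir / "proteins.fasta",
            "alignment": outdir / "aligned_representatives.fasta",
            "gff3": outdir / "genes.gff3",
            "neighborhoods": outdir / "neighborhoods.tsv",
            "ground_truth": outdir / "ground_truth.json",
        }
        write_gene_table(self.gene_records, paths["gene_table"])
        write_fasta(self.scaffolds, paths["scaffolds"])
        write_fasta(self.protein_records, paths["proteins"])
        write_fasta(self.alignment_records, paths["alignment"])
        paths["gff3"].write_text(self.gff3_text)
        write_neighborhoods(self.neighborhoods, paths["neighborhoods"])
        truth = dict(self.ground_truth)
        truth["config"] = asdict(self.config)
        paths["ground_truth"].write_text(
            json.dumps(truth, indent=1, sort_keys=True)
        )
        return paths


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    # one fixed codon per residue keeps variant CDSs consistent with the
    # representative; rng picks only the stop codon
    stop = ("TAA", "TAG", "TGA")[rng.integers(0, 3)]
    return "".join(CODON_OF[ch] for ch in protein) + stop


def plant_neighborhoods(
    cfg: SimulationConfig,
    genes_by_species: dict[str, list[str]],
    order_of_species: dict[str, str],
    scaffold_of_gene: dict[str, str],
    rng: np.random.Generator,
) -> tuple[dict, list[dict]]:
    """Per-focal-gene neighborhoods with an order-level conserved block.

    Every species of an order shares the same ordered, stranded block of
    ``shared_block_size`` orthogroups around its focal genes; remaining
    window slots carry species-unique filler labels.  Per neighborhood,
    one inversion / insertion / translocation may be applied (configured
    probabilities) and is logged.
    """
    s = cfg.shared_block_size
    k = cfg.neighborhood_k
    block_of_order: dict[str, list[tuple[str, str]]] = {}
    ops_log: list[dict] = []
    neighborhoods: dict[str, list[ScaffoldNeighborhood]] = {}
    fill_counter = 0
    for species in sorted(genes_by_species):
        order = order_of_species[species]
        if order not in block_of_order:
            strands = ["+" if rng.random() < 0.5 else "-" for _ in range(s)]
            block_of_order[order] = [
                (f"{order}_og{j + 1}", strands[j]) for j in range(s)
            ]
        block = block_of_order[order]
        neighborhoods[species] = []
        for gene_id in genes_by_species[species]:
            left_fill = k - s // 2
            right_fill = k - (s - s // 2)
            neighbors: list[tuple[str, str]] = []
            for _ in range(left_fill):
                fill_counter += 1
                neighbors.append((f"{species}_fill{fill_counter}", "+"))
            neighbors.extend(block[: s // 2])
            split = len(neighbors)
            neighbors.extend(block[s // 2 :])
            for _ in range(right_fill):
                fill_counter += 1
                neighbors.append((f"{species}_fill{fill_counter}", "+"))
            # rearrangements
            if s >= 2 and rng.random() < cfg.p_inversion:
                a = int(rng.integers(0, len(neighbors) - 1))
                b = int(rng.integers(a + 2, min(len(neighbors), a + 5) + 1))
                seg = [("-" if st == "+" else "+", lbl)
                       for lbl, st in reversed(neighbors[a:b])]
                neighbors[a:b] = [(lbl, st) for st, lbl in seg]
                ops_log.append(
                    {"species": species, "gene": gene_id,
                     "op": "inversion", "span": [a, b]}
                )
            if rng.random() < cfg.p_insertion:
                fill_counter += 1
                pos = int(rng.integers(0, len(neighbors) + 1))
                neighbors.insert(pos, (f"{species}_fill{fill_counter}", "+"))
                dropped = neighbors.pop()  # keep the <= 2k window
                ops_log.append(
                    {"species": species, "gene": gene_id, "op": "insertion",
                     "position": pos, "dropped": dropped[0]}
                )
            if rng.random() < cfg.p_translocation:
                src = int(rng.integers(0, len(neighbors)))
                dst = int(rng.integers(0, len(neighbors)))
                item = neighbors.pop(src)
                neighbors.insert(dst, item)
                ops_log.append(
                    {"species": species, "gene": gene_id, "op": "translocation",
                     "from": src, "to": dst, "label": item[0]}
                )
            neighborhoods[species].append(
                ScaffoldNeighborhood(
                    species=species,
                    scaffold_id=scaffold_of_gene[gene_id],
                    focal_gene_id=gene_id,
                    neighbors=tuple(neighbors),
                )
            )
    return neighborhoods, ops_log


def simulate_dataset(cfg: SimulationConfig) -> Dataset:
    """Run the full generator (see module docstring) under one seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    newick = cfg.species_tree or build_species_tree(cfg.orders)
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)

    order_of_species = {}
    dup_rate_of_order = {}
    for order, n_species, genes_per_species in cfg.orders:
        for i in range(n_species):
            order_of_species[f"{order}_sp{i + 1}"] = order
        # within-order root-to-tip path is 0.5; tune the net rate so the
        # expected tip gene count is the configured genes-per-species
        net = 2.0 * math.log(max(genes_per_species, 1e-9))
        dup_rate_of_order[order] = max(net + cfg.loss_rate, 0.0)

    def order_of_node(node) -> str | None:
        leaves = {lf.taxon.label for lf in node.leaf_iter()}
        orders = {order_of_species.get(l, "?") for l in leaves}
        return orders.pop() if len(orders) == 1 else None

    sub_log: dict = {}
    root_protein = ancestral_protein(rng, cfg.topology_noise)
    genes_of_species: dict[str, list[str]] = {}

    # deterministic preorder traversal carrying the set of gene lineages
    def descend(node, proteins: list[str]) -> None:
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            order = order_of_node(child)
            dup = dup_rate_of_order.get(order, 0.0) if order else 0.0
            evolved = _evolve_edge(
                proteins, t, dup, cfg.loss_rate if order else 0.0, cfg, rng, sub_log
            )
            if child.is_leaf():
                genes_of_species[child.taxon.label] = evolved
            else:
                descend(child, evolved)

    descend(tree.seed_node, [root_protein])

    # --- per-species assembly -------------------------------------------
    gene_records: list[GeneRecord] = []
    scaffolds: list[SequenceRecord] = []
    protein_records: list[SequenceRecord] = []
    alignment_records: list[SequenceRecord] = []
    gff_lines = ["##gff-version 3"]
    truth_topology: dict = {}
    truth_domains: dict = {}
    truth_ath: dict = {}
    iso_truth: dict = {}
    gene_counts: dict = {}
    tx_counts: dict = {}
    genes_by_species_ids: dict[str, list[str]] = {}
    scaffold_of_gene: dict[str, str] = {}

    tx_values = list(range(cfg.tx_min, cfg.tx_max + 1))

    for species in sorted(genes_of_species):
        order = order_of_species[species]
        proteins = genes_of_species[species]
        gene_counts[species] = {"treh": len(proteins), "ath": cfg.ath_per_species}
        tx_counts[species] = 0
        genes_by_species_ids[species] = []
        species_variants: list[str] = []
        species_signatures: set = set()
        for gi, core in enumerate(proteins):
            gene_id = f"{species}_treh{gi + 1:02d}"
            genes_by_species_ids[species].append(gene_id)
            scaffold_id = f"{species}_scaf{gi + 1}"
            scaffold_of_gene[gene_id] = scaffold_id

            chars = list(core)
            has_signal = rng.random() < cfg.p_signal
            has_tm = rng.random() < cfg.p_tm
            if has_signal:
                s0, e0 = LAYOUT.signal_zone
                chars[s0:e0] = rng.choice(list(HYDROPHOBIC), size=e0 - s0)
            if has_tm:
                s0, e0 = LAYOUT.tm_zone
                chars[s0:e0] = rng.choice(list(HYDROPHOBIC), size=e0 - s0)
            gene_protein = "".join(chars)

            truth_domains[f"{gene_id}.t1"] = {
                name: [s, e] for name, s, e in LAYOUT.domain_intervals
            }
            species_signatures.add(
                tuple(gene_protein[s:e] for _, s, e in LAYOUT.domain_intervals)
            )

            n_tx = int(rng.choice(tx_values, p=list(cfg.tx_probs)))
            trims = [(0, 0)]
            while len(trims) < n_tx:
                dn = 0 if has_signal else int(rng.integers(0, MAX_TRIM + 1))
                dc = int(rng.integers(0, MAX_TRIM + 1))
                if (dn, dc) not in trims:
                    trims.append((dn, dc))
            tx_counts[species] += n_tx

            variant_proteins = []
            for ti, (dn, dc) in enumerate(trims):
                tx_id = f"{gene_id}.t{ti + 1}"
                vp = "M" + gene_protein[1 + dn : len(gene_protein) - dc]
                variant_proteins.append((tx_id, vp))
                species_variants.append(vp)
                protein_records.append(SequenceRecord(tx_id, vp, "protein"))
                truth_topology[tx_id] = {
                    "signal": bool(has_signal),
                    "tm": bool(has_tm),
                    "class": "membrane_bound" if has_tm else "soluble",
                }
            alignment_records.append(
                SequenceRecord(f"{gene_id}.t1", gene_protein, "aligned-protein")
            )

            # --- genomic layout: each variant spliced from its own segment
            region_parts: list[str] = []
            exon_map: list[tuple[str, list[tuple[int, int]]]] = []
            cursor = 0
            for tx_id, vp in variant_proteins:
                cds = _reverse_translate(vp, rng)
                n_exons = int(rng.integers(2, 4))
                cuts = sorted(
                    int(rng.integers(3, len(cds) - 3)) for _ in range(n_exons - 1)
                )
                cuts = [0] + cuts + [len(cds)]
                exons_sense: list[tuple[int, int]] = []
                for a, b in zip(cuts[:-1], cuts[1:]):
                    if b <= a:
                        continue
                    exons_sense.append((cursor, cursor + (b - a)))
                    region_parts.append(cds[a:b])
                    cursor += b - a
                    intron = "".join(
                        rng.choice(list(NUCLEOTIDES), size=int(rng.integers(40, 121)))
                    )
                    region_parts.append(intron)
                    cursor += len(intron)
                exon_map.append((tx_id, exons_sense))
            region = "".join(region_parts)
            strand = "+" if rng.random() < 0.5 else "-"
            pad5 = "".join(rng.choice(list(NUCLEOTIDES), size=100))
            pad3 = "".join(rng.choice(list(NUCLEOTIDES), size=100))
            if strand == "+":
                scaffold_seq = pad5 + region + pad3
            else:
                comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
                rc = "".join(comp[c] for c in reversed(region))
                scaffold_seq = pad5 + rc + pad3
            g_off = len(pad5)
            scaffolds.append(
                SequenceRecord(scaffold_id, scaffold_seq, "nucleotide")
            )

            def on_scaffold(s_sense: int, e_sense: int) -> tuple[int, int]:
                if strand == "+":
                    return g_off + s_sense + 1, g_off + e_sense
                return g_off + len(region) - e_sense + 1, g_off + len(region) - s_sense

            gene_start, gene_end = g_off + 1, g_off + len(region)
            gff_lines.append(
                f"{scaffold_id}\tfamdiverge\tgene\t{gene_start}\t{gene_end}\t.\t"
                f"{strand}\t.\tID={gene_id};species={species};order={order};family=treh"
            )
            tx_ids = []
            for tx_id, exons_sense in exon_map:
                coords = sorted(on_scaffold(s, e) for s, e in exons_sense)
                gff_lines.append(
                    f"{scaffold_id}\tfamdiverge\tmRNA\t{coords[0][0]}\t"
                    f"{coords[-1][1]}\t.\t{strand}\t.\tID={tx_id};Parent={gene_id}"
                )
                for ei, (a, b) in enumerate(coords):
                    gff_lines.append(
                        f"{scaffold_id}\tfamdiverge\texon\t{a}\t{b}\t.\t{strand}\t.\t"
                        f"ID={tx_id}.e{ei + 1};Parent={tx_id}"
                    )
                tx_ids.append(tx_id)
            gene_records.append(
                GeneRecord(
                    gene_id=gene_id,
                    species=species,
                    order_name=order,
                    family="treh",
                    scaffold_id=scaffold_id,
                    start=gene_start,
                    end=gene_end,
                    strand=strand,
                    transcript_ids=tuple(tx_ids),
                )
            )

        # --- acid-trehalase genes: intronless, single isoform, all six motifs
        for ai in range(cfg.ath_per_species):
            gene_id = f"{species}_ath{ai + 1:02d}"
            scaffold_id = f"{species}_athscaf{ai + 1}"
            parts = ["M"]
            offsets = {}
            pos = 1
            for name, instance in ATH_INSTANCES:
                pad = _background(rng, PAD, cfg.topology_noise)
                parts.append(pad)
                pos += len(pad)
                offsets[name] = pos
                parts.append(instance)
                pos += len(instance)
            parts.append(_background(rng, PAD, cfg.topology_noise))
            ath_protein = "".join(parts)
            tx_id = f"{gene_id}.t1"
            truth_ath[tx_id] = offsets
            protein_records.append(SequenceRecord(tx_id, ath_protein, "protein"))
            cds = _reverse_translate(ath_protein, rng)
            pad5 = "".join(rng.choice(list(NUCLEOTIDES), size=60))
            pad3 = "".join(rng.choice(list(NUCLEOTIDES), size=60))
            scaffolds.append(
                SequenceRecord(scaffold_id, pad5 + cds + pad3, "nucleotide")
            )
            a, b = len(pad5) + 1, len(pad5) + len(cds)
            gff_lines.append(
                f"{scaffold_id}\tfamdiverge\tgene\t{a}\t{b}\t.\t+\t.\t"
                f"ID={gene_id};species={species};order={order};family=ath"
            )
            gff_lines.append(
                f"{scaffold_id}\tfamdiverge\tmRNA\t{a}\t{b}\t.\t+\t.\t"
                f"ID={tx_id};Parent={gene_id}"
            )
            gff_lines.append(
                f"{scaffold_id}\tfamdiverge\texon\t{a}\t{b}\t.\t+\t.\t"
                f"ID={tx_id}.e1;Parent={tx_id}"
            )
            gene_records.append(
                GeneRecord(
                    gene_id=gene_id, species=species, order_name=order,
                    family="ath", scaffold_id=scaffold_id, start=a, end=b,
                    strand="+", transcript_ids=(tx_id,),
                )
            )

        iso_truth[species] = {
            "sensu_stricto": len(set(species_variants)),
            "sensu_lato": len(species_signatures),
        }

    # outgroup: a deeply diverged family member for rooting the tree
    out_probs = {name: 0.15 for name, _, _ in LAYOUT.domain_intervals}
    outgroup = evolve_sequence(
        root_protein, LAYOUT.domain_intervals, out_probs, 0.5, rng, None
    )
    alignment_records.append(
        SequenceRecord("Ecoli_treh_outgroup", outgroup, "aligned-protein")
    )

    neighborhoods, ops_log = plant_neighborhoods(
        cfg, genes_by_species_ids, order_of_species, scaffold_of_gene, rng
    )
    species_list = sorted(neighborhoods)
    pairwise_shared = {}
    for i, sa in enumerate(species_list):
        for sb in species_list[i + 1 :]:
            best = 0
            for na in neighborhoods[sa]:
                labels_a = {l for l, _ in na.neighbors}
                for nb in neighborhoods[sb]:
                    best = max(best, len(labels_a & {l for l, _ in nb.neighbors}))
            pairwise_shared[f"{sa}|{sb}"] = best

    ground_truth = {
        "gene_counts": gene_counts,
        "transcript_counts": tx_counts,
        "isoforms": iso_truth,
        "topology": truth_topology,
        "domain_intervals": truth_domains,
        "ath_motif_offsets": truth_ath,
        "pairwise_shared_neighbors": pairwise_shared,
        "rearrangements": ops_log,
        "substitution_log": sub_log,
    }
    return Dataset(
        config=cfg,
        gene_records=gene_records,
        scaffolds=scaffolds,
        protein_records=protein_records,
        alignment_records=alignment_records,
        neighborhoods=neighborhoods,
        gff3_text="\n".join(gff_lines) + "\n",
        ground_truth=ground_truth,
    )
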