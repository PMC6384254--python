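"""Distance-based phylogeny of the trimmed family alignment.

A pairwise p-distance matrix (pairwise deletion, as in the conservation
module) feeds canonical neighbor joining (Q-matrix criterion) with
deterministic tie-breaking by label order.  Neighbor joining is exact on
additive distance matrices and stands in for likelihood inference, keeping
the whole pipeline self-contained; an externally computed Newick tree can
be annotated instead when one is available.  Trees are carried as dendropy
objects, rooted on an outgroup leaf by splitting its subtending edge
evenly, and written as Newick plus an annotation table keyed by leaf
label (conservation heat-strip plus isoform counts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd

from famdiverge.anchors_and_trim import ProteinAlignment
from famdiverge.conservation import ConservationMatrix, p_distance
from famdiverge.errors import ValidationError


@dataclass
class DistanceMatrix:
    """Symmetric p-distance matrix with ordered labels (NaN = missing)."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError("distance matrix shape does not match labels")
        if not np.allclose(np.diag(self.values), 0.0, equal_nan=False):
            raise ValidationError("distance matrix diagonal must be zero")
        with np.errstate(invalid="ignore"):
            asym = np.nanmax(np.abs(self.values - self.values.T)) if n else 0.0
        if n and asym > 1e-12:
            raise ValidationError("distance matrix must be symmetric")

    def has_missing(self) -> bool:
        off = ~np.eye(len(self.labels), dtype=bool)
        return bool(np.isnan(self.values[off]).any())

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t", float_format="%.6f"
        )


def distance_matrix(msa: ProteinAlignment) -> DistanceMatrix:
    """All-pairs p-distance on the (trimmed) alignment rows.

    Pairs with zero comparable columns are missing; a row missing against
    every other row is an error (it cannot be placed in any tree).
    """
    ids = list(msa.ids)
    seqs = [seq for _, seq in msa.rows]
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = p_distance(seqs[i], seqs[j])
    for i in range(n):
        others = [j for j in range(n) if j != i]
        if others and all(math.isnan(d[i, j]) for j in others):
            raise ValidationError(
                f"sequence {ids[i]!r} shares no comparable columns with any "
                "other sequence; filter it before building a tree"
            )
    return DistanceMatrix(tuple(ids), d)


@dataclass
class PhyloTree:
    """A tree over the matrix labels; negative NJ branch lengths are
    clamped to zero and recorded in ``clamped_edges``."""

    tree: dendropy.Tree
    clamped_edges: int = 0
    _namespace: dendropy.TaxonNamespace = field(default=None, repr=False)

    @property
    def leaf_labels(self) -> set[str]:
        return {leaf.taxon.label for leaf in self.tree.leaf_node_iter()}

    def newick(self) -> str:
        return self.tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        )

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        tree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
        return cls(tree=tree)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.newick())


def _clamp(length: float, counter: list[int]) -> float:
    if length < 0:
        counter[0] += 1
        return 0.0
    return length


def nj_tree(d: DistanceMatrix) -> PhyloTree:
    """Canonical neighbor joining (Saitou-Nei, Q-matrix criterion).

    Requires >= 3 labels and a complete matrix.  When several pairs share
    the minimal Q value, the pair whose sorted label pair is smallest is
    joined — fully deterministic.  Negative branch-length estimates are
    clamped to zero and counted.
    """
    if len(d.labels) < 3:
        raise ValidationError("neighbor joining requires at least 3 labels")
    if d.has_missing():
        raise ValidationError(
            "distance matrix has missing entries; filter sequences with no "
            "comparable columns before tree building"
        )
    tns = dendropy.TaxonNamespace()
    clamped = [0]

    # active nodes: (sort label, dendropy node); distances in a dict keyed by node id
    nodes: list[tuple[str, dendropy.Node]] = []
    for label in d.labels:
        taxon = tns.new_taxon(label)
        nodes.append((label, dendropy.Node(taxon=taxon)))
    dist: dict[tuple[int, int], float] = {}
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            dist[(i, j)] = float(d.values[i, j])
    index = list(range(len(nodes)))  # active node indices into `nodes`
    next_index = len(nodes)

    def get_d(a: int, b: int) -> float:
        return dist[(a, b) if a < b else (b, a)]

    while len(index) > 3:
        n = len(index)
        r = {a: sum(get_d(a, b) for b in index if b != a) for a in index}
        best_pair = None
        best_q = None
        # iterate pairs in sorted-label order so Q ties break deterministically
        ordered = sorted(index, key=lambda a: nodes[a][0])
        for ii, a in enumerate(ordered):
            for b in ordered[ii + 1 :]:
                q = (n - 2) * get_d(a, b) - r[a] - r[b]
                if best_q is None or q < best_q:
                    best_q = q
                    best_pair = (a, b)
        a, b = best_pair
        dab = get_d(a, b)
        la = dab / 2.0 + (r[a] - r[b]) / (2.0 * (n - 2))
        lb = dab - la
        parent = dendropy.Node()
        child_a, child_b = nodes[a][1], nodes[b][1]
        parent.add_child(child_a)
        parent.add_child(child_b)
        child_a.edge.length = _clamp(la, clamped)
        child_b.edge.length = _clamp(lb, clamped)
        u = next_index
        next_index += 1
        nodes.append((min(nodes[a][0], nodes[b][0]), parent))
        for c in index:
            if c in (a, b):
                continue
            duc = (get_d(a, c) + get_d(b, c) - dab) / 2.0
            dist[(min(u, c), max(u, c))] = duc
        index = [c for c in index if c not in (a, b)] + [u]

    a, b, c = index
    dab, dac, dbc = get_d(a, b), get_d(a, c), get_d(b, c)
    root = dendropy.Node()
    for node_idx, length in (
        (a, (dab + dac - dbc) / 2.0),
        (b, (dab + dbc - dac) / 2.0),
        (c, (dac + dbc - dab) / 2.0),
    ):
        child = nodes[node_idx][1]
        root.add_child(child)
        child.edge.length = _clamp(length, clamped)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = False
    return PhyloTree(tree=tree, clamped_edges=clamped[0], _namespace=tns)


def root_with_outgroup(t: PhyloTree, label: str) -> PhyloTree:
    """Root on the edge subtending the outgroup leaf, length split evenly."""
    tree = t.tree.clone(depth=1)
    leaf = None
    for node in tree.leaf_node_iter():
        if node.taxon is not None and node.taxon.label == label:
            leaf = node
            break
    if leaf is None:
        raise ValidationError(f"outgroup label {label!r} not in tree")
    edge_len = leaf.edge.length or 0.0
    tree.reroot_at_edge(
        leaf.edge, length1=edge_len / 2.0, length2=edge_len / 2.0,
        update_bipartitions=False,
    )
    tree.is_rooted = True
    return PhyloTree(tree=tree, clamped_edges=t.clamped_edges)


def annotate_leaves(
    t: PhyloTree,
    conservation: ConservationMatrix,
    isoforms: Mapping[str, tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Per-leaf annotation: anchor p-distances plus isoform counts.

    Leaves absent from the conservation matrix get missing cells; row
    order follows the tree's leaf order.
    """
    iso = isoforms or {}
    rows = []
    for leaf in t.tree.leaf_node_iter():
        label = leaf.taxon.label
        row: dict = {"leaf": label}
        if label in conservation.table.index:
            row.update(conservation.table.loc[label].to_dict())
        else:
            row.update({c: math.nan for c in conservation.table.columns})
        s, l = iso.get(label, (None, None))
        row["isoforms_s"] = s
        row["isoforms_l"] = l
        rows.append(row)
    return pd.DataFrame(rows)


def robinson_foulds(a: PhyloTree, b: PhyloTree) -> int:
    """Unweighted RF distance on a shared taxon namespace."""
    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=a.newick(), schema="newick", taxon_namespace=tns)
    tb = dendropy.Tree.get(data=b.newick(), schema="newick", taxon_namespace=tns)
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(ta, tb)


def nj_bootstrap(
    msa: ProteinAlignment, replicates: int, seed: int
) -> pd.DataFrame:
    """Seeded column-resampling bootstrap support for the NJ tree.

    Returns one row per internal bipartition of the reference tree with
    its support fraction over the replicates.
    """
    rng = np.random.default_rng(seed)
    reference = nj_tree(distance_matrix(msa))
    tns = dendropy.TaxonNamespace()
    ref = dendropy.Tree.get(
        data=reference.newick(), schema="newick", taxon_namespace=tns
    )
    ref.encode_bipartitions()
    ref_splits = {
        b.split_bitmask: 0
        for b in ref.bipartition_encoding
        if not b.is_trivial()
    }
    width = msa.width
    for _ in range(replicates):
        cols = rng.integers(0, width, size=width)
        rows = tuple(
            (rid, "".join(seq[c] for c in cols)) for rid, seq in msa.rows
        )
        rep = nj_tree(distance_matrix(ProteinAlignment(rows)))
        rep_tree = dendropy.Tree.get(
            data=rep.newick(), schema="newick", taxon_namespace=tns
        )
        rep_tree.encode_bipartitions()
        rep_splits = {
            b.split_bitmask for b in rep_tree.bipartition_encoding if not b.is_trivial()
        }
        for s in ref_splits:
            if s in rep_splits:
                ref_splits[s] += 1
    rows_out = [
        {"bipartition": f"{mask:x}", "support": count / replicates}
        for mask, count in sorted(ref_splits.items())
    ]
    return pd.DataFrame(rows_out, columns=["bipartition", "support"])


def assign_subfamilies(
    t: PhyloTree, reference_labels: Mapping[str, str]
) -> dict[str, str]:
    """Heuristic subfamily labels by nearest reference leaf.

    Each non-reference leaf receives the subfamily (e.g. ``treh-1`` /
    ``treh-2``) of its patristically nearest reference leaf.  This is a
    tree-position heuristic, not a claim about clade membership.
    """
    pdm = t.tree.phylogenetic_distance_matrix()
    taxa = {taxon.label: taxon for taxon in t.tree.taxon_namespace}
    missing = [lbl for lbl in reference_labels if lbl not in taxa]
    if missing:
        raise ValidationError(f"reference labels not in tree: {missing}")
    out: dict[str, str] = {}
    for leaf in t.tree.leaf_node_iter():
        label = leaf.taxon.label
        if label in reference_labels:
            out[label] = reference_labels[label]
            continue
        best = min(
            sorted(reference_labels),
            key=lambda ref: (pdm.patristic_distance(taxa[ref], leaf.taxon), ref),
        )
        out[label] = reference_labels[best]
    return out
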