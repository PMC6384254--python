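import itertools
import math

import dendropy
import numpy as np
import pytest

from famdiverge.anchors_and_trim import ProteinAlignment
from famdiverge.conservation import ConservationMatrix, p_distance
from famdiverge.errors import ValidationError
from famdiverge.phylo_distance import (
    DistanceMatrix,
    PhyloTree,
    annotate_leaves,
    assign_subfamilies,
    distance_matrix,
    nj_bootstrap,
    nj_tree,
    robinson_foulds,
    root_with_outgroup,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_additive_matrix(rng, n=5):
    """A random additive matrix from a random tree with positive lengths.

    Built independently of neighbor joining: draw a random binary topology
    by sequential leaf attachment, assign random edge lengths, and read off
    path-length distances.
    """
    # represent the tree as an adjacency list over node ids
    edges = {}  # node -> list of (node, length)

    def add_edge(u, v, w):
        edges.setdefault(u, []).append((v, w))
        edges.setdefault(v, []).append((u, w))

    next_node = [n]
    leaf_ids = list(range(n))
    # start from a 3-leaf star
    center = next_node[0]
    next_node[0] += 1
    for leaf in leaf_ids[:3]:
        add_edge(leaf, center, float(rng.uniform(0.05, 1.0)))
    existing_edges = [(leaf, center) for leaf in leaf_ids[:3]]
    for leaf in leaf_ids[3:]:
        u, v = existing_edges[rng.integers(0, len(existing_edges))]
        w = dict(edges[u])[v]
        mid = next_node[0]
        next_node[0] += 1
        # split edge (u,v) at mid
        edges[u] = [(x, d) for x, d in edges[u] if x != v]
        edges[v] = [(x, d) for x, d in edges[v] if x != u]
        cut = float(rng.uniform(0.2, 0.8)) * w
        add_edge(u, mid, cut)
        add_edge(v, mid, w - cut)
        add_edge(leaf, mid, float(rng.uniform(0.05, 1.0)))
        existing_edges.remove((u, v))
        existing_edges += [(u, mid), (v, mid), (leaf, mid)]

    def path_length(a, b):
        stack = [(a, 0.0, -1)]
        while stack:
            node, dist, prev = stack.pop()
            if node == b:
                return dist
            for nxt, w in edges.get(node, []):
                if nxt != prev:
                    stack.append((nxt, dist + w, node))
        raise AssertionError("disconnected")

    labels = tuple(chr(ord("A") + i) for i in range(n))
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = path_length(i, j)
    return labels, values


def quartet_split_by_four_point(values, quartet):
    """The four-point condition's preferred pairing of a quartet."""
    i, j, k, l = quartet
    sums = {
        frozenset([frozenset([i, j]), frozenset([k, l])]): values[i, j] + values[k, l],
        frozenset([frozenset([i, k]), frozenset([j, l])]): values[i, k] + values[j, l],
        frozenset([frozenset([i, l]), frozenset([j, k])]): values[i, l] + values[j, k],
    }
    return min(sums, key=sums.get)


def tree_quartet_split(tree: PhyloTree, labels, quartet):
    """The pairing a tree induces on four leaves (via patristic distance)."""
    tns = dendropy.TaxonNamespace()
    t = dendropy.Tree.get(data=tree.newick(), schema="newick",
                          taxon_namespace=tns, preserve_underscores=True)
    pdm = t.phylogenetic_distance_matrix()
    taxa = {x.label: x for x in tns}
    d = {}
    for a, b in itertools.combinations(quartet, 2):
        d[(a, b)] = d[(b, a)] = pdm.path_edge_count(
            taxa[labels[a]], taxa[labels[b]]
        )
    i, j, k, l = quartet
    sums = {
        frozenset([frozenset([i, j]), frozenset([k, l])]): d[(i, j)] + d[(k, l)],
        frozenset([frozenset([i, k]), frozenset([j, l])]): d[(i, k)] + d[(j, l)],
        frozenset([frozenset([i, l]), frozenset([j, k])]): d[(i, l)] + d[(j, k)],
    }
    return min(sums, key=sums.get)


class TestDistanceMatrix:
    def test_identical_rows_zero_offdiagonal(self):
        msa = ProteinAlignment((("a", "VIVPGGR"), ("b", "VIVPGGR")))
        dm = distance_matrix(msa)
        assert dm.values[0, 1] == 0.0

    def test_single_substitution(self):
        msa = ProteinAlignment((("a", "VIVPGGR"), ("b", "VIVPGGK")))
        assert distance_matrix(msa).values[0, 1] == pytest.approx(1 / 7)

    def test_equals_brute_force_double_loop(self):
        rng = np.random.default_rng(13)
        rows = tuple(
            (f"s{i}", "".join(rng.choice(list(AA + "-"), size=30)))
            for i in range(8)
        )
        msa = ProteinAlignment(rows)
        dm = distance_matrix(msa)
        for i in range(8):
            for j in range(8):
                expect = 0.0 if i == j else p_distance(rows[i][1], rows[j][1])
                if math.isnan(expect):
                    assert math.isnan(dm.values[i, j])
                else:
                    assert dm.values[i, j] == pytest.approx(expect)

    def test_symmetry_enforced(self):
        with pytest.raises(ValidationError):
            DistanceMatrix(("a", "b"), np.array([[0.0, 0.1], [0.2, 0.0]]))


class TestNeighborJoining:
    def test_four_taxon_additive_topology(self):
        # d(A,B)=2, d(C,D)=2, cross distances 4 -> split AB|CD
        labels = ("A", "B", "C", "D")
        v = np.array([
            [0, 2, 4, 4],
            [2, 0, 4, 4],
            [4, 4, 0, 2],
            [4, 4, 2, 0],
        ], dtype=float)
        t = nj_tree(DistanceMatrix(labels, v))
        split = tree_quartet_split(t, labels, (0, 1, 2, 3))
        assert split == frozenset([frozenset([0, 1]), frozenset([2, 3])])

    def test_three_taxon_closed_form(self):
        labels = ("A", "B", "C")
        v = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        t = nj_tree(DistanceMatrix(labels, v))
        lengths = {
            leaf.taxon.label: leaf.edge.length
            for leaf in t.tree.leaf_node_iter()
        }
        assert lengths["A"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["B"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["C"] == pytest.approx((4 + 5 - 3) / 2)

    def test_additive_matrices_reconstructed_exactly(self):
        # path-length metric check on random additive 5-taxon trees
        for seed in range(15):
            rng = np.random.default_rng(seed)
            labels, values = random_additive_matrix(rng, 5)
            t = nj_tree(DistanceMatrix(labels, values))
            tns = dendropy.TaxonNamespace()
            dt = dendropy.Tree.get(data=t.newick(), schema="newick",
                                   taxon_namespace=tns, preserve_underscores=True)
            pdm = dt.phylogenetic_distance_matrix()
            taxa = {x.label: x for x in tns}
            for i, j in itertools.combinations(range(5), 2):
                got = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
                assert got == pytest.approx(values[i, j], abs=1e-9)

    def test_agrees_with_skbio_reference_nj(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(42)
        labels, values = random_additive_matrix(rng, 6)
        ours = nj_tree(DistanceMatrix(labels, values))
        ref = skbio.tree.nj(skbio.DistanceMatrix(values, ids=list(labels)))
        ref_pt = PhyloTree.from_newick(str(ref).strip())
        assert robinson_foulds(ours, ref_pt) == 0

    def test_missing_distances_are_an_error(self):
        v = np.array([[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0.0]])
        with pytest.raises(ValidationError, match="missing"):
            nj_tree(DistanceMatrix(("a", "b", "c"), v))

    def test_generator_topology_recovered_at_zero_rate_noise(self):
        # an ultrametric matrix from a clean 4-clade structure
        labels = tuple("ABCDEF")
        blocks = {(0, 1): 0.1, (2, 3): 0.1, (4, 5): 0.1}
        v = np.full((6, 6), 0.8)
        np.fill_diagonal(v, 0.0)
        for (i, j), d in blocks.items():
            v[i, j] = v[j, i] = d
        t = nj_tree(DistanceMatrix(labels, v))
        for (i, j) in blocks:
            for k, l in itertools.combinations(
                [x for x in range(6) if x not in (i, j)], 2
            ):
                split = tree_quartet_split(t, labels, (i, j, k, l))
                assert frozenset([i, j]) in split


class TestRooting:
    def _tree(self):
        labels = ("A", "B", "C", "D")
        v = np.array([
            [0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]
        ], dtype=float)
        return nj_tree(DistanceMatrix(labels, v))

    def test_outgroup_becomes_sister_to_rest(self):
        rooted = root_with_outgroup(self._tree(), "A")
        children = rooted.tree.seed_node.child_nodes()
        assert len(children) == 2
        kid_leafsets = [
            {lf.taxon.label for lf in c.leaf_iter()} for c in children
        ]
        assert {"A"} in kid_leafsets

    def test_absent_label_is_error(self):
        with pytest.raises(ValidationError):
            root_with_outgroup(self._tree(), "Z")

    def test_rooting_preserves_topology(self):
        t = self._tree()
        rooted = root_with_outgroup(t, "B")
        assert robinson_foulds(t, rooted) == 0

    def test_newick_roundtrip_identical_topology(self):
        t = self._tree()
        back = PhyloTree.from_newick(t.newick())
        assert robinson_foulds(t, back) == 0


class TestAnnotation:
    def test_leaf_rows_and_missing_cells(self):
        import pandas as pd
        t = TestRooting()._tree()
        cm = ConservationMatrix(
            pd.DataFrame({"d1": [0.0, 0.5]}, index=["A", "B"])
        )
        table = annotate_leaves(t, cm, {"A": (2, 1)})
        table = table.set_index("leaf")
        assert table.loc["A", "d1"] == 0.0
        assert math.isnan(table.loc["C", "d1"])
        assert table.loc["A", "isoforms_s"] == 2

    def test_subfamily_assignment_by_nearest_reference(self):
        t = TestRooting()._tree()
        got = assign_subfamilies(t, {"A": "treh-1", "C": "treh-2"})
        assert got == {"A": "treh-1", "B": "treh-1", "C": "treh-2", "D": "treh-2"}


class TestBootstrap:
    def test_identical_columns_give_full_support(self):
        rng = np.random.default_rng(2)
        core = "".join(rng.choice(list(AA), size=40))
        rows = (
            ("A", core),
            ("B", core[:-1] + "W"),
            ("C", "".join(rng.choice(list(AA), size=40))),
            ("D", "".join(rng.choice(list(AA), size=40))),
        )
        table = nj_bootstrap(ProteinAlignment(rows), replicates=10, seed=5)
        assert ((table["support"] >= 0) & (table["support"] <= 1)).all()
        # seeded: same call twice is identical
        again = nj_bootstrap(ProteinAlignment(rows), replicates=10, seed=5)
        assert table.equals(again)
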