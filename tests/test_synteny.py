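from itertools import combinations

import numpy as np
import pytest

from famdiverge.errors import ValidationError
from famdiverge.synteny_colinearity import (
    ScaffoldNeighborhood,
    colinearity_score,
    compare,
    extract_neighborhood,
    intersection_across_species,
    pairwise_synteny_matrix,
    read_neighborhoods,
    shared_neighbors,
    write_neighborhoods,
)


def nb(labels, strands=None, species="sp", focal="F"):
    strands = strands or ["+"] * len(labels)
    return ScaffoldNeighborhood(
        species, "scaf", focal, tuple(zip(labels, strands))
    )


def exhaustive_lcs(a_labels, b_labels):
    """Oracle: longest common subsequence by explicit enumeration (n <= 8)."""
    best = 0
    n = len(a_labels)
    for mask in range(1 << n):
        sub = [a_labels[i] for i in range(n) if mask >> i & 1]
        it = iter(b_labels)
        if all(any(x == y for y in it) for x in sub):
            best = max(best, len(sub))
    return best


class TestExtract:
    def test_window(self):
        genes = [("g1", "o1", "+"), ("g2", "o2", "+"), ("T", "ot", "+"),
                 ("g3", "o3", "+"), ("g4", "o4", "+")]
        got = extract_neighborhood(genes, "T", 2)
        assert got.labels() == ("o1", "o2", "o3", "o4")

    def test_truncation_at_scaffold_end(self):
        genes = [("T", "ot", "+"), ("g3", "o3", "+"), ("g4", "o4", "+")]
        assert extract_neighborhood(genes, "T", 2).labels() == ("o3", "o4")

    def test_k_zero(self):
        genes = [("T", "ot", "+")]
        assert extract_neighborhood(genes, "T", 0).neighbors == ()

    def test_focal_absent_is_error(self):
        with pytest.raises(ValidationError):
            extract_neighborhood([("g", "o", "+")], "T", 2)


class TestShared:
    def test_counts_label_set_intersection(self):
        assert shared_neighbors(nb(["g1", "g2", "g3", "g4"]),
                                nb(["g9", "g2", "g3", "g8"])) == 2

    def test_identical(self):
        assert shared_neighbors(nb(list("abcd")), nb(list("abcd"))) == 4

    def test_disjoint_and_symmetry(self):
        a, b = nb(list("abc")), nb(list("xyz"))
        assert shared_neighbors(a, b) == shared_neighbors(b, a) == 0


class TestColinearity:
    def test_identical_neighborhoods(self):
        a = nb(list("abcd"), list("++--"))
        assert colinearity_score(a, a) == (4, 1.0)

    def test_inversion_awareness(self):
        a = nb(list("abcd"), list("++--"))
        b = nb(list("dcba"), list("++--"))  # reversed with strands flipped
        assert colinearity_score(a, b) == (4, 1.0)

    def test_shuffled_order_gives_partial_run(self):
        a, b = nb(list("abc")), nb(["c", "a", "b"])
        run, _ = colinearity_score(a, b)
        assert run == 2

    def test_matches_exhaustive_subsequence_search(self):
        rng = np.random.default_rng(31)
        pool = list("abcdefgh")
        for _ in range(100):
            la = [pool[i] for i in rng.integers(0, 8, size=rng.integers(0, 9))]
            lb = [pool[i] for i in rng.integers(0, 8, size=rng.integers(0, 9))]
            run, _ = colinearity_score(nb(la), nb(lb))
            assert run == max(exhaustive_lcs(la, lb),
                              exhaustive_lcs(la, lb[::-1]))

    def test_reversal_invariance_of_scores(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            labels = [f"g{i}" for i in rng.permutation(6)]
            strands = ["+" if rng.random() < 0.5 else "-" for _ in labels]
            a = nb([f"g{i}" for i in range(6)])
            b = nb(labels, strands)
            flipped = nb(labels[::-1],
                         ["-" if s == "+" else "+" for s in strands[::-1]])
            assert colinearity_score(a, b) == colinearity_score(a, flipped)

    def test_run_never_exceeds_shared(self):
        rng = np.random.default_rng(77)
        for _ in range(50):
            la = [f"g{i}" for i in rng.integers(0, 5, size=7)]
            lb = [f"g{i}" for i in rng.integers(0, 5, size=7)]
            res = compare(nb(la), nb(lb))
            assert 0 <= res.colinear_run <= res.shared_count


class TestMatrix:
    def test_identical_single_neighborhoods(self):
        nbhds = {
            "A": [nb(list("abcd"), species="A")],
            "B": [nb(list("abcd"), species="B")],
        }
        df = pairwise_synteny_matrix(nbhds)
        assert df.iloc[0]["shared"] == 4

    def test_species_without_focal_genes_gives_missing_row(self):
        nbhds = {"A": [nb(list("ab"), species="A")], "B": []}
        df = pairwise_synteny_matrix(nbhds)
        assert df.iloc[0][["shared", "colinear_run"]].isna().all()

    def test_intersection_across_species(self):
        nbhds = {
            "A": [nb(list("abc"), species="A")],
            "B": [nb(list("abd"), species="B")],
            "C": [nb(list("abe"), species="C")],
        }
        assert intersection_across_species(nbhds) == 2

    def test_tsv_roundtrip(self, tmp_path):
        nbhds = {
            "A": [nb(list("abc"), list("+-+"), species="A", focal="f1")],
            "B": [nb(list("xyz"), species="B", focal="f2")],
        }
        p = tmp_path / "n.tsv"
        write_neighborhoods(nbhds, p)
        back = read_neighborhoods(p)
        assert back["A"][0].neighbors == nbhds["A"][0].neighbors
        assert back["B"][0].focal_gene_id == "f2"


class TestPlantedRearrangements:
    def test_planted_counts_recovered(self, default_dataset):
        nbhds = default_dataset.neighborhoods
        truth = default_dataset.ground_truth["pairwise_shared_neighbors"]
        species = sorted(nbhds)
        for sa, sb in combinations(species, 2):
            best = max(
                shared_neighbors(na, nbb)
                for na in nbhds[sa]
                for nbb in nbhds[sb]
            )
            assert best == truth[f"{sa}|{sb}"]

    def test_same_order_shares_more_than_cross_order(self, default_dataset):
        df = pairwise_synteny_matrix(default_dataset.neighborhoods)
        same = df[[a.split("_")[0] == b.split("_")[0]
                   for a, b in zip(df.species_a, df.species_b)]]
        cross = df[[a.split("_")[0] != b.split("_")[0]
                    for a, b in zip(df.species_a, df.species_b)]]
        assert same["shared"].min() >= 1
        assert cross["shared"].max() == 0
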