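import json
import math

import numpy as np
import pytest

from famdiverge import synthetic_data as sim
from famdiverge.errors import ValidationError
from famdiverge.io_formats import read_fasta


def tiny_config(**overrides):
    base = dict(
        seed=3,
        orders=(("Hemiptera", 2, 1.0), ("Diptera", 2, 1.0)),
        domain_rates=(0.0,) * 7,
        background_rate=0.0,
        tx_min=1, tx_max=1, tx_probs=(1.0,),
        p_signal=0.0, p_tm=0.0,
        ath_per_species=0,
    )
    base.update(overrides)
    return sim.SimulationConfig(**base)


class TestConfig:
    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValidationError):
            sim.SimulationConfig(tx_probs=(0.5, 0.2)).validate()
        with pytest.raises(ValidationError):
            sim.SimulationConfig(p_signal=1.5).validate()

    def test_species_tree_is_ultrametric_depth_one(self):
        import dendropy
        newick = sim.build_species_tree((("Hemiptera", 3, 2.0), ("Diptera", 1, 2.0)))
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True)
        depths = {}
        for leaf in tree.leaf_node_iter():
            d, node = 0.0, leaf
            while node.parent_node is not None:
                d += node.edge.length or 0.0
                node = node.parent_node
            depths[leaf.taxon.label] = d
        assert all(abs(d - 1.0) < 1e-9 for d in depths.values())
        assert len(depths) == 4


class TestTrivialRegimes:
    def test_no_duplication_no_loss_one_gene_per_species(self):
        ds = sim.simulate_dataset(tiny_config())
        counts = ds.ground_truth["gene_counts"]
        assert all(v["treh"] == 1 for v in counts.values())
        assert len(counts) == 4

    def test_zero_rates_identical_sequences_everywhere(self):
        ds = sim.simulate_dataset(tiny_config())
        seqs = {r.residues for r in ds.alignment_records
                if r.id != "Ecoli_treh_outgroup"}
        assert len(seqs) == 1  # every p-distance is 0
        assert ds.ground_truth["substitution_log"]["background"]["subs"] == 0

    def test_same_seed_byte_identical_outputs(self, tmp_path):
        cfg = sim.default_config(11)
        d1 = tmp_path / "a"
        d2 = tmp_path / "b"
        sim.simulate_dataset(cfg).write(d1)
        sim.simulate_dataset(sim.default_config(11)).write(d2)
        for p1 in sorted(d1.iterdir()):
            assert p1.read_bytes() == (d2 / p1.name).read_bytes()

    def test_different_seeds_differ(self, tmp_path):
        a = sim.simulate_dataset(sim.default_config(1))
        b = sim.simulate_dataset(sim.default_config(2))
        assert a.gff3_text != b.gff3_text


class TestEvolveSequence:
    def test_rate_zero_identity(self):
        rng = np.random.default_rng(0)
        parent = "M" + "A" * 50
        child = sim.evolve_sequence(parent, [("d", 10, 20)], {"d": 0.0}, 0.0, rng)
        assert child == parent

    def test_rate_one_saturates_domain(self):
        rng = np.random.default_rng(0)
        parent = "M" + "A" * 50
        child = sim.evolve_sequence(parent, [("d", 10, 17)], {"d": 1.0}, 0.0, rng)
        assert all(child[i] != parent[i] for i in range(10, 17))
        assert child[:10] == parent[:10] and child[17:] == parent[17:]

    def test_realized_fraction_within_3_sigma_of_binomial(self):
        rng = np.random.default_rng(123)
        n = 10_000
        parent = "M" + "A" * n
        p = 0.07
        log = {}
        sim.evolve_sequence(parent, [("d", 1, n + 1)], {"d": p}, 0.0, rng, log)
        entry = log["d"]
        sigma = math.sqrt(entry["sum_pq"])
        assert abs(entry["subs"] - entry["sum_p"]) <= 3 * sigma

    def test_position_zero_never_mutates(self):
        rng = np.random.default_rng(5)
        parent = "M" + "A" * 20
        child = sim.evolve_sequence(parent, [], {}, 1.0, rng)
        assert child[0] == "M"


class TestPlantedStructure:
    def test_planted_domains_sit_at_recorded_intervals(self, default_dataset):
        reps = {r.id: r.residues for r in default_dataset.alignment_records}
        truth = default_dataset.ground_truth["domain_intervals"]
        layout = sim.LAYOUT
        for rep_id, intervals in list(truth.items())[:20]:
            protein = reps[rep_id]
            assert len(protein) == layout.length
            for (name, s, e) in layout.domain_intervals:
                assert intervals[name] == [s, e]

    def test_ath_motifs_planted_exactly(self, default_dataset):
        prots = {r.id: r.residues for r in default_dataset.protein_records}
        instances = dict(sim.ATH_INSTANCES)
        for pid, offsets in default_dataset.ground_truth["ath_motif_offsets"].items():
            for name, off in offsets.items():
                seq = prots[pid]
                assert seq[off: off + len(instances[name])] == instances[name]

    def test_no_rearrangement_full_block_shared(self):
        cfg = tiny_config(p_inversion=0.0, p_insertion=0.0, p_translocation=0.0)
        ds = sim.simulate_dataset(cfg)
        shared = ds.ground_truth["pairwise_shared_neighbors"]
        assert shared["Hemiptera_sp1|Hemiptera_sp2"] == cfg.shared_block_size
        assert shared["Diptera_sp1|Hemiptera_sp1"] == 0

    def test_ground_truth_json_consistent_with_files(self, dataset_dir):
        truth = json.loads((dataset_dir / "ground_truth.json").read_text())
        proteins = read_fasta(dataset_dir / "proteins.fasta", "protein")
        assert len(proteins) == (
            sum(truth["transcript_counts"].values())
            + sum(v["ath"] for v in truth["gene_counts"].values())
        )


class TestConservationResponse:
    def test_realized_domain_divergence_tracks_configured_rates(self, default_dataset):
        # ranks of realized per-domain substitution fractions must correlate
        # positively with the configured (ascending) per-domain rates
        log = default_dataset.ground_truth["substitution_log"]
        cfg = default_dataset.config
        names = [name for name, _, _ in sim.LAYOUT.domain_intervals]
        realized = [log[n]["subs"] / log[n]["sites"] for n in names]
        from scipy.stats import spearmanr
        rho, _ = spearmanr(realized, cfg.domain_rates)
        assert rho > 0
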