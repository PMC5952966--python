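"""Generator contracts: determinism, ground-truth consistency, planted
events, start-error corruption, and predictor emulation."""

import dataclasses
import hashlib

import numpy as np
import pytest
from Bio.Seq import Seq
from scipy.stats import binom

from sigpevo.io import load_dataset, write_dataset
from sigpevo.secretome import consensus_state, heuristic_sp_score
from sigpevo.startfix import zero_noise_predictor
from sigpevo.synthetic_data import SimulationConfig, emulate_predictors, \
    plant_start_errors, sample_signal_peptide, simulate_dataset, \
    simulate_family, simulate_taxonomy
from sigpevo.types import ConsensusState


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"family_size_range": (2, 10)},
        {"lifestyle_fractions": (0.5, 0.4, 0.2)},
        {"sp_loss_rate": -0.1},
        {"mechanism_mix": 1.5},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)

    def test_too_few_species_rejected(self):
        with pytest.raises(ValueError):
            simulate_taxonomy(SimulationConfig(n_species=2))


class TestTaxonomy:
    def test_three_species_single_lifestyle(self):
        cfg = SimulationConfig(seed=0, n_species=3,
                               lifestyle_fractions=(1.0, 0.0, 0.0))
        ss = simulate_taxonomy(cfg)
        assert len(ss.species) == 3
        assert all(s.lifestyle == 0 for s in ss.species)
        assert len(ss.tree.leaf_nodes()) == 3

    def test_same_seed_same_species_set(self):
        cfg = SimulationConfig(seed=5, n_species=25)
        a, b = simulate_taxonomy(cfg), simulate_taxonomy(cfg)
        assert [dataclasses.asdict(s) for s in a.species] == \
            [dataclasses.asdict(s) for s in b.species]
        assert a.tree.as_string(schema="newick") == \
            b.tree.as_string(schema="newick")

    def test_lifestyle_counts_within_binomial_bounds(self):
        cfg = SimulationConfig(seed=3, n_species=153)
        ss = simulate_taxonomy(cfg)
        counts = np.bincount([s.lifestyle for s in ss.species], minlength=3)
        for k, p in enumerate(cfg.lifestyle_fractions):
            lo = binom.ppf(0.005, 153, p)
            hi = binom.ppf(0.995, 153, p)
            assert lo <= counts[k] <= hi

    def test_taxonomy_ranks_are_clades(self, species20):
        tree = species20.tree
        by_genus: dict[str, list[str]] = {}
        for s in species20.species:
            by_genus.setdefault(s.taxonomy["genus"], []).append(s.species_id)
        for genus, members in by_genus.items():
            if len(members) < 2:
                continue
            mrca = tree.mrca(taxon_labels=members)
            clade = {l.taxon.label for l in mrca.leaf_iter()}
            assert clade == set(members), f"genus {genus} is not a clade"

    def test_branch_lengths_positive(self, species20):
        for edge in species20.tree.preorder_edge_iter():
            if edge.tail_node is not None:
                assert edge.length > 0

    def test_endosymbiont_genomes_smaller(self):
        cfg = SimulationConfig(seed=2, n_species=100)
        ss = simulate_taxonomy(cfg)
        sizes = {0: [], 1: [], 2: []}
        for s in ss.species:
            sizes[s.lifestyle].append(s.genome_size)
        assert np.mean(sizes[1]) < 0.5 * np.mean(sizes[0])


class TestFamilySimulation:
    def test_no_event_limit_all_leaves_keep_sp(self, species20):
        cfg = SimulationConfig(seed=0, n_species=20, sp_gain_rate=0.0,
                               sp_loss_rate=0.0, root_sp_prob=1.0,
                               tat_fraction=0.0)
        subset = [s.species_id for s in species20.species[:6]]
        cluster, truth = simulate_family(cfg, species20, subset, "F", seed=1)
        assert truth.events == []
        assert all(v == 1 for v in truth.node_states.values())

    def test_msa_rows_degap_to_sequences(self, species20):
        cfg = SimulationConfig(seed=0, n_species=20, sp_loss_rate=0.2,
                               root_sp_prob=0.8)
        subset = [s.species_id for s in species20.species[:8]]
        cluster, _ = simulate_family(cfg, species20, subset, "F", seed=4)
        for m in cluster.members:
            assert cluster.msa.degapped(m.protein_id) == m.sequence

    def test_translation_reproduces_protein(self, species20):
        cfg = SimulationConfig(seed=0, n_species=20)
        subset = [s.species_id for s in species20.species[:5]]
        cluster, _ = simulate_family(cfg, species20, subset, "F", seed=2)
        for m in cluster.members:
            aa = str(Seq(m.cds).translate(table=11))
            assert aa == m.sequence  # initiator is a genuine ATG here

    def test_planted_loss_count_matches_closed_form(self, species20):
        """Mean planted losses over replicates vs. the branch-survival
        expectation: each branch loses with rate x P(parent still SP)."""
        rate = 0.3
        cfg = SimulationConfig(seed=0, n_species=20, sp_gain_rate=0.0,
                               sp_loss_rate=rate, root_sp_prob=1.0,
                               tat_fraction=0.0, endo_loss_multiplier=1.0)
        subset = sorted(s.species_id for s in species20.species[:10])

        # closed-form expectation on the induced tree (oracle, no package
        # event machinery): recurse survival probability down the tree
        tree = species20.tree.extract_tree_with_taxa_labels(labels=subset)
        def expected_losses(node, p_sp):
            total = 0.0
            for child in node.child_nodes():
                total += p_sp * rate
                total += expected_losses(child, p_sp * (1 - rate))
            return total
        expectation = expected_losses(tree.seed_node, 1.0)

        n_rep = 400
        counts = []
        for r in range(n_rep):
            _, truth = simulate_family(cfg, species20, subset, "F", seed=r)
            counts.append(sum(e["type"] == "loss" for e in truth.events))
        mean = np.mean(counts)
        se = np.std(counts, ddof=1) / np.sqrt(n_rep)
        assert abs(mean - expectation) <= 3 * se

    def test_indel_loss_leaves_gaps_over_sp_columns(self, species20):
        cfg = SimulationConfig(seed=0, n_species=20, sp_gain_rate=0.0,
                               sp_loss_rate=0.5, root_sp_prob=1.0,
                               mechanism_mix=1.0, tat_fraction=0.0,
                               endo_loss_multiplier=1.0)
        subset = [s.species_id for s in species20.species[:8]]
        cluster, truth = simulate_family(cfg, species20, subset, "F", seed=3)
        losses = [e for e in truth.events if e["type"] == "loss"]
        assert losses and all(e["mechanism"] == "indel" for e in losses)
        sp_len = max(truth.cleavage.values())
        for m in cluster.members:
            row = cluster.msa.row(m.protein_id)
            if truth.node_states[m.protein_id] == 0:
                assert set(row[:sp_len]) == {"-"}

    def test_zero_noise_zero_error_consensus_equals_ground_truth(self):
        cfg = SimulationConfig(seed=8, n_species=25, n_families=40,
                               predictor_noise=(0, 0, 0),
                               start_error_rate=0.0, tat_fraction=0.0)
        ds = simulate_dataset(cfg)
        for cluster in ds.clusters:
            for m in cluster.members:
                state = consensus_state(ds.predictions[m.protein_id])
                expected = (ConsensusState.POSITIVE if m.true_state
                            else ConsensusState.NEGATIVE)
                assert state is expected

    def test_planted_events_lie_on_tree_branches(self, small_dataset):
        from sigpevo.parsimony import node_key
        for cid, fam in small_dataset.truth.families.items():
            cluster = next(c for c in small_dataset.clusters
                           if c.cluster_id == cid)
            branches = {(node_key(n.parent_node), node_key(n))
                        for n in cluster.tree.preorder_node_iter()
                        if n.parent_node is not None}
            for e in fam.events:
                assert (e["parent"], e["child"]) in branches


class TestStartErrors:
    def _sp_cluster(self, species20, seed=6):
        cfg = SimulationConfig(seed=0, n_species=20, sp_gain_rate=0.0,
                               sp_loss_rate=0.0, root_sp_prob=1.0,
                               tat_fraction=0.0)
        subset = [s.species_id for s in species20.species[:6]]
        return cfg, *simulate_family(cfg, species20, subset, "F", seed=seed)

    def test_zero_rate_is_identity(self, species20):
        cfg, cluster, truth = self._sp_cluster(species20)
        before = {m.protein_id: m.sequence for m in cluster.members}
        plant_start_errors(cluster, truth,
                           dataclasses.replace(cfg, start_error_rate=0.0),
                           np.random.default_rng(0))
        assert {m.protein_id: m.sequence for m in cluster.members} == before
        assert truth.start_errors == {}

    def test_corruption_flips_zero_noise_call_and_shift_near_sp_length(
            self, species20):
        cfg, cluster, truth = self._sp_cluster(species20)
        plant_start_errors(cluster, truth,
                           dataclasses.replace(cfg, start_error_rate=1.0),
                           np.random.default_rng(0))
        assert truth.start_errors
        for pid, shift in truth.start_errors.items():
            record = next(m for m in cluster.members if m.protein_id == pid)
            assert not zero_noise_predictor(record.sequence).signalp_call
            sp_len = truth.cleavage[pid]
            assert sp_len <= shift <= sp_len + cfg.start_shift_range[1]
            assert 15 <= shift <= 50  # concentrated near the SP length
            assert cluster.msa.degapped(pid) == record.sequence


class TestPredictorEmulation:
    def _record(self, sequence):
        from sigpevo.types import ProteinRecord
        return ProteinRecord("p", "s", sequence)

    def test_zero_noise_matches_heuristic_on_canonical_sp(self):
        seq = sample_signal_peptide(np.random.default_rng(0)) + "TDNSQEG" * 10
        triple = emulate_predictors(self._record(seq), (0, 0, 0), seed=1)
        assert triple.signalp_call and triple.phobius_call
        assert not triple.tatp_call
        assert triple.signalp_score > 0.5
        assert triple.cleavage_pos == heuristic_sp_score(seq)[1]

    def test_twin_arginine_variant_sets_tat_call(self):
        seq = sample_signal_peptide(np.random.default_rng(0), tat=True) \
            + "TDNSQEG" * 10
        triple = emulate_predictors(self._record(seq), (0, 0, 0), seed=1)
        assert triple.tatp_call

    def test_forced_phobius_flip_creates_discordance(self):
        seq = sample_signal_peptide(np.random.default_rng(0)) + "TDNSQEG" * 10
        triple = emulate_predictors(self._record(seq), (0.0, 1.0, 0.0), seed=1)
        assert triple.signalp_call and not triple.phobius_call
        assert consensus_state(triple) is ConsensusState.DISCORDANT

    def test_score_consistent_with_call_under_noise(self, rng):
        seq = sample_signal_peptide(np.random.default_rng(0)) + "TDNSQEG" * 10
        for seed in range(40):
            triple = emulate_predictors(self._record(seq), (0.5, 0.2, 0.0),
                                        seed=seed)
            assert (triple.signalp_score > 0.5) == triple.signalp_call

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            emulate_predictors(self._record(""), (0, 0, 0), seed=0)


class TestDatasetDeterminism:
    def test_written_datasets_byte_identical(self, tmp_path):
        cfg = SimulationConfig(seed=3, n_species=15, n_families=8)
        digests = []
        for sub in ("a", "b"):
            out = tmp_path / sub
            write_dataset(simulate_dataset(cfg), out)
            h = hashlib.sha256()
            for p in sorted(out.rglob("*")):
                if p.is_file():
                    h.update(p.name.encode())
                    h.update(p.read_bytes())
            digests.append(h.hexdigest())
        assert digests[0] == digests[1]

    def test_roundtrip_preserves_cluster_content(self, tmp_path):
        cfg = SimulationConfig(seed=3, n_species=15, n_families=8)
        ds = simulate_dataset(cfg)
        write_dataset(ds, tmp_path / "ds")
        loaded = load_dataset(tmp_path / "ds")
        assert len(loaded.clusters) == len(ds.clusters)
        orig = {m.protein_id: m.sequence
                for c in ds.clusters for m in c.members}
        back = {m.protein_id: m.sequence
                for c in loaded.clusters for m in c.members}
        assert orig == back
        assert set(loaded.predictions) == set(ds.predictions)
        assert len(loaded.truth.families) == len(ds.truth.families)
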