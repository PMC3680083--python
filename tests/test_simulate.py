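import numpy as np
import pytest

from genefam.reconcile import reconcile
from genefam.simulate import (
    ANCESTRAL_INTRON_CDS_POSITIONS,
    ANCESTRAL_PHASES,
    SimulationConfig,
    simulate_ct_data,
    simulate_gene_family,
    simulate_species_tree,
    simulate_structure_evolution,
    simulate_tandem_loci,
)
from genefam.structure import CharacterState, EventType, encode_character_state


class TestSpeciesTree:
    def test_two_species_cherry(self):
        tree = simulate_species_tree(2, 0)
        assert sorted(tree.leaf_labels()) == ["S1", "S2"]
        assert len(tree.root.children) == 2

    def test_same_seed_same_newick(self):
        assert (
            simulate_species_tree(10, 7).to_newick()
            == simulate_species_tree(10, 7).to_newick()
        )

    def test_different_seed_changes_tree(self):
        assert (
            simulate_species_tree(10, 7).to_newick()
            != simulate_species_tree(10, 8).to_newick()
        )

    def test_node_counts(self):
        tree = simulate_species_tree(50, 3)
        assert len(tree.leaves()) == 50
        assert len(tree.internal_nodes()) == 49

    def test_ultrametric_unit_depth(self):
        tree = simulate_species_tree(12, 5)
        for leaf in tree.leaves():
            depth = 0.0
            node = leaf
            while node.parent is not None:
                depth += node.length
                node = node.parent
            assert depth == pytest.approx(1.0, abs=1e-9)

    def test_too_few_species_rejected(self):
        with pytest.raises(ValueError):
            simulate_species_tree(1, 0)


class TestGeneFamily:
    def test_no_events_gives_congruent_tree(self):
        species = simulate_species_tree(8, 1)
        genes, truth = simulate_gene_family(species, 0.0, 0.0, seed=2)
        assert truth.n_duplications == truth.n_losses == 0
        renamed = genes.copy()
        for leaf in renamed.leaves():
            leaf.label = leaf.label.rsplit("_", 1)[0]
        assert renamed.same_topology(species)

    @pytest.mark.parametrize("seed", range(20))
    def test_lossfree_duplications_recovered_by_reconciliation(self, seed):
        """With no losses, every simulated duplication survives and LCA
        reconciliation counts them exactly."""
        species = simulate_species_tree(8, seed)
        genes, truth = simulate_gene_family(species, 0.5, 0.0, seed=seed + 100)
        result = reconcile(genes, species)
        assert result.n_duplications == truth.n_duplications
        assert result.n_losses == 0

    def test_event_log_consistent_with_counts(self):
        species = simulate_species_tree(10, 11)
        genes, truth = simulate_gene_family(species, 0.6, 0.4, seed=12)
        assert truth.n_duplications == sum(
            1 for e in truth.events if e["type"] == "duplication"
        )
        assert truth.n_losses == sum(1 for e in truth.events if e["type"] == "loss")

    def test_determinism(self):
        species = simulate_species_tree(8, 1)
        a, _ = simulate_gene_family(species, 0.4, 0.2, seed=5)
        b, _ = simulate_gene_family(species, 0.4, 0.2, seed=5)
        assert a.to_newick() == b.to_newick()


class TestStructureEvolution:
    def test_rate_zero_keeps_ancestral_state_everywhere(self):
        tree = simulate_species_tree(10, 3)
        sim = simulate_structure_evolution(tree, 0.0, 0.0, 0.0, seed=4)
        for code in sim.leaf_codes.values():
            assert encode_character_state(code) is CharacterState.FULL_14_EXON

    def test_leaf_state_equals_events_applied_along_path(self):
        """Conservation along lineages: every leaf structure is the
        ancestor transformed by exactly the events on its path."""
        tree = simulate_species_tree(12, 13)
        sim = simulate_structure_evolution(tree, 1.2, 0.4, 0.5, seed=14)
        for leaf in sim.gene_tree.leaves():
            present = [True] * 13
            gained = False
            node = leaf
            events = []
            while node.parent is not None:
                events.extend(sim.branch_events.get(node, []))
                node = node.parent
            for event in events:
                if event.event_type is EventType.TYPE3:
                    gained = True
                else:
                    for k in event.intron_indices:
                        assert present[k - 1], "event hit an already-lost intron"
                        present[k - 1] = False
            truth = sim.leaf_codes[leaf.label]
            assert tuple(present) == truth.ancestral_intron_present
            assert gained == truth.novel_exon2_intron
            n_loss = sum(len(e.intron_indices) for e in events if e.event_type is not EventType.TYPE3)
            assert truth.intron_count == 13 - n_loss + int(gained)

    def test_intron_floor_respected(self):
        tree = simulate_species_tree(10, 23)
        sim = simulate_structure_evolution(tree, 5.0, 2.0, 0.0, seed=24)
        for code in sim.leaf_codes.values():
            assert code.intron_count >= 7

    def test_gains_confined_to_gain_clade(self):
        tree = simulate_species_tree(12, 33)
        sim = simulate_structure_evolution(tree, 0.0, 0.0, 5.0, seed=34)
        gained = {l for l, c in sim.leaf_codes.items() if c.novel_exon2_intron}
        assert gained  # high rate: the clade should acquire the intron
        assert gained <= sim.gain_clade_leaves

    def test_reference_layout_matches_declared_positions(self):
        from genefam.structure import compute_intron_profile

        profile = compute_intron_profile(
            simulate_structure_evolution(
                simulate_species_tree(2, 1), 0, 0, 0, seed=1
            ).reference_model
        )
        assert tuple(i.cds_position for i in profile.introns) == ANCESTRAL_INTRON_CDS_POSITIONS
        assert profile.phases == ANCESTRAL_PHASES

    def test_determinism(self):
        tree = simulate_species_tree(8, 2)
        a = simulate_structure_evolution(tree, 0.5, 0.1, 0.1, seed=6)
        b = simulate_structure_evolution(tree, 0.5, 0.1, 0.1, seed=6)
        assert a.leaf_codes == b.leaf_codes
        assert str(a.alignment[0].seq) == str(b.alignment[0].seq)


class TestCtSimulation:
    def test_noise_free_folds_exact(self):
        data = simulate_ct_data({"control": 1.0, "a": 2.0, "b": 0.25}, 0.0, seed=1)
        from genefam.qpcr import ddct

        rows = {r.sample: r.fold_change for r in ddct(data, "GeneX")}
        assert rows["control"] == 1.0
        assert rows["a"] == pytest.approx(2.0, rel=1e-12)
        assert rows["b"] == pytest.approx(0.25, rel=1e-12)

    def test_noisy_mean_fold_unbiased(self):
        from genefam.qpcr import ddct

        estimates = []
        for seed in range(500):
            data = simulate_ct_data({"control": 1.0, "salt": 6.0}, 0.15, seed=seed)
            estimates.append(
                {r.sample: r.fold_change for r in ddct(data, "GeneX")}["salt"]
            )
        assert np.mean(estimates) == pytest.approx(6.0, rel=0.05)

    def test_triplicate_structure(self):
        data = simulate_ct_data({"control": 1.0, "x": 2.0}, 0.1, seed=2)
        counts = data.wells.groupby(["gene", "sample"]).size()
        assert (counts == 3).all()

    def test_calibrator_must_be_present(self):
        with pytest.raises(ValueError, match="calibrator"):
            simulate_ct_data({"salt": 6.0}, 0.1, seed=1)


class TestTandemLoci:
    def test_array_sizes_between_two_and_three(self):
        _, truth = simulate_tandem_loci(n_arrays=4, seed=5)
        assert all(2 <= len(a) <= 3 for a in truth)

    def test_determinism(self):
        a_loci, a_truth = simulate_tandem_loci(seed=6)
        b_loci, b_truth = simulate_tandem_loci(seed=6)
        assert a_loci == b_loci and a_truth == b_truth


class TestConfig:
    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(dup_rate=-1)
        with pytest.raises(ValueError):
            SimulationConfig(tandem_fraction=1.5)

    def test_defaults_are_valid(self):
        config = SimulationConfig()
        assert config.n_species == 28
        assert config.fold_changes["NaCl_4h"] >= 6.0
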