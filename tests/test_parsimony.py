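import numpy as np
import pytest

from genefam.parsimony import (
    CharacterMatrix,
    count_mprs,
    fitch_parsimony,
    reconstruct_structure_history,
)
from genefam.simulate import (
    simulate_species_tree,
    simulate_structure_evolution,
)
from genefam.structure import CharacterState, EventType, StructureCode
from genefam.trees import RootedTree
from oracles import enumerate_parsimony, random_binary_tree


def matrix(newick, **states):
    return CharacterMatrix(tree=RootedTree.from_newick(newick), states=states)


class TestFitch:
    def test_uniform_states_need_no_changes(self):
        m = matrix("((A,B),(C,D));", A="x", B="x", C="x", D="x")
        result = fitch_parsimony(m)
        assert result.parsimony_length == 0
        assert all(s == frozenset({"x"}) for s in result.node_state_sets.values())

    def test_one_deviant_leaf_costs_one_change(self):
        m = matrix("((A,B),(C,D));", A="a", B="b", C="b", D="b")
        result = fitch_parsimony(m)
        assert result.parsimony_length == 1
        root = m.tree.root
        assert result.node_state_sets[root] == frozenset({"b"})

    def test_leaf_without_state_rejected(self):
        with pytest.raises(ValueError, match="without a state"):
            matrix("((A,B),C);", A="a", B="b")

    def test_polytomy_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            fitch_parsimony(matrix("(A,B,C);", A="a", B="a", C="a"))

    def test_length_matches_exhaustive_enumeration(self, rng):
        """Fitch length equals the brute-force minimum on random trees."""
        states_pool = ["a", "b", "c", "d"]
        for _ in range(60):
            n = int(rng.integers(3, 8))
            tree = random_binary_tree([f"t{i}" for i in range(n)], rng)
            leaf_states = {
                f"t{i}": states_pool[int(rng.integers(len(states_pool)))]
                for i in range(n)
            }
            m = CharacterMatrix(tree=tree, states=leaf_states)
            expected, _, _ = enumerate_parsimony(tree, leaf_states, states_pool[:])
            space = m.state_space()
            expected_restricted, _, _ = enumerate_parsimony(tree, leaf_states, space)
            assert expected_restricted == expected  # unused states never help
            assert fitch_parsimony(m).parsimony_length == expected

    def test_length_depends_only_on_topology_and_states(self, rng):
        """Relabelling leaves together with their states leaves the
        parsimony length unchanged."""
        labels = [f"t{i}" for i in range(6)]
        states = dict(zip(labels, ["a", "a", "b", "c", "b", "a"]))
        tree = random_binary_tree(labels, rng)
        base = fitch_parsimony(CharacterMatrix(tree=tree, states=states)).parsimony_length
        for _ in range(10):
            remap = dict(zip(labels, rng.permutation(labels)))
            relabelled = tree.copy()
            for leaf in relabelled.leaves():
                leaf.label = remap[leaf.label]
            moved_states = {remap[l]: states[l] for l in labels}
            got = fitch_parsimony(
                CharacterMatrix(tree=relabelled, states=moved_states)
            ).parsimony_length
            assert got == base

    def test_length_invariant_under_rerooting(self, rng):
        from genefam.reconcile import _all_rootings

        labels = [f"t{i}" for i in range(7)]
        for _ in range(5):
            tree = random_binary_tree(labels, rng)
            states = {
                l: ["a", "b", "c"][int(rng.integers(3))] for l in labels
            }
            lengths = {
                fitch_parsimony(
                    CharacterMatrix(tree=rooted, states=states)
                ).parsimony_length
                for rooted in _all_rootings(tree)
            }
            assert len(lengths) == 1


class TestMprCounting:
    def test_cherry_resolves_unambiguously(self):
        m = matrix("((A,B),C);", A="a", B="b", C="a")
        rec = count_mprs(m)
        cherry = next(
            n for n in m.tree.internal_nodes()
            if sorted(l.label for l in n.leaves()) == ["A", "B"]
        )
        assert rec.node_state_frequencies[cherry] == {"a": 1.0}

    def test_uniform_tree_has_single_mpr(self):
        rec = count_mprs(matrix("((A,B),(C,D));", A="x", B="x", C="x", D="x"))
        assert rec.mpr_count == 1

    def test_frequencies_match_exhaustive_enumeration(self, rng):
        """Per-node MPR state frequencies equal brute-force counts exactly."""
        states_pool = ["a", "b", "c"]
        for _ in range(40):
            n = int(rng.integers(3, 7))
            tree = random_binary_tree([f"t{i}" for i in range(n)], rng)
            leaf_states = {
                f"t{i}": states_pool[int(rng.integers(len(states_pool)))]
                for i in range(n)
            }
            m = CharacterMatrix(tree=tree, states=leaf_states)
            rec = count_mprs(m)
            space = m.state_space()
            length, total, counts = enumerate_parsimony(tree, leaf_states, space)
            assert rec.parsimony_length == length
            assert rec.mpr_count == total
            for node, per_state in counts.items():
                got = rec.node_state_frequencies[node]
                want = {s: c / total for s, c in per_state.items()}
                assert got.keys() == want.keys()
                for state in want:
                    assert got[state] == pytest.approx(want[state], abs=1e-12)

    def test_frequencies_sum_to_one(self, rng):
        tree = random_binary_tree([f"t{i}" for i in range(9)], rng)
        leaf_states = {f"t{i}": "ab"[int(rng.integers(2))] for i in range(9)}
        rec = count_mprs(CharacterMatrix(tree=tree, states=leaf_states))
        assert rec.mpr_count >= 1
        for node, freqs in rec.node_state_frequencies.items():
            assert sum(freqs.values()) == pytest.approx(1.0, abs=1e-12)
            assert set(freqs) == rec.node_state_sets[node]

    def test_ambiguous_leaf_counts_as_missing(self):
        m = CharacterMatrix(
            tree=RootedTree.from_newick("((A,B),C);"),
            states={"A": "a", "B": frozenset({"a", "b"}), "C": "a"},
        )
        rec = count_mprs(m)
        assert rec.parsimony_length == 0
        assert rec.node_state_frequencies[m.tree.root] == {"a": 1.0}


class TestStructureHistory:
    def _codes(self, states):
        from genefam.structure import state_to_code

        return [state_to_code(CharacterState(s), gene_id=g) for g, s in states.items()]

    def test_two_identical_leaves_no_events(self):
        tree = RootedTree.from_newick("(g1,g2);")
        history = reconstruct_structure_history(self._codes({"g1": "a", "g2": "a"}), tree)
        assert history.branch_events == []
        assert history.node_states[tree.root] is CharacterState.FULL_14_EXON

    def test_single_loss_localised_to_one_branch(self):
        tree = RootedTree.from_newick("((g1,g2),(g3,g4));")
        history = reconstruct_structure_history(
            self._codes({"g1": "b", "g2": "b", "g3": "a", "g4": "a"}), tree
        )
        assert len(history.branch_events) == 1
        be = history.branch_events[0]
        assert sorted(l.label for l in be.node.leaves()) == ["g1", "g2"]
        assert [e.event_type for e in be.events] == [EventType.TYPE1]
        assert be.events[0].intron_indices == (1,)

    def test_simulated_history_recovers_root_state(self):
        tree = simulate_species_tree(20, 41)
        sim = simulate_structure_evolution(tree, 0.25, 0.05, 0.05, seed=42)
        history = reconstruct_structure_history(list(sim.leaf_codes.values()), tree)
        assert history.node_states[tree.root] is CharacterState.FULL_14_EXON

    def test_unknown_as_missing_drops_unknown_state(self):
        tree = RootedTree.from_newick("((g1,g2),g3);")
        codes = self._codes({"g1": "a", "g2": "a"})
        codes.append(StructureCode("g3", (True,) * 13, unresolved=True))
        history = reconstruct_structure_history(codes, tree, unknown_as_missing=True)
        assert history.reconstruction.parsimony_length == 0
        assert history.node_states[tree.root] is CharacterState.FULL_14_EXON
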