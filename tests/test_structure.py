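import numpy as np
import pytest
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from genefam.io import GeneModel
from genefam.simulate import (
    ANCESTRAL_PHASES,
    N_ANCESTRAL_INTRONS,
    ancestral_gene_model,
    simulate_species_tree,
    simulate_structure_evolution,
    _build_gene_model,
)
from genefam.structure import (
    CharacterState,
    EventType,
    StructureCode,
    StructureEvent,
    classify_events,
    compute_intron_profile,
    encode_character_state,
    project_introns,
    state_to_code,
)


def model_from_coding_lengths(lengths, gene_id="g", intron_bp=100):
    exons = []
    cursor = 0
    for length in lengths:
        exons.append((cursor, cursor + length))
        cursor += length + intron_bp
    return GeneModel(gene_id, "chr1", "+", tuple(exons))


def code(present_missing=(), novel=False, gene_id="g"):
    present = [k not in present_missing for k in range(1, N_ANCESTRAL_INTRONS + 1)]
    return StructureCode(gene_id, tuple(present), novel_exon2_intron=novel)


class TestIntronProfile:
    def test_phase0_after_complete_codon(self):
        profile = compute_intron_profile(model_from_coding_lengths([9, 12]))
        assert [(i.cds_position, i.phase) for i in profile.introns] == [(9, 0)]

    def test_phase1_after_first_nucleotide(self):
        profile = compute_intron_profile(model_from_coding_lengths([10, 11]))
        assert [(i.cds_position, i.phase) for i in profile.introns] == [(10, 1)]

    def test_phase2_after_second_nucleotide(self):
        profile = compute_intron_profile(model_from_coding_lengths([11, 10]))
        assert profile.introns[0].phase == 2

    def test_single_exon_gene_has_no_introns(self):
        profile = compute_intron_profile(model_from_coding_lengths([300]))
        assert profile.introns == ()

    def test_noncoding_length_warns(self):
        with pytest.warns(UserWarning, match="divisible by 3"):
            compute_intron_profile(model_from_coding_lengths([10, 10]))

    def test_phase_identity_on_simulated_genes(self):
        """phase == cds_position mod 3 for every intron of every gene."""
        tree = simulate_species_tree(10, 5)
        sim = simulate_structure_evolution(tree, 0.8, 0.3, 0.3, seed=6)
        for model in sim.leaf_models.values():
            profile = compute_intron_profile(model)
            for intron in profile.introns:
                assert intron.phase == intron.cds_position % 3


class TestProjection:
    @pytest.fixture
    def reference(self):
        model = ancestral_gene_model()
        return model, compute_intron_profile(model)

    def _alignment(self, *ids, length=784):
        seq = "M" * length
        return MultipleSeqAlignment(
            [SeqRecord(Seq(seq), id=i, description="") for i in ids]
        )

    def test_reference_projects_onto_itself(self, reference):
        model, profile = reference
        aln = self._alignment("ancestor")
        result = project_introns(profile, aln, profile)
        assert all(result.ancestral_intron_present)
        assert not result.novel_exon2_intron and not result.unresolved

    def test_known_deletions_recovered(self, reference):
        _, ref_profile = reference
        lost = _build_gene_model("d", [k not in (1, 6) for k in range(1, 14)], False, [])
        profile = compute_intron_profile(lost)
        aln = self._alignment("ancestor", "d")
        result = project_introns(profile, aln, ref_profile)
        assert result.lost_introns == (1, 6)
        assert not result.novel_exon2_intron and not result.unresolved

    def test_novel_exon2_intron_detected(self, reference):
        _, ref_profile = reference
        gained = _build_gene_model("n", [True] * 13, True, [])
        profile = compute_intron_profile(gained)
        aln = self._alignment("ancestor", "n")
        result = project_introns(profile, aln, ref_profile)
        assert result.novel_exon2_intron
        assert all(result.ancestral_intron_present)

    def test_gene_absent_from_alignment(self, reference):
        _, ref_profile = reference
        aln = self._alignment("ancestor")
        profile = compute_intron_profile(_build_gene_model("x", [True] * 13, False, []))
        with pytest.raises(KeyError):
            project_introns(profile, aln, ref_profile)

    def test_invariant_to_all_gap_columns(self, reference):
        _, ref_profile = reference
        lost = _build_gene_model("d", [k != 5 for k in range(1, 14)], False, [])
        profile = compute_intron_profile(lost)
        seq = "M" * 784
        gapped = seq[:100] + "-" * 7 + seq[100:]
        plain = MultipleSeqAlignment(
            [SeqRecord(Seq(seq), id=i, description="") for i in ("ancestor", "d")]
        )
        padded = MultipleSeqAlignment(
            [SeqRecord(Seq(gapped), id=i, description="") for i in ("ancestor", "d")]
        )
        assert project_introns(profile, plain, ref_profile) == project_introns(
            profile, padded, ref_profile
        )

    def test_gapped_alignment_from_indel_mode(self):
        """Per-leaf coding insertions do not disturb the projection."""
        tree = simulate_species_tree(8, 9)
        sim = simulate_structure_evolution(tree, 0.5, 0.1, 0.2, seed=10, indel_rate=1.0)
        assert sim.alignment.get_alignment_length() > 784  # gaps present
        for label, model in sim.leaf_models.items():
            result = project_introns(
                compute_intron_profile(model), sim.alignment, sim.reference_profile
            )
            assert result == sim.leaf_codes[label]


class TestClassifyEvents:
    def test_single_loss_is_type1(self):
        assert classify_events(code({1})) == [StructureEvent(EventType.TYPE1, (1,))]

    def test_adjacent_pair_is_type2(self):
        assert classify_events(code({3, 4})) == [StructureEvent(EventType.TYPE2, (3, 4))]

    def test_two_isolated_losses_plus_gain(self):
        events = classify_events(code({1, 5}, novel=True))
        assert events == [
            StructureEvent(EventType.TYPE1, (1,)),
            StructureEvent(EventType.TYPE1, (5,)),
            StructureEvent(EventType.TYPE3, (2,)),
        ]

    def test_long_run_decomposed_greedily_with_warning(self):
        with pytest.warns(UserWarning, match="consecutive"):
            events = classify_events(code({6, 7, 8}))
        assert events == [
            StructureEvent(EventType.TYPE2, (6, 7)),
            StructureEvent(EventType.TYPE1, (8,)),
        ]

    def test_unresolved_rejected(self):
        unresolved = StructureCode("g", (True,) * 13, unresolved=True)
        with pytest.raises(ValueError):
            classify_events(unresolved)

    def test_decomposition_is_minimal(self, rng):
        """Greedy pairing gives the fewest events explaining any loss set
        (oracle: per-run minimum is ceil(run/2), found by enumeration)."""
        for _ in range(200):
            lost = set(
                int(k) for k in rng.choice(13, size=rng.integers(0, 9), replace=False) + 1
            )
            with pytest.warns() if _has_long_run(lost) else _nullcontext():
                events = classify_events(code(lost))
            assert sum(len(e.intron_indices) for e in events) == len(lost)
            assert len(events) == _min_events(lost)


def _has_long_run(lost):
    run = 0
    for k in range(1, 15):
        run = run + 1 if k in lost else 0
        if run > 2:
            return True
    return False


def _nullcontext():
    import contextlib

    return contextlib.nullcontext()


def _min_events(lost):
    # minimum events: each event removes 1 intron or 2 adjacent introns
    total = 0
    run = 0
    for k in range(1, 15):
        if k in lost:
            run += 1
        else:
            total += (run + 1) // 2
            run = 0
    return total


class TestCharacterState:
    def test_full_structure_is_a(self):
        assert encode_character_state(code()) is CharacterState.FULL_14_EXON

    def test_intronless_is_o(self):
        assert encode_character_state(code(set(range(1, 14)))) is CharacterState.INTRONLESS

    def test_gain_only_is_p(self):
        assert encode_character_state(code(novel=True)) is CharacterState.EXON2_INSERTION

    @pytest.mark.parametrize("k,letter", [(1, "b"), (2, "c"), (7, "h"), (13, "n")])
    def test_single_losses_map_to_b_through_n(self, k, letter):
        assert encode_character_state(code({k})).value == letter

    def test_nonadjacent_double_loss_is_unknown(self):
        """No state in the 19-letter vocabulary covers losses {2, 7}."""
        assert encode_character_state(code({2, 7})) is CharacterState.UNKNOWN

    def test_gain_plus_loss_is_unknown(self):
        assert encode_character_state(code({3}, novel=True)) is CharacterState.UNKNOWN

    def test_unresolved_is_unknown(self):
        unresolved = StructureCode("g", (True,) * 13, unresolved=True)
        assert encode_character_state(unresolved) is CharacterState.UNKNOWN

    def test_state_to_code_inverts_encoding(self):
        for state in CharacterState:
            decoded = state_to_code(state)
            if decoded is not None:
                assert encode_character_state(decoded) is state
            else:
                assert state in (
                    CharacterState.ANIMAL_14_INTRON,
                    CharacterState.ANIMAL_15_INTRON,
                    CharacterState.UNKNOWN,
                )


class TestStructureInvariants:
    def test_intron_count_conservation(self):
        tree = simulate_species_tree(12, 21)
        sim = simulate_structure_evolution(tree, 0.9, 0.3, 0.3, seed=22)
        for label, model in sim.leaf_models.items():
            profile = compute_intron_profile(model)
            assert sim.leaf_codes[label].intron_count == len(profile.introns)

    def test_surviving_intron_phases_conserved(self):
        """Losses never alter the phases of the introns that survive."""
        tree = simulate_species_tree(12, 31)
        sim = simulate_structure_evolution(tree, 1.0, 0.3, 0.4, seed=32)
        for label, model in sim.leaf_models.items():
            truth = sim.leaf_codes[label]
            expected = [
                ANCESTRAL_PHASES[k - 1]
                for k, present in enumerate(truth.ancestral_intron_present, start=1)
                if present
            ]
            if truth.novel_exon2_intron:
                # the novel intron (phase 0) sits between ancestral introns 1 and 2
                idx = 1 if truth.ancestral_intron_present[0] else 0
                expected.insert(idx, 0)
            assert list(compute_intron_profile(model).phases) == expected
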