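"""Maximum-parsimony ancestral states with MPR pie-chart frequencies.

A five-leaf family in which one clade lost intron 1 (state 'b') while the
rest keep the full structure (state 'a').  The reconstruction reports, per
internal node, the fraction of most-parsimonious reconstructions assigning
each state, and labels the branch where the loss happened.
"""

from genefam.parsimony import CharacterMatrix, count_mprs, reconstruct_structure_history
from genefam.structure import CharacterState, state_to_code
from genefam.trees import RootedTree

tree = RootedTree.from_newick("(((g1,g2),g3),(g4,g5));")
leaf_states = {"g1": "b", "g2": "b", "g3": "a", "g4": "a", "g5": "a"}

matrix = CharacterMatrix(
    tree=tree, states={g: CharacterState(s) for g, s in leaf_states.items()}
)
rec = count_mprs(matrix)
print(f"parsimony length: {rec.parsimony_length} change(s); {rec.mpr_count} MPR(s)")
for node, freqs in rec.node_state_frequencies.items():
    clade = ",".join(sorted(l.label for l in node.leaves()))
    shares = {s.value: round(f, 3) for s, f in freqs.items()}
    print(f"  node ({clade}): {shares}")

codes = [state_to_code(CharacterState(s), gene_id=g) for g, s in leaf_states.items()]
history = reconstruct_structure_history(codes, tree)
print(f"root state: '{history.node_states[tree.root].value}' (14-exon ancestor)")
for be in history.branch_events:
    clade = ",".join(sorted(l.label for l in be.node.leaves()))
    print(
        f"branch above ({clade}): {be.parent_state.value} -> {be.child_state.value}, "
        f"events {[f'{e.event_type.value}{e.intron_indices}' for e in be.events]}"
    )
# A frequency of 1.0 means every most-parsimonious reconstruction agrees
# on that node's state (a "solid" pie chart).
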