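"""Gene-tree/species-tree reconciliation and the weighted D/L score.

A family duplicated before the A/B speciation leaves two gene copies per
species; LCA reconciliation finds the duplication, and the D/L score
weights duplications 1.5 and losses 1.0 (so the classic 90-duplication,
29-loss family scores 164).
"""

from genefam.reconcile import dl_score, reconcile
from genefam.trees import RootedTree

species = RootedTree.from_newick("((A,B),C);")
genes = RootedTree.from_newick("(((a1,b1),(a2,b2)),c1);")
leaf_map = {"a1": "A", "b1": "B", "a2": "A", "b2": "B", "c1": "C"}

result = reconcile(genes, species, leaf_map)
print(f"duplications D = {result.n_duplications}")
print(f"losses       L = {result.n_losses}")
print(f"D/L score      = {result.dl_score}  (= 1.5*D + 1.0*L)")
for node, count in result.per_branch_losses.items():
    print(f"  loss on species branch above {node.label}: {count}")

print(f"\nworked example: dl_score(90, 29) = {dl_score(90, 29)}")
# The clade ((a1,b1),(a2,b2)) maps to the A/B ancestor together with both
# of its children, so its root is the single duplication; no species-tree
# edges are skipped, so there are no losses.
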