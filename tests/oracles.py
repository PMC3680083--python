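"""Independent brute-force oracles used by the test suite.

These enumerate search spaces exhaustively and deliberately share no code
with the implementations they check.
"""

from __future__ import annotations

import itertools

import numpy as np

from genefam.trees import RootedTree, TreeNode


def random_binary_tree(labels, rng: np.random.Generator) -> RootedTree:
    """Random rooted binary topology by repeatedly joining two subtrees."""
    nodes = [TreeNode(label=l) for l in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = TreeNode()
        parent.add_child(a)
        parent.add_child(b)
        nodes.append(parent)
    return RootedTree(nodes[0])


def enumerate_parsimony(tree: RootedTree, leaf_states: dict, space):
    """Exhaustive minimum-change reconstruction of one character.

    ``leaf_states`` maps leaf label -> state or set of states.  Returns
    (min_length, mpr_count, per-internal-node {state: count of MPRs}).
    """
    space = list(space)
    internal = [n for n in tree.postorder() if not n.is_leaf]
    free_leaves = []
    fixed = {}
    for leaf in tree.leaves():
        value = leaf_states[leaf.label]
        allowed = value if isinstance(value, (set, frozenset)) else {value}
        if len(allowed) == 1:
            fixed[leaf] = next(iter(allowed))
        else:
            free_leaves.append((leaf, sorted(allowed, key=str)))
    variables = internal + [leaf for leaf, _ in free_leaves]
    domains = [space] * len(internal) + [allowed for _, allowed in free_leaves]

    best = None
    counts: dict = {}
    mpr_count = 0
    for assignment in itertools.product(*domains):
        state = dict(fixed)
        state.update(zip(variables, assignment))
        changes = sum(
            1
            for node in tree.postorder()
            if node.parent is not None and state[node] != state[node.parent]
        )
        if best is None or changes < best:
            best = changes
            counts = {n: {} for n in internal}
            mpr_count = 0
        if changes == best:
            mpr_count += 1
            for node in internal:
                counts[node][state[node]] = counts[node].get(state[node], 0) + 1
    return best, mpr_count, counts


def enumerate_reconciliation(gene_tree: RootedTree, species_tree: RootedTree, leaf_map: dict):
    """Minimum duplications and losses over all valid embeddings.

    A valid map sends each internal gene node to a species node that is an
    ancestor-or-equal of all its children's images.  For a given map, a
    node is a duplication when it shares its image with a child; each gene
    edge whose images are d species edges apart contributes d-1 losses
    below a speciation and d below a duplication.  Returns
    (min_D, min_L, min_{D+L} as a (D, L) pair).
    """
    ancestors: dict[TreeNode, set] = {}
    depth: dict[TreeNode, int] = {}
    for node in species_tree.preorder():
        if node.parent is None:
            ancestors[node] = {node}
            depth[node] = 0
        else:
            ancestors[node] = ancestors[node.parent] | {node}
            depth[node] = depth[node.parent] + 1
    species_nodes = list(species_tree.postorder())
    species_leaf = {l.label: l for l in species_tree.leaves()}

    internal = [n for n in gene_tree.postorder() if not n.is_leaf]
    fixed = {leaf: species_leaf[leaf_map[leaf.label]] for leaf in gene_tree.leaves()}

    best_d = best_l = best_sum = None
    best_pair = None
    for assignment in itertools.product(species_nodes, repeat=len(internal)):
        image = dict(fixed)
        image.update(zip(internal, assignment))
        valid = all(
            image[node] in ancestors[image[child]]
            for node in internal
            for child in node.children
        )
        if not valid:
            continue
        # a node is a speciation only when its children's images descend
        # into two *different* child subtrees of the node's own image;
        # anything else (shared image, or both on one side) is a duplication
        def subtree_index(parent_image, child_image):
            if child_image is parent_image:
                return None
            for i, sp_child in enumerate(parent_image.children):
                if sp_child in ancestors[child_image]:
                    return i
            return None

        dups = set()
        for node in internal:
            sides = [subtree_index(image[node], image[c]) for c in node.children]
            if None in sides or len(set(sides)) < len(sides):
                dups.add(node)
        losses = 0
        for node in gene_tree.postorder():
            if node.parent is None:
                continue
            d = depth[image[node]] - depth[image[node.parent]]
            losses += d - 1 + (1 if node.parent in dups else 0) if d > 0 else 0
        n_dup = len(dups)
        if best_d is None or n_dup < best_d:
            best_d = n_dup
        if best_l is None or losses < best_l:
            best_l = losses
        if best_sum is None or n_dup + losses < best_sum:
            best_sum = n_dup + losses
            best_pair = (n_dup, losses)
    return best_d, best_l, best_pair
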