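"""Gene-tree / species-tree reconciliation by LCA mapping.

Each gene-tree node is mapped to the last common ancestor, in the species
tree, of the species carrying its descendant genes.  A gene node is a
*duplication* when it maps to the same species node as at least one of its
children; every other internal node is a speciation.  Losses are counted
per gene-tree edge from the species-tree path skipped between the parent's
and the child's images: an edge whose images are k species-tree edges
apart implies k-1 losses below a speciation and k below a duplication
(the duplicated lineage must additionally pass its own species split).
This LCA reconciliation minimises both the duplication and the loss count
over all valid embeddings.

The summary statistic is the weighted duplication/loss score
``D/L = w_dup * D + w_loss * L`` with default weights 1.5 and 1.0.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Optional

from .trees import RootedTree, TreeNode, resolve_polytomies

__all__ = [
    "ReconciliationResult",
    "lca_map",
    "reconcile",
    "dl_score",
    "resolve_polytomies",
    "species_from_gene_id",
    "infer_leaf_map",
    "min_score_rooting",
]

DEFAULT_DUP_WEIGHT = 1.5
DEFAULT_LOSS_WEIGHT = 1.0

#: species label = prefix of the gene label before the first digit
DEFAULT_SPECIES_PATTERN = r"^([^\d]+)"


@dataclass
class ReconciliationResult:
    duplication_nodes: set
    n_duplications: int
    n_losses: int
    dl_score: float
    per_branch_losses: dict  # species TreeNode -> losses on the branch above it
    node_map: dict  # gene TreeNode -> species TreeNode

    def duplication_labels(self) -> list[str]:
        labels = []
        for node in self.duplication_nodes:
            labels.append("{" + ",".join(sorted(l.label for l in node.leaves())) + "}")
        return sorted(labels)


def species_from_gene_id(gene_id: str, pattern: str = DEFAULT_SPECIES_PATTERN) -> str:
    """Extract the species label from a gene label (default: everything
    before the first digit, matching prefixes like Gma/Ath/Osa)."""
    match = re.match(pattern, gene_id)
    if not match or not match.group(1):
        raise ValueError(f"cannot extract species from gene id {gene_id!r}")
    return match.group(1).rstrip("_")


def infer_leaf_map(
    gene_tree: RootedTree,
    species_tree: RootedTree,
    pattern: str = DEFAULT_SPECIES_PATTERN,
) -> dict[str, str]:
    mapping = {}
    species = set(species_tree.leaf_labels())
    for label in gene_tree.leaf_labels():
        candidates = [species_from_gene_id(label, pattern)]
        if "_" in label:
            candidates.append(label.rsplit("_", 1)[0])  # <species>_<copy> style
        sp = next((c for c in candidates if c in species), None)
        if sp is None:
            raise ValueError(
                f"species {candidates[0]!r} (from gene {label!r}) not in species tree"
            )
        mapping[label] = sp
    return mapping


def _validate_leaf_map(gene_tree, species_tree, leaf_map) -> None:
    species = set(species_tree.leaf_labels())
    for label in gene_tree.leaf_labels():
        if label not in leaf_map:
            raise ValueError(f"gene leaf {label!r} has no species mapping")
        if leaf_map[label] not in species:
            raise ValueError(
                f"species {leaf_map[label]!r} (gene {label!r}) absent from species tree"
            )


def lca_map(
    gene_tree: RootedTree,
    species_tree: RootedTree,
    leaf_map: Mapping[str, str],
) -> dict[TreeNode, TreeNode]:
    """Map every gene-tree node to the species-tree LCA of its species set."""
    _validate_leaf_map(gene_tree, species_tree, leaf_map)
    depth: dict[TreeNode, int] = {}
    for node in species_tree.preorder():
        depth[node] = 0 if node.parent is None else depth[node.parent] + 1
    species_leaf = {leaf.label: leaf for leaf in species_tree.leaves()}

    def lca(a: TreeNode, b: TreeNode) -> TreeNode:
        while depth[a] > depth[b]:
            a = a.parent
        while depth[b] > depth[a]:
            b = b.parent
        while a is not b:
            a, b = a.parent, b.parent
        return a

    mapping: dict[TreeNode, TreeNode] = {}
    for node in gene_tree.postorder():
        if node.is_leaf:
            mapping[node] = species_leaf[leaf_map[node.label]]
        else:
            image = mapping[node.children[0]]
            for child in node.children[1:]:
                image = lca(image, mapping[child])
            mapping[node] = image
    return mapping


def reconcile(
    gene_tree: RootedTree,
    species_tree: RootedTree,
    leaf_map: Optional[Mapping[str, str]] = None,
    w_dup: float = DEFAULT_DUP_WEIGHT,
    w_loss: float = DEFAULT_LOSS_WEIGHT,
) -> ReconciliationResult:
    """Reconcile a rooted binary gene tree with a rooted binary species
    tree, counting duplications, losses and the weighted D/L score.

    When ``leaf_map`` is omitted, species labels are extracted from gene
    labels by :func:`species_from_gene_id`.
    """
    if not gene_tree.is_binary or not species_tree.is_binary:
        raise ValueError("both trees must be binary (see resolve_polytomies)")
    if leaf_map is None:
        leaf_map = infer_leaf_map(gene_tree, species_tree)
    mapping = lca_map(gene_tree, species_tree, leaf_map)

    depth: dict[TreeNode, int] = {}
    for node in species_tree.preorder():
        depth[node] = 0 if node.parent is None else depth[node.parent] + 1

    duplications = {
        node
        for node in gene_tree.internal_nodes()
        if any(mapping[child] is mapping[node] for child in node.children)
    }

    per_branch_losses: dict[TreeNode, int] = {}
    n_losses = 0
    for node in gene_tree.postorder():
        if node.parent is None:
            continue
        top = mapping[node.parent]
        bottom = mapping[node]
        path = [bottom]  # species path bottom -> ... -> top, inclusive
        while path[-1] is not top:
            path.append(path[-1].parent)
        # Species splits the lineage passes through: the interior nodes of
        # the path always; `top` itself additionally when the parent gene
        # node is a duplication (the duplicated copy starts inside top's
        # branch and must still cross its split).  At each passed split the
        # sibling branch off the path is a loss.
        last = len(path) if node.parent in duplications else len(path) - 1
        for i in range(1, last):
            split = path[i]
            survivor = path[i - 1]
            for child in split.children:
                if child is not survivor:
                    per_branch_losses[child] = per_branch_losses.get(child, 0) + 1
                    n_losses += 1

    n_dup = len(duplications)
    return ReconciliationResult(
        duplication_nodes=duplications,
        n_duplications=n_dup,
        n_losses=n_losses,
        dl_score=dl_score(n_dup, n_losses, w_dup, w_loss),
        per_branch_losses=per_branch_losses,
        node_map=mapping,
    )


def dl_score(
    n_dup: int,
    n_loss: int,
    w_dup: float = DEFAULT_DUP_WEIGHT,
    w_loss: float = DEFAULT_LOSS_WEIGHT,
) -> float:
    """Weighted duplication/loss score ``w_dup * D + w_loss * L``."""
    if n_dup < 0 or n_loss < 0:
        raise ValueError("event counts must be non-negative")
    if w_dup < 0 or w_loss < 0:
        raise ValueError("weights must be non-negative")
    return w_dup * n_dup + w_loss * n_loss


def min_score_rooting(
    unrooted_like: RootedTree,
    species_tree: RootedTree,
    leaf_map: Optional[Mapping[str, str]] = None,
    w_dup: float = DEFAULT_DUP_WEIGHT,
    w_loss: float = DEFAULT_LOSS_WEIGHT,
) -> tuple[RootedTree, ReconciliationResult]:
    """Scan all rootings of a gene tree and return the one minimising the
    D/L score (ties broken by the first edge in a deterministic postorder
    edge enumeration of the input tree)."""
    best = None
    for candidate in _all_rootings(unrooted_like):
        if leaf_map is None:
            lm = infer_leaf_map(candidate, species_tree)
        else:
            lm = leaf_map
        result = reconcile(candidate, species_tree, lm, w_dup=w_dup, w_loss=w_loss)
        if best is None or result.dl_score < best[1].dl_score:
            best = (candidate, result)
    assert best is not None
    return best


def _all_rootings(tree: RootedTree):
    """Yield the tree rooted on every edge of its unrooted version, in a
    deterministic (postorder-derived) edge order."""
    base = tree.copy()
    adj: dict[TreeNode, list[TreeNode]] = {}
    for node in base.postorder():
        adj.setdefault(node, [])
        for child in node.children:
            adj[node].append(child)
            adj.setdefault(child, []).append(node)
    root = base.root
    if len(root.children) == 2:
        # binary rooted tree: the root is a virtual node on one edge
        a, b = root.children
        adj[a] = [n for n in adj[a] if n is not root] + [b]
        adj[b] = [n for n in adj[b] if n is not root] + [a]
        del adj[root]
    edges = []
    seen = set()
    for node in base.postorder():
        if node not in adj:
            continue
        for nb in adj[node]:
            key = frozenset((id(node), id(nb)))
            if key not in seen:
                seen.add(key)
                edges.append((node, nb))
    for u, v in edges:
        new_root = TreeNode()
        new_root.add_child(_orient(u, v, adj))
        new_root.add_child(_orient(v, u, adj))
        yield RootedTree(new_root)


def _orient(node: TreeNode, came_from: TreeNode, adj) -> TreeNode:
    neighbours = [n for n in adj[node] if n is not came_from]
    fresh = TreeNode(label=node.label if not neighbours else None)
    for nb in neighbours:
        fresh.add_child(_orient(nb, node, adj))
    return fresh
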