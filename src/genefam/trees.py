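"""Rooted-tree container and Newick I/O.

The tree classes here are deliberately small: a node with parent/children
links, an optional label and an optional branch length.  Newick parsing and
serialisation are delegated to :mod:`dendropy` at the boundary; the rest of
the package manipulates :class:`RootedTree` objects directly, which keeps
the parsimony, reconciliation and simulation code free of taxon-namespace
bookkeeping.

Conventions
-----------
* Trees are always rooted.  A basal trifurcation in a Newick string is kept
  as a root polytomy (see :func:`resolve_polytomies`).
* Leaf labels must be unique; duplicate labels raise
  :class:`TreeValidationError`.
* Branch lengths are optional and non-negative when present.
"""

from __future__ import annotations

import io
from typing import Callable, Iterator, Optional

import dendropy

__all__ = [
    "TreeNode",
    "RootedTree",
    "TreeParseError",
    "TreeValidationError",
    "resolve_polytomies",
]


class TreeParseError(ValueError):
    """Raised when a Newick string cannot be parsed."""


class TreeValidationError(ValueError):
    """Raised when a parsed tree violates a structural invariant."""


class TreeNode:
    """One node of a rooted tree."""

    __slots__ = ("label", "length", "parent", "children")

    def __init__(self, label: Optional[str] = None, length: Optional[float] = None):
        self.label = label
        self.length = length
        self.parent: Optional[TreeNode] = None
        self.children: list[TreeNode] = []

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["TreeNode"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self) -> Iterator["TreeNode"]:
        yield self
        for child in self.children:
            yield from child.preorder()

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.postorder() if n.is_leaf]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.label!r}, n_children={len(self.children)})"


class RootedTree:
    """A rooted tree with uniquely labelled leaves."""

    def __init__(self, root: TreeNode):
        self.root = root
        self.validate()

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_newick(cls, newick: str) -> "RootedTree":
        """Parse a Newick string into a rooted tree.

        Unbalanced parentheses or other syntax problems raise
        :class:`TreeParseError`; duplicate leaf labels raise
        :class:`TreeValidationError`.
        """
        try:
            dtree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
            raise TreeValidationError(f"duplicate leaf labels: {exc}") from exc
        except Exception as exc:
            raise TreeParseError(f"invalid Newick: {exc}") from exc

        def convert(dnode) -> TreeNode:
            if dnode.taxon is not None:
                label = dnode.taxon.label
            else:
                label = dnode.label
            node = TreeNode(label=label, length=dnode.edge.length)
            for dchild in dnode.child_nodes():
                node.add_child(convert(dchild))
            return node

        return cls(convert(dtree.seed_node))

    @classmethod
    def from_file(cls, path) -> "RootedTree":
        with open(path) as fh:
            text = fh.read()
        if not text.strip():
            raise TreeParseError(f"empty tree file: {path}")
        return cls.from_newick(text)

    def to_newick(self, include_lengths: bool = True) -> str:
        out = io.StringIO()

        def write(node: TreeNode) -> None:
            if node.children:
                out.write("(")
                for i, child in enumerate(node.children):
                    if i:
                        out.write(",")
                    write(child)
                out.write(")")
            if node.label is not None:
                out.write(_quote_label(node.label))
            if include_lengths and node.length is not None:
                out.write(f":{node.length:g}")

        write(self.root)
        out.write(";")
        return out.getvalue()

    def to_file(self, path, include_lengths: bool = True) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick(include_lengths=include_lengths) + "\n")

    # ------------------------------------------------------------ structure
    def validate(self) -> None:
        if self.root.parent is not None:
            raise TreeValidationError("root must not have a parent")
        labels = self.leaf_labels()
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeValidationError(f"duplicate leaf labels: {dupes}")
        for node in self.root.postorder():
            if node.length is not None and node.length < 0:
                raise TreeValidationError(
                    f"negative branch length {node.length} at {node.label!r}"
                )
            if node.is_leaf and node.label is None:
                raise TreeValidationError("leaf without a label")

    def postorder(self) -> Iterator[TreeNode]:
        return self.root.postorder()

    def preorder(self) -> Iterator[TreeNode]:
        return self.root.preorder()

    def leaves(self) -> list[TreeNode]:
        return self.root.leaves()

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.postorder() if not n.is_leaf]

    def find_leaf(self, label: str) -> TreeNode:
        for leaf in self.leaves():
            if leaf.label == label:
                return leaf
        raise KeyError(f"no leaf labelled {label!r}")

    @property
    def is_binary(self) -> bool:
        return all(len(n.children) in (0, 2) for n in self.postorder())

    def copy(self) -> "RootedTree":
        def clone(node: TreeNode) -> TreeNode:
            new = TreeNode(label=node.label, length=node.length)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return RootedTree(clone(self.root))

    # ----------------------------------------------------------- comparison
    def topology_signature(self) -> frozenset:
        """Set of leaf-label bipartition clades; equal signatures mean equal
        rooted topologies."""
        clades = set()
        for node in self.postorder():
            clades.add(frozenset(l.label for l in node.leaves()))
        return frozenset(clades)

    def same_topology(self, other: "RootedTree") -> bool:
        return self.topology_signature() == other.topology_signature()

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"RootedTree({len(self.leaves())} leaves)"


def _quote_label(label: str) -> str:
    if any(c in label for c in " ()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def resolve_polytomies(tree: RootedTree, mode: str = "ladderize-left") -> RootedTree:
    """Return a binary version of ``tree``.

    ``ladderize-left`` folds each polytomy deterministically from the left:
    children ``(A, B, C, D)`` become ``(((A, B), C), D)``.  New internal
    nodes carry zero-length branches so path lengths are unchanged.  With
    ``mode="reject"`` the first polytomy raises :class:`TreeValidationError`
    naming the offending node.
    """
    if mode not in ("ladderize-left", "reject"):
        raise ValueError(f"unknown mode {mode!r}")
    out = tree.copy()
    for node in list(out.postorder()):
        while len(node.children) > 2:
            if mode == "reject":
                desc = node.label or "{" + ",".join(sorted(l.label for l in node.leaves())) + "}"
                raise TreeValidationError(f"polytomy at node {desc}")
            first, second = node.children[0], node.children[1]
            joint = TreeNode(length=0.0)
            joint.add_child(first)
            joint.add_child(second)
            joint.parent = node
            node.children = [joint] + node.children[2:]
    out.validate()
    return out
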