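"""Maximum-parsimony ancestral state reconstruction.

A single multistate character (the 19-state gene-structure character, or
any hashable labels) is reconstructed on a rooted binary tree under the
unordered model: every state change costs one step, so the parsimony
length is the minimum number of changes over all ancestral assignments.

Beyond the Fitch length, :func:`count_mprs` enumerates — by dynamic
programming, not brute force — all most-parsimonious reconstructions
(MPRs) and reports, per internal node, the fraction of MPRs assigning each
state.  These fractions are the per-node "pie chart" probabilities used to
summarise ancestral-state uncertainty; a node with frequency 1 for one
state is unambiguously reconstructed.

Leaves may carry a set of states (ambiguity / missing data); an ambiguous
leaf contributes cost 0 for any of its allowed states and its choices are
counted as part of each MPR.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Hashable, Mapping, Optional

from .structure import (
    CharacterState,
    EventType,
    StructureCode,
    StructureEvent,
    encode_character_state,
    state_to_code,
)
from .trees import RootedTree, TreeNode

__all__ = [
    "CharacterMatrix",
    "FitchResult",
    "AncestralReconstruction",
    "BranchEvents",
    "StructureHistory",
    "fitch_parsimony",
    "count_mprs",
    "reconstruct_structure_history",
]

_INF = 10**9


@dataclass
class CharacterMatrix:
    """Leaf states for one character on a rooted tree.

    ``states`` maps each leaf label to a state or to a set of allowed
    states.  The leaf set of the tree and the keys of ``states`` must
    coincide exactly.
    """

    tree: RootedTree
    states: Mapping[str, object]

    def __post_init__(self):
        leaf_labels = set(self.tree.leaf_labels())
        given = set(self.states)
        if leaf_labels - given:
            raise ValueError(f"leaves without a state: {sorted(leaf_labels - given)}")
        if given - leaf_labels:
            raise ValueError(f"states for unknown taxa: {sorted(given - leaf_labels)}")

    def leaf_state_set(self, label: str) -> frozenset:
        value = self.states[label]
        if isinstance(value, (set, frozenset)):
            if not value:
                raise ValueError(f"leaf {label!r} has an empty state set")
            return frozenset(value)
        return frozenset([value])

    def state_space(self) -> list:
        space = set()
        for label in self.states:
            space |= self.leaf_state_set(label)
        return sorted(space, key=_state_key)


def _state_key(state) -> str:
    return state.value if isinstance(state, CharacterState) else str(state)


def _check_tree(matrix: CharacterMatrix) -> None:
    if len(matrix.tree.leaves()) < 2:
        raise ValueError("parsimony reconstruction needs at least 2 leaves")
    if not matrix.tree.is_binary:
        raise ValueError(
            "tree must be binary; resolve polytomies first "
            "(genefam.trees.resolve_polytomies)"
        )


@dataclass
class FitchResult:
    parsimony_length: int
    node_state_sets: dict  # TreeNode -> frozenset of states


def fitch_parsimony(matrix: CharacterMatrix) -> FitchResult:
    """Bottom-up Fitch pass: parsimony length and preliminary state sets.

    The length is computed by the unit-cost dynamic programme (exact also
    for ambiguous leaves); the returned sets are the per-node states that
    occur in at least one MPR.
    """
    _check_tree(matrix)
    space, inside = _inside_pass(matrix)
    total = min(cost for cost, _ in inside[matrix.tree.root])
    outside = _outside_pass(matrix, space, inside)
    sets = {}
    for node in matrix.tree.postorder():
        if node.is_leaf:
            continue
        states = frozenset(
            space[i]
            for i in range(len(space))
            if inside[node][i][0] + outside[node][i][0] == total
        )
        sets[node] = states
    return FitchResult(parsimony_length=total, node_state_sets=sets)


@dataclass
class AncestralReconstruction:
    """Summary of all most-parsimonious reconstructions of one character."""

    parsimony_length: int
    mpr_count: int
    node_state_sets: dict  # TreeNode -> frozenset
    node_state_frequencies: dict  # TreeNode -> {state: float}

    def majority_state(self, node: TreeNode, fallback=None):
        """State with the highest MPR frequency at ``node``; ties resolve
        to ``fallback`` when it is among the tied states, else to the
        alphabetically first tied state."""
        freqs = self.node_state_frequencies[node]
        best = max(freqs.values())
        tied = sorted((s for s, f in freqs.items() if f == best), key=_state_key)
        if fallback is not None and fallback in tied:
            return fallback
        return tied[0]


def count_mprs(matrix: CharacterMatrix) -> AncestralReconstruction:
    """Count MPRs and per-node state frequencies by inside/outside DP.

    For every internal node and state, the number of MPRs assigning that
    state is ``inside_count * outside_count`` whenever the combined cost
    equals the global minimum.  Frequencies are exact rationals converted
    to floats at the end.
    """
    _check_tree(matrix)
    space, inside = _inside_pass(matrix)
    root = matrix.tree.root
    total = min(cost for cost, _ in inside[root])
    mpr_count = sum(count for cost, count in inside[root] if cost == total)
    outside = _outside_pass(matrix, space, inside)

    sets = {}
    freqs = {}
    for node in matrix.tree.postorder():
        if node.is_leaf:
            continue
        node_counts = {}
        for i, state in enumerate(space):
            ic, icount = inside[node][i]
            oc, ocount = outside[node][i]
            if ic + oc == total:
                node_counts[state] = icount * ocount
        assert sum(node_counts.values()) == mpr_count, "MPR counts must be conserved"
        sets[node] = frozenset(node_counts)
        freqs[node] = {
            s: float(Fraction(c, mpr_count)) for s, c in node_counts.items()
        }
    return AncestralReconstruction(
        parsimony_length=total,
        mpr_count=mpr_count,
        node_state_sets=sets,
        node_state_frequencies=freqs,
    )


def _inside_pass(matrix: CharacterMatrix):
    """Per node and state: (min changes within the subtree given the node
    has that state, number of such minimal subtree assignments)."""
    space = matrix.state_space()
    n = len(space)
    inside: dict[TreeNode, list[tuple[int, int]]] = {}
    for node in matrix.tree.postorder():
        if node.is_leaf:
            allowed = matrix.leaf_state_set(node.label)
            inside[node] = [
                (0, 1) if space[i] in allowed else (_INF, 0) for i in range(n)
            ]
            continue
        rows = []
        for i in range(n):
            cost = 0
            count = 1
            for child in node.children:
                best = _INF
                best_count = 0
                for j in range(n):
                    c = inside[child][j][0] + (0 if i == j else 1)
                    if c < best:
                        best, best_count = c, inside[child][j][1]
                    elif c == best:
                        best_count += inside[child][j][1]
                cost += best
                count *= best_count
            rows.append((min(cost, _INF), count if cost < _INF else 0))
        inside[node] = rows
    return space, inside


def _outside_pass(matrix: CharacterMatrix, space, inside):
    """Per node and state: (min changes outside the subtree given the node
    has that state, number of such minimal outside assignments)."""
    n = len(space)
    outside: dict[TreeNode, list[tuple[int, int]]] = {}
    root = matrix.tree.root
    outside[root] = [(0, 1)] * n
    for node in matrix.tree.preorder():
        if node.is_leaf:
            continue
        for child in node.children:
            siblings = [c for c in node.children if c is not child]
            # cost/count of the rest of the tree given the parent's state
            parent_rows = []
            for i in range(n):
                cost = outside[node][i][0]
                count = outside[node][i][1]
                for sib in siblings:
                    best = _INF
                    best_count = 0
                    for j in range(n):
                        c = inside[sib][j][0] + (0 if i == j else 1)
                        if c < best:
                            best, best_count = c, inside[sib][j][1]
                        elif c == best:
                            best_count += inside[sib][j][1]
                    cost += best
                    count *= best_count
                parent_rows.append((min(cost, _INF), count if cost < _INF else 0))
            rows = []
            for t in range(n):
                best = _INF
                best_count = 0
                for i in range(n):
                    c = parent_rows[i][0] + (0 if i == t else 1)
                    if c < best:
                        best, best_count = c, parent_rows[i][1]
                    elif c == best:
                        best_count += parent_rows[i][1]
                rows.append((best, best_count))
            outside[child] = rows
    return outside


# ------------------------------------------------- structure-history wrapper


@dataclass
class BranchEvents:
    """Structural events implied on the branch above ``node``."""

    node: TreeNode
    parent_state: CharacterState
    child_state: CharacterState
    events: tuple[StructureEvent, ...]
    irregular: bool  # transition involves regains or non-decodable states


@dataclass
class StructureHistory:
    reconstruction: AncestralReconstruction
    node_states: dict  # TreeNode -> CharacterState (majority-MPR labelling)
    branch_events: list


def reconstruct_structure_history(
    codes,
    tree: RootedTree,
    unknown_as_missing: bool = False,
) -> StructureHistory:
    """Encode structure codes, reconstruct ancestral states, and label each
    state-changing branch with the structural events it implies.

    ``unknown_as_missing`` treats the unknown state as missing data (the
    leaf may take any observed state) instead of as a distinct 19th state.
    Branch labelling uses the majority-MPR state at each node, with ties
    broken toward the parent's state so that no spurious change is
    reported.
    """
    states: dict[str, object] = {
        code.gene_id: encode_character_state(code) for code in codes
    }
    if unknown_as_missing:
        observed = {s for s in states.values() if s is not CharacterState.UNKNOWN}
        if observed:
            states = {
                g: (frozenset(observed) if s is CharacterState.UNKNOWN else s)
                for g, s in states.items()
            }
    matrix = CharacterMatrix(tree=tree, states=states)
    rec = count_mprs(matrix)

    node_states: dict[TreeNode, CharacterState] = {}
    for node in tree.preorder():
        if node.is_leaf:
            value = matrix.leaf_state_set(node.label)
            if len(value) == 1:
                node_states[node] = next(iter(value))
            else:
                node_states[node] = node_states[node.parent]  # missing leaf: no change
            continue
        fallback = node_states.get(node.parent) if node.parent is not None else None
        node_states[node] = rec.majority_state(node, fallback=fallback)

    branch_events = []
    for node in tree.preorder():
        if node.parent is None:
            continue
        parent_state = node_states[node.parent]
        child_state = node_states[node]
        if parent_state == child_state:
            continue
        events, irregular = _transition_events(parent_state, child_state)
        branch_events.append(
            BranchEvents(
                node=node,
                parent_state=parent_state,
                child_state=child_state,
                events=tuple(events),
                irregular=irregular,
            )
        )
    return StructureHistory(
        reconstruction=rec, node_states=node_states, branch_events=branch_events
    )


def _transition_events(parent_state, child_state):
    from .structure import classify_events

    parent_code = state_to_code(parent_state)
    child_code = state_to_code(child_state)
    if parent_code is None or child_code is None:
        return [], True
    lost = [
        k
        for k, (p, c) in enumerate(
            zip(parent_code.ancestral_intron_present, child_code.ancestral_intron_present),
            start=1,
        )
        if p and not c
    ]
    regained = [
        k
        for k, (p, c) in enumerate(
            zip(parent_code.ancestral_intron_present, child_code.ancestral_intron_present),
            start=1,
        )
        if c and not p
    ]
    gained_novel = child_code.novel_exon2_intron and not parent_code.novel_exon2_intron
    lost_novel = parent_code.novel_exon2_intron and not child_code.novel_exon2_intron
    present = [True] * len(parent_code.ancestral_intron_present)
    for k in lost:
        present[k - 1] = False
    diff = StructureCode(
        gene_id="transition",
        ancestral_intron_present=tuple(present),
        novel_exon2_intron=gained_novel,
    )
    events = classify_events(diff)
    irregular = bool(regained) or lost_novel
    return events, irregular
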