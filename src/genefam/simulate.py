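"""Synthetic gene families with known ground truth.

Everything the analysis pipeline consumes can be generated here with the
true history attached: a Yule species tree, a birth-death gene family
evolving on it (duplication/loss events logged per species branch),
gene structures descending from the 14-exon / 13-intron ancestor under
Type 1/2/3 events, a gap-free protein alignment for intron projection,
chromosomal gene placements with planted tandem arrays, and triplicate
qPCR Ct tables with known fold changes.

The ancestral architecture used throughout is fixed: 14 exons of ~168
coding bases each (protein length 784 aa, inside the 753-817 aa range of
the soybean family), intron phases mostly 0 with a sprinkling of 1 and 2,
and a designated exon-2 locus for the novel intron gain.  Simulated losses
never push a gene below 7 introns, matching the observed 7-14 range, and
by default events are placed so that no two losses on one lineage touch
adjacent introns — making every leaf's event decomposition unambiguous
(collision-free mode; switch off for stress testing).

All functions are deterministic given (parameters, seed).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .io import GeneModel
from .qpcr import CtDataset
from .stats import GeneLocus
from .structure import (
    N_ANCESTRAL_INTRONS,
    EventType,
    IntronProfile,
    Intron,
    StructureCode,
    StructureEvent,
    compute_intron_profile,
)
from .trees import RootedTree, TreeNode

__all__ = [
    "SimulationConfig",
    "GeneFamilyTruth",
    "StructureSimulation",
    "ANCESTRAL_PHASES",
    "ANCESTRAL_INTRON_CDS_POSITIONS",
    "simulate_species_tree",
    "simulate_gene_family",
    "simulate_structure_evolution",
    "simulate_ct_data",
    "simulate_tandem_loci",
    "paper_tissue_design",
    "paper_stress_design",
    "ancestral_gene_model",
]

# ------------------------------------------------------ ancestral structure

EXON_CODING_BP = 168  # per ancestral exon; 14 exons -> 784 aa protein
ANCESTRAL_PHASES = (0, 2, 0, 0, 1, 0, 0, 2, 0, 0, 0, 1, 0)
ANCESTRAL_INTRON_CDS_POSITIONS = tuple(
    EXON_CODING_BP * k + ANCESTRAL_PHASES[k - 1] for k in range(1, N_ANCESTRAL_INTRONS + 1)
)
TOTAL_CDS_BP = EXON_CODING_BP * (N_ANCESTRAL_INTRONS + 1)
PROTEIN_LENGTH = TOTAL_CDS_BP // 3
NOVEL_INTRON_CDS_POS = 252  # inside exon 2, phase 0
INTRON_GENOMIC_BP = 200
MIN_INTRONS = 7

_AA = "ACDEFGHIKLMNPQRSTVWY"


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


@dataclass
class SimulationConfig:
    """Default study conditions for end-to-end simulations.

    Rates are events per unit branch length on trees scaled to depth 1.
    The structural-event rates keep the paper-like proportions (single
    fusions an order of magnitude more common than double fusions and
    gains); fold changes follow the salt/osmotic stress design with its
    >6-fold salt induction.
    """

    seed: int = 0
    n_species: int = 28
    dup_rate: float = 0.3
    loss_rate: float = 0.1
    type1_rate: float = 0.35
    type2_rate: float = 0.04
    type3_rate: float = 0.04
    tandem_fraction: float = 0.4
    ct_noise_sd: float = 0.15
    fold_changes: dict = field(
        default_factory=lambda: {
            "control": 1.0,
            "PEG_4h": 0.5,
            "PEG_8h": 0.4,
            "NaCl_4h": 6.0,
            "NaCl_8h": 6.5,
        }
    )

    def __post_init__(self):
        for name in ("dup_rate", "loss_rate", "type1_rate", "type2_rate", "type3_rate", "ct_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.tandem_fraction <= 1:
            raise ValueError("tandem_fraction must be in [0, 1]")
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")


# ------------------------------------------------------------- species tree


def simulate_species_tree(n_species: int, seed: Union[int, np.random.Generator] = 0) -> RootedTree:
    """Yule (pure-birth) species tree, ultrametric, scaled to depth 1.

    Leaves are labelled ``S1..Sn``; internal nodes ``N1..``.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = _rng(seed)
    root = TreeNode()
    depth = {root: 0.0}
    active = []
    for _ in range(2):
        child = root.add_child(TreeNode())
        depth[child] = 0.0
        active.append(child)
    t = 0.0
    while len(active) < n_species:
        t += rng.exponential(1.0 / len(active))
        idx = int(rng.integers(len(active)))
        node = active.pop(idx)
        depth[node] = t
        for _ in range(2):
            child = node.add_child(TreeNode())
            active.append(child)
    t_final = t + rng.exponential(1.0 / len(active))
    for node in active:
        depth[node] = t_final
    scale = t_final if t_final > 0 else 1.0
    for node in root.postorder():
        if node.parent is not None:
            node.length = (depth[node] - depth[node.parent]) / scale
    for i, leaf in enumerate(root.leaves(), start=1):
        leaf.label = f"S{i}"
    internal = [n for n in root.postorder() if not n.is_leaf]
    for i, node in enumerate(internal, start=1):
        node.label = f"N{i}"
    return RootedTree(root)


# -------------------------------------------------------------- gene family


@dataclass
class GeneFamilyTruth:
    """Event log of one simulated birth-death gene family."""

    n_duplications: int
    n_losses: int
    events: list  # dicts: {type, species_branch, time}
    duplication_nodes: set  # gene-tree nodes that are true duplications
    n_resampled: int
    leaf_species: dict  # gene leaf label -> species label


def simulate_gene_family(
    species_tree: RootedTree,
    dup_rate: float,
    loss_rate: float,
    seed: Union[int, np.random.Generator] = 0,
    max_resample: int = 1000,
) -> tuple[RootedTree, GeneFamilyTruth]:
    """Birth-death gene family along a species tree, one root copy.

    Gene lineages duplicate (rate ``dup_rate``) or die (``loss_rate``)
    along species branches and split at every speciation.  Gene leaves are
    labelled ``<species>_<i>``.  Families extinct in all species are
    resampled, with the resample count reported in the truth record.
    """
    if dup_rate < 0 or loss_rate < 0:
        raise ValueError("rates must be >= 0")
    rng = _rng(seed)
    for attempt in range(max_resample):
        events: list[dict] = []
        dup_nodes: set[TreeNode] = set()
        counters: dict[str, int] = {}
        depth: dict[TreeNode, float] = {}

        def evolve(sp_node: TreeNode, remaining: float, t_abs: float) -> Optional[TreeNode]:
            total = dup_rate + loss_rate
            wait = rng.exponential(1.0 / total) if total > 0 else np.inf
            if wait < remaining:
                t_event = t_abs + wait
                if rng.random() < (dup_rate / total if total else 0):
                    events.append(
                        {"type": "duplication", "species_branch": sp_node.label, "time": t_event}
                    )
                    left = evolve(sp_node, remaining - wait, t_event)
                    right = evolve(sp_node, remaining - wait, t_event)
                    if left is not None and right is not None:
                        node = TreeNode()
                        node.add_child(left)
                        node.add_child(right)
                        depth[node] = t_event
                        dup_nodes.add(node)
                        return node
                    return left if left is not None else right
                events.append(
                    {"type": "loss", "species_branch": sp_node.label, "time": t_event}
                )
                return None
            t_end = t_abs + remaining
            if sp_node.is_leaf:
                counters[sp_node.label] = counters.get(sp_node.label, 0) + 1
                leaf = TreeNode(label=f"{sp_node.label}_{counters[sp_node.label]}")
                depth[leaf] = t_end
                return leaf
            subtrees = [
                evolve(child, child.length if child.length is not None else 1.0, t_end)
                for child in sp_node.children
            ]
            alive = [s for s in subtrees if s is not None]
            if not alive:
                return None
            if len(alive) == 1:
                return alive[0]
            node = TreeNode()
            for sub in alive:
                node.add_child(sub)
            depth[node] = t_end
            return node

        root_sub = [
            evolve(child, child.length if child.length is not None else 1.0, 0.0)
            for child in species_tree.root.children
        ]
        alive = [s for s in root_sub if s is not None]
        if not alive:
            continue
        if len(alive) == 1:
            root = alive[0]
        else:
            root = TreeNode()
            for sub in alive:
                root.add_child(sub)
            depth[root] = 0.0
        root.parent = None
        for node in root.postorder():
            if node.parent is not None:
                node.length = depth[node] - depth[node.parent]
        root.length = None
        gene_tree = RootedTree(root)
        truth = GeneFamilyTruth(
            n_duplications=sum(1 for e in events if e["type"] == "duplication"),
            n_losses=sum(1 for e in events if e["type"] == "loss"),
            events=events,
            duplication_nodes={n for n in dup_nodes if _in_tree(n, root)},
            n_resampled=attempt,
            leaf_species={
                leaf.label: leaf.label.rsplit("_", 1)[0] for leaf in gene_tree.leaves()
            },
        )
        return gene_tree, truth
    raise RuntimeError(f"family went extinct in all {max_resample} resampling attempts")


def _in_tree(node: TreeNode, root: TreeNode) -> bool:
    while node is not None:
        if node is root:
            return True
        node = node.parent
    return False


# ---------------------------------------------------------- gene structures


@dataclass
class StructureSimulation:
    """Simulated structure evolution with full ground truth."""

    gene_tree: RootedTree
    leaf_models: dict  # gene label -> GeneModel
    leaf_codes: dict  # gene label -> true StructureCode
    reference_model: GeneModel
    alignment: MultipleSeqAlignment
    branch_events: dict  # TreeNode -> list[StructureEvent] applied on the branch above
    n_rejected_draws: int
    n_suppressed: int
    gain_clade_leaves: frozenset

    @property
    def reference_profile(self) -> IntronProfile:
        return compute_intron_profile(self.reference_model)

    def true_event_multiset(self, leaf_label: str):
        """Multiset of events accumulated on the root-to-leaf path."""
        leaf = self.gene_tree.find_leaf(leaf_label)
        events = []
        node = leaf
        while node.parent is not None:
            events.extend(self.branch_events.get(node, []))
            node = node.parent
        return sorted(events, key=lambda e: (e.event_type.value, e.intron_indices))


def ancestral_gene_model(gene_id: str = "ancestor") -> GeneModel:
    """The 14-exon ancestral gene laid out on a synthetic chromosome."""
    return _build_gene_model(gene_id, (True,) * N_ANCESTRAL_INTRONS, False, [])


def _build_gene_model(
    gene_id: str,
    present: Sequence[bool],
    novel: bool,
    insertions: Sequence[tuple[int, int]],
) -> GeneModel:
    """Exon coordinates implied by a structure: ancestral exon coding
    lengths, fused across lost introns, split at the novel exon-2 locus,
    with optional (cds_position, bp) insertions applied."""
    bounds = [0, *ANCESTRAL_INTRON_CDS_POSITIONS, TOTAL_CDS_BP]
    splice_sites = [
        pos
        for k, pos in enumerate(ANCESTRAL_INTRON_CDS_POSITIONS)
        if present[k]
    ]
    if novel:
        splice_sites.append(NOVEL_INTRON_CDS_POS)
    splice_sites.sort()
    cuts = [0, *splice_sites, TOTAL_CDS_BP]
    lengths = [b - a for a, b in zip(cuts, cuts[1:])]
    for cds_pos, bp in sorted(insertions):
        cumulative = 0
        for i, length in enumerate(lengths):
            if cds_pos <= cumulative + length:
                lengths[i] += bp
                break
            cumulative += length
        else:
            lengths[-1] += bp
    exons = []
    cursor = 0
    for length in lengths:
        exons.append((cursor, cursor + length))
        cursor += length + INTRON_GENOMIC_BP
    return GeneModel(
        gene_id=gene_id, chromosome="sim", strand="+", exons=tuple(exons)
    )


def simulate_structure_evolution(
    gene_tree: RootedTree,
    type1_rate: float = 0.35,
    type2_rate: float = 0.04,
    type3_rate: float = 0.04,
    seed: Union[int, np.random.Generator] = 0,
    gain_clade: Optional[TreeNode] = None,
    avoid_collisions: bool = True,
    min_introns: int = MIN_INTRONS,
    indel_rate: float = 0.0,
    max_redraws: int = 50,
) -> StructureSimulation:
    """Evolve gene structures from the 14-exon ancestor along a gene tree.

    Per branch, Type 1 (single intron loss), Type 2 (adjacent double loss)
    and Type 3 (novel exon-2 gain) event counts are Poisson in the branch
    length.  Draws hitting already-lost introns are rejected and redrawn;
    draws that would leave fewer than ``min_introns`` introns are
    suppressed.  Type 3 is restricted to ``gain_clade`` (default: the
    subtree of the root's first child, emulating a gain confined to one
    lineage) and can happen at most once per lineage.

    With ``avoid_collisions`` (default) no loss is placed next to an
    already-lost intron, so each leaf's cumulative lost-intron set
    decomposes uniquely into the simulated events.  ``indel_rate`` > 0
    adds per-leaf coding insertions (1-3 codons), producing a gapped
    alignment that stresses the projection tolerance.
    """
    rng = _rng(seed)
    if gain_clade is None and not gene_tree.root.is_leaf:
        gain_clade = gene_tree.root.children[0]
    gain_leaves = frozenset(
        l.label for l in (gain_clade.leaves() if gain_clade is not None else [])
    )

    branch_events: dict[TreeNode, list[StructureEvent]] = {}
    state: dict[TreeNode, tuple[tuple[bool, ...], bool]] = {}
    n_rejected = 0
    n_suppressed = 0
    state[gene_tree.root] = ((True,) * N_ANCESTRAL_INTRONS, False)

    for node in gene_tree.preorder():
        if node.parent is None:
            continue
        present, gained = state[node.parent]
        present = list(present)
        bl = node.length if node.length is not None else 1.0
        applied: list[StructureEvent] = []
        in_gain_clade = gain_clade is not None and _in_tree(node, gain_clade)

        n2 = rng.poisson(type2_rate * bl)
        for _ in range(n2):
            placed = False
            for _ in range(max_redraws):
                k = int(rng.integers(1, N_ANCESTRAL_INTRONS))  # pair (k, k+1)
                if not (present[k - 1] and present[k]):
                    n_rejected += 1
                    continue
                if avoid_collisions and (
                    (k >= 2 and not present[k - 2])
                    or (k + 1 <= N_ANCESTRAL_INTRONS - 1 and not present[k + 1])
                ):
                    n_rejected += 1
                    continue
                if sum(present) + int(gained) - 2 < min_introns:
                    n_suppressed += 1
                    placed = True  # suppressed, not retried
                    break
                present[k - 1] = False
                present[k] = False
                applied.append(StructureEvent(EventType.TYPE2, (k, k + 1)))
                placed = True
                break
            if not placed:
                n_suppressed += 1

        n1 = rng.poisson(type1_rate * bl)
        for _ in range(n1):
            placed = False
            for _ in range(max_redraws):
                k = int(rng.integers(1, N_ANCESTRAL_INTRONS + 1))
                if not present[k - 1]:
                    n_rejected += 1
                    continue
                if avoid_collisions and (
                    (k >= 2 and not present[k - 2])
                    or (k <= N_ANCESTRAL_INTRONS - 1 and not present[k])
                ):
                    n_rejected += 1
                    continue
                if sum(present) + int(gained) - 1 < min_introns:
                    n_suppressed += 1
                    placed = True
                    break
                present[k - 1] = False
                applied.append(StructureEvent(EventType.TYPE1, (k,)))
                placed = True
                break
            if not placed:
                n_suppressed += 1

        if in_gain_clade and not gained and type3_rate > 0:
            if rng.poisson(type3_rate * bl) > 0:
                gained = True
                applied.append(StructureEvent(EventType.TYPE3, (2,)))

        branch_events[node] = applied
        state[node] = (tuple(present), gained)

    leaf_codes = {}
    leaf_insertions: dict[str, list[tuple[int, int]]] = {}
    for leaf in gene_tree.leaves():
        present, gained = state[leaf]
        leaf_codes[leaf.label] = StructureCode(
            gene_id=leaf.label,
            ancestral_intron_present=present,
            novel_exon2_intron=gained,
        )
        inserts = []
        if indel_rate > 0:
            for _ in range(int(rng.poisson(indel_rate))):
                codon = int(rng.integers(1, PROTEIN_LENGTH))
                n_codons = int(rng.integers(1, 4))
                inserts.append((codon * 3, n_codons * 3))
        leaf_insertions[leaf.label] = inserts

    leaf_models = {
        label: _build_gene_model(
            label,
            leaf_codes[label].ancestral_intron_present,
            leaf_codes[label].novel_exon2_intron,
            leaf_insertions[label],
        )
        for label in leaf_codes
    }
    reference_model = ancestral_gene_model()
    alignment = _build_alignment(rng, leaf_insertions, reference_id="ancestor")
    return StructureSimulation(
        gene_tree=gene_tree,
        leaf_models=leaf_models,
        leaf_codes=leaf_codes,
        reference_model=reference_model,
        alignment=alignment,
        branch_events=branch_events,
        n_rejected_draws=n_rejected,
        n_suppressed=n_suppressed,
        gain_clade_leaves=gain_leaves,
    )


def _build_alignment(rng, leaf_insertions, reference_id: str) -> MultipleSeqAlignment:
    base = "".join(rng.choice(list(_AA), size=PROTEIN_LENGTH))
    rows: dict[str, list[str]] = {reference_id: list(base)}
    for label in leaf_insertions:
        rows[label] = list(base)
    for label, inserts in leaf_insertions.items():
        for cds_pos, bp in sorted(inserts, reverse=True):
            codon = cds_pos // 3
            n_codons = bp // 3
            row = rows[label]
            cols = [i for i, ch in enumerate(row) if ch != "-"]
            at = cols[codon] if codon < len(cols) else len(row)
            insert_aa = [str(rng.choice(list(_AA))) for _ in range(n_codons)]
            for other, other_row in rows.items():
                if other == label:
                    other_row[at:at] = insert_aa
                else:
                    other_row[at:at] = ["-"] * n_codons
    records = [
        SeqRecord(Seq("".join(row)), id=label, description="")
        for label, row in rows.items()
    ]
    return MultipleSeqAlignment(records)


# -------------------------------------------------------------------- loci


def simulate_tandem_loci(
    n_scattered: int = 4,
    n_arrays: int = 2,
    seed: Union[int, np.random.Generator] = 0,
    species: str = "SimSp",
    n_chromosomes: int = 5,
) -> tuple[list[GeneLocus], list[list[str]]]:
    """Chromosomal placements with planted tandem arrays.

    Arrays of 2-3 adjacent family members (consecutive gene ranks, small
    gaps) are planted among scattered members placed at least three gene
    ranks and well over 100 kb away from each other.  Returns the family
    loci and the true arrays.
    """
    rng = _rng(seed)
    slot_bp = 60_000  # background gene every 60 kb
    used: dict[str, set[int]] = {f"chr{i + 1}": set() for i in range(n_chromosomes)}
    loci: list[GeneLocus] = []
    true_arrays: list[list[str]] = []
    counter = 0

    def place(chrom: str, rank: int, gene_id: str) -> GeneLocus:
        start = rank * slot_bp
        return GeneLocus(
            gene_id=gene_id,
            species=species,
            chromosome=chrom,
            start=start,
            end=start + 2_000,
            family_member=True,
            gene_rank=rank,
        )

    def free_stretch(chrom: str, size: int, margin: int = 3) -> int:
        for _ in range(500):
            rank = int(rng.integers(0, 200))
            span = set(range(rank - margin, rank + size + margin))
            if not span & used[chrom]:
                used[chrom].update(range(rank, rank + size))
                return rank
        raise RuntimeError("could not place gene; too crowded")

    for _ in range(n_arrays):
        size = int(rng.integers(2, 4))
        chrom = f"chr{int(rng.integers(n_chromosomes)) + 1}"
        rank = free_stretch(chrom, size)
        array = []
        for offset in range(size):
            counter += 1
            locus = place(chrom, rank + offset, f"{species}_fam{counter}")
            loci.append(locus)
            array.append(locus.gene_id)
        true_arrays.append(array)
    for _ in range(n_scattered):
        counter += 1
        chrom = f"chr{int(rng.integers(n_chromosomes)) + 1}"
        rank = free_stretch(chrom, 1)
        loci.append(place(chrom, rank, f"{species}_fam{counter}"))
    return loci, true_arrays


# -------------------------------------------------------------------- qPCR


def paper_tissue_design() -> tuple[list[str], str]:
    """Organ panel: seven tissues/fruit stages, roots as calibrator."""
    return (
        ["root", "stem", "leaf", "flower", "fruit_1d", "fruit_3d", "fruit_5d", "fruit_7d"],
        "root",
    )


def paper_stress_design() -> tuple[list[str], str]:
    """Stress panel: PEG and NaCl at 4 h and 8 h, untreated calibrator."""
    return (["control", "PEG_4h", "PEG_8h", "NaCl_4h", "NaCl_8h"], "control")


def simulate_ct_data(
    fold_changes: dict,
    ct_noise_sd: float = 0.15,
    seed: Union[int, np.random.Generator] = 0,
    genes: Sequence[str] = ("GeneX",),
    reference_gene: str = "actin",
    calibrator_sample: str = "control",
    n_replicates: int = 3,
    baseline_ct: float = 20.0,
    dct_calibrator: float = 3.0,
    conditions: Optional[dict] = None,
) -> CtDataset:
    """Triplicate Ct wells with known per-sample fold changes.

    Per replicate, the reference Ct is Normal(baseline, sd) and the target
    Ct is that reference Ct plus the calibrator dCt, minus log2(fold),
    plus Normal(0, sd) noise — so the paired ddCt estimator is unbiased
    for ``fold`` and exact when sd = 0.
    """
    if ct_noise_sd < 0:
        raise ValueError("ct_noise_sd must be >= 0")
    if calibrator_sample not in fold_changes:
        raise ValueError(f"fold_changes must include the calibrator {calibrator_sample!r}")
    rng = _rng(seed)
    conditions = conditions or {}
    records = []
    for sample, fold in fold_changes.items():
        if fold <= 0:
            raise ValueError(f"fold change for {sample!r} must be > 0")
        condition = conditions.get(sample, sample)
        for rep in range(1, n_replicates + 1):
            ct_ref = baseline_ct + rng.normal(0.0, ct_noise_sd) if ct_noise_sd else baseline_ct
            records.append(
                {
                    "gene": reference_gene,
                    "sample": sample,
                    "condition": condition,
                    "replicate": rep,
                    "Ct": ct_ref,
                }
            )
            for gene in genes:
                noise = rng.normal(0.0, ct_noise_sd) if ct_noise_sd else 0.0
                relative_fold = fold / fold_changes[calibrator_sample]
                ct_gene = ct_ref + dct_calibrator - np.log2(relative_fold) + noise
                records.append(
                    {
                        "gene": gene,
                        "sample": sample,
                        "condition": condition,
                        "replicate": rep,
                        "Ct": ct_gene,
                    }
                )
    wells = pd.DataFrame.from_records(records)
    return CtDataset(
        wells=wells, reference_gene=reference_gene, calibrator_sample=calibrator_sample
    )
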