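"""Intron-level gene-structure analysis.

The gene family studied here descends from a 14-exon / 13-intron ancestral
architecture.  Observed structures are explained as losses of ancestral
introns (seen as exon fusions) plus at most one novel intron gained inside
exon 2.  This module computes intron positions and phases from exon
coordinates, projects introns onto a reference protein alignment to decide
which ancestral intron each one is, classifies the implied structural
events, and encodes each gene into a single 19-state structure character:

====== ==========================================================
state  meaning
====== ==========================================================
a      full 14-exon structure (all 13 ancestral introns present)
b..n   exactly one ancestral intron (1..13) lost
o      intronless
p      novel intron gained in exon 2, all ancestral introns kept
q, r   animal outgroup architectures (14 / 15 introns)
s      unknown: any structure not expressible as above
====== ==========================================================

Intron phase follows the standard convention: phase 0 when splicing falls
after the third nucleotide of a codon, phase 1 after the first, phase 2
after the second — i.e. phase = (coding bases upstream of the intron) mod 3.

Event taxonomy: a *Type 1* event is a single exon fusion (one intron lost
between two adjacent exons); a *Type 2* event is a double fusion merging
three consecutive exons (two adjacent introns lost); a *Type 3* event is
the novel exon-2 intron gain.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .io import GeneModel

__all__ = [
    "N_ANCESTRAL_INTRONS",
    "Intron",
    "IntronProfile",
    "StructureCode",
    "EventType",
    "StructureEvent",
    "CharacterState",
    "ProjectionError",
    "compute_intron_profile",
    "project_introns",
    "classify_events",
    "encode_character_state",
    "state_to_code",
]

#: introns of the 14-exon ancestral architecture, numbered 1..13
N_ANCESTRAL_INTRONS = 13


class ProjectionError(ValueError):
    """Projection onto the reference alignment failed or was ambiguous."""


@dataclass(frozen=True)
class Intron:
    """An intron located by its coding-sequence coordinate.

    ``cds_position`` counts coding bases upstream of the splice junction;
    ``phase`` is ``cds_position mod 3``.
    """

    cds_position: int
    phase: int

    def __post_init__(self):
        if self.phase != self.cds_position % 3:
            raise ValueError(
                f"phase {self.phase} inconsistent with cds_position {self.cds_position}"
            )


@dataclass(frozen=True)
class IntronProfile:
    gene_id: str
    introns: tuple[Intron, ...]

    def __post_init__(self):
        positions = [i.cds_position for i in self.introns]
        if positions != sorted(set(positions)):
            raise ValueError(f"{self.gene_id}: intron positions must strictly increase")

    @property
    def phases(self) -> tuple[int, ...]:
        return tuple(i.phase for i in self.introns)


@dataclass(frozen=True)
class StructureCode:
    """Presence/absence of the 13 ancestral introns plus the exon-2 gain.

    ``unresolved`` marks genes whose introns could not all be confidently
    assigned to ancestral slots; such genes are excluded from event
    classification and coded as the unknown state.
    """

    gene_id: str
    ancestral_intron_present: tuple[bool, ...]
    novel_exon2_intron: bool = False
    unresolved: bool = False

    def __post_init__(self):
        if len(self.ancestral_intron_present) != N_ANCESTRAL_INTRONS:
            raise ValueError(
                f"{self.gene_id}: expected {N_ANCESTRAL_INTRONS} presence flags"
            )

    @property
    def intron_count(self) -> int:
        return sum(self.ancestral_intron_present) + int(self.novel_exon2_intron)

    @property
    def lost_introns(self) -> tuple[int, ...]:
        """1-based indices of absent ancestral introns."""
        return tuple(
            k for k, present in enumerate(self.ancestral_intron_present, start=1) if not present
        )


class EventType(enum.Enum):
    TYPE1 = "Type1"
    TYPE2 = "Type2"
    TYPE3 = "Type3"


@dataclass(frozen=True)
class StructureEvent:
    event_type: EventType
    intron_indices: tuple[int, ...]

    def __post_init__(self):
        n = len(self.intron_indices)
        if self.event_type is EventType.TYPE1 and n != 1:
            raise ValueError("Type1 references exactly one lost intron")
        if self.event_type is EventType.TYPE2:
            if n != 2 or self.intron_indices[1] != self.intron_indices[0] + 1:
                raise ValueError("Type2 references exactly two adjacent lost introns")
        if self.event_type is EventType.TYPE3 and n != 1:
            raise ValueError("Type3 references the gained-intron locus only")


class CharacterState(enum.Enum):
    """The closed 19-state vocabulary of the structure character."""

    FULL_14_EXON = "a"
    LOSS_1 = "b"
    LOSS_2 = "c"
    LOSS_3 = "d"
    LOSS_4 = "e"
    LOSS_5 = "f"
    LOSS_6 = "g"
    LOSS_7 = "h"
    LOSS_8 = "i"
    LOSS_9 = "j"
    LOSS_10 = "k"
    LOSS_11 = "l"
    LOSS_12 = "m"
    LOSS_13 = "n"
    INTRONLESS = "o"
    EXON2_INSERTION = "p"
    ANIMAL_14_INTRON = "q"
    ANIMAL_15_INTRON = "r"
    UNKNOWN = "s"


_SINGLE_LOSS_STATES = {
    k: CharacterState("bcdefghijklmn"[k - 1]) for k in range(1, N_ANCESTRAL_INTRONS + 1)
}


# ---------------------------------------------------------------- profiles


def compute_intron_profile(gene: GeneModel) -> IntronProfile:
    """Intron coding positions and phases from exon coordinates.

    A single-exon gene yields an empty intron list.  A coding length not
    divisible by 3 triggers a warning (truncated or mis-annotated model)
    but still returns the profile.
    """
    lengths = gene.coding_exon_lengths()
    total = sum(lengths)
    if total % 3:
        warnings.warn(
            f"{gene.gene_id}: coding length {total} not divisible by 3", stacklevel=2
        )
    introns = []
    cumulative = 0
    for length in lengths[:-1]:
        cumulative += length
        introns.append(Intron(cds_position=cumulative, phase=cumulative % 3))
    return IntronProfile(gene_id=gene.gene_id, introns=tuple(introns))


# -------------------------------------------------------------- projection


def _aligned_row(alignment, name: str) -> str:
    for record in alignment:
        if record.id == name:
            return str(record.seq)
    raise KeyError(f"sequence {name!r} not found in alignment")


def _residue_columns(row: str) -> list[int]:
    return [col for col, ch in enumerate(row) if ch != "-"]


def _intron_columns(profile: IntronProfile, row: str) -> list[tuple[int, int]]:
    """(alignment column, phase) of each intron; the column is that of the
    residue whose codon the intron interrupts (or, for phase 0, begins)."""
    cols = _residue_columns(row)
    out = []
    for intron in profile.introns:
        residue = intron.cds_position // 3
        if residue >= len(cols):
            raise ProjectionError(
                f"{profile.gene_id}: intron at cds position {intron.cds_position} "
                f"beyond aligned sequence ({len(cols)} residues)"
            )
        out.append((cols[residue], intron.phase))
    return out


def project_introns(
    profile: IntronProfile,
    alignment,
    reference_profile: IntronProfile,
    tolerance: int = 0,
) -> StructureCode:
    """Assign each intron of ``profile`` to an ancestral intron slot.

    Both genes must be rows of ``alignment`` (a Biopython
    ``MultipleSeqAlignment`` of the proteins) and the reference must carry
    all 13 ancestral introns.  An intron matches ancestral slot *k* when it
    falls on the same alignment column (within ``tolerance`` columns) with
    the same phase.  An unmatched intron inside exon-2 territory (reference
    columns between ancestral introns 1 and 2) is recorded as the novel
    exon-2 gain; any other unmatched intron flags the gene unresolved.
    Two introns claiming one slot raise :class:`ProjectionError`.
    """
    if len(reference_profile.introns) != N_ANCESTRAL_INTRONS:
        raise ValueError(
            f"reference gene must have {N_ANCESTRAL_INTRONS} introns, "
            f"got {len(reference_profile.introns)}"
        )
    gene_row = _aligned_row(alignment, profile.gene_id)
    ref_row = _aligned_row(alignment, reference_profile.gene_id)
    ref_marks = _intron_columns(reference_profile, ref_row)
    gene_marks = _intron_columns(profile, gene_row)

    present = [False] * N_ANCESTRAL_INTRONS
    slot_of: dict[int, int] = {}
    unmatched: list[tuple[int, int]] = []
    for gi, (col, phase) in enumerate(gene_marks):
        candidates = [
            k
            for k, (ref_col, ref_phase) in enumerate(ref_marks)
            if phase == ref_phase and abs(col - ref_col) <= tolerance
        ]
        if not candidates:
            unmatched.append((col, phase))
            continue
        candidates.sort(key=lambda k: (abs(col - ref_marks[k][0]), k))
        best = candidates[0]
        if len(candidates) > 1 and abs(col - ref_marks[candidates[1]][0]) == abs(
            col - ref_marks[best][0]
        ):
            raise ProjectionError(
                f"{profile.gene_id}: intron at column {col} matches ancestral "
                f"slots {best + 1} and {candidates[1] + 1} equally well"
            )
        if best in slot_of:
            raise ProjectionError(
                f"{profile.gene_id}: two introns map to ancestral slot {best + 1}"
            )
        slot_of[best] = gi
        present[best] = True

    exon2_lo = ref_marks[0][0]
    exon2_hi = ref_marks[1][0]
    novel = False
    unresolved = False
    for col, phase in unmatched:
        if not novel and exon2_lo <= col <= exon2_hi:
            novel = True
        else:
            unresolved = True
    return StructureCode(
        gene_id=profile.gene_id,
        ancestral_intron_present=tuple(present),
        novel_exon2_intron=novel,
        unresolved=unresolved,
    )


# ------------------------------------------------------- event classification


def classify_events(code: StructureCode) -> list[StructureEvent]:
    """Decompose a structure code into Type 1/2/3 events.

    Maximal runs of consecutively lost ancestral introns are split greedily
    from the 5' end: pairs become Type 2 fusions, a remainder becomes
    Type 1.  Runs longer than two introns exceed what the family's event
    taxonomy anticipates and are flagged with a warning before being
    decomposed the same way.  The novel exon-2 intron adds one Type 3 gain.
    """
    if code.unresolved:
        raise ValueError(f"{code.gene_id}: cannot classify an unresolved structure")
    events: list[StructureEvent] = []
    lost = code.lost_introns
    runs: list[list[int]] = []
    for k in lost:
        if runs and k == runs[-1][-1] + 1:
            runs[-1].append(k)
        else:
            runs.append([k])
    for run in runs:
        if len(run) > 2:
            warnings.warn(
                f"{code.gene_id}: {len(run)} consecutive introns lost "
                f"(run {run[0]}..{run[-1]}); decomposing greedily",
                stacklevel=2,
            )
        i = 0
        while len(run) - i >= 2:
            events.append(StructureEvent(EventType.TYPE2, (run[i], run[i + 1])))
            i += 2
        if len(run) - i == 1:
            events.append(StructureEvent(EventType.TYPE1, (run[i],)))
    if code.novel_exon2_intron:
        events.append(StructureEvent(EventType.TYPE3, (2,)))
    return events


# --------------------------------------------------------------- state coding


def encode_character_state(code: StructureCode) -> CharacterState:
    """Map a structure code into the 19-state vocabulary.

    Structures outside the vocabulary (several simultaneous losses, a gain
    combined with losses, or unresolved projections) are coded as the
    unknown state rather than force-fit.  The two animal outgroup states
    are never produced from plant structure codes.
    """
    if code.unresolved:
        return CharacterState.UNKNOWN
    lost = code.lost_introns
    if code.novel_exon2_intron:
        if not lost:
            return CharacterState.EXON2_INSERTION
        return CharacterState.UNKNOWN
    if not lost:
        return CharacterState.FULL_14_EXON
    if len(lost) == N_ANCESTRAL_INTRONS:
        return CharacterState.INTRONLESS
    if len(lost) == 1:
        return _SINGLE_LOSS_STATES[lost[0]]
    return CharacterState.UNKNOWN


def state_to_code(state: CharacterState, gene_id: str = "ancestor") -> Optional[StructureCode]:
    """Canonical structure code for a decodable state, or ``None`` for the
    animal and unknown states (which carry no plant intron-set meaning)."""
    if state is CharacterState.FULL_14_EXON:
        return StructureCode(gene_id, (True,) * N_ANCESTRAL_INTRONS)
    if state is CharacterState.INTRONLESS:
        return StructureCode(gene_id, (False,) * N_ANCESTRAL_INTRONS)
    if state is CharacterState.EXON2_INSERTION:
        return StructureCode(gene_id, (True,) * N_ANCESTRAL_INTRONS, novel_exon2_intron=True)
    for k, single in _SINGLE_LOSS_STATES.items():
        if state is single:
            present = [True] * N_ANCESTRAL_INTRONS
            present[k - 1] = False
            return StructureCode(gene_id, tuple(present))
    return None
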