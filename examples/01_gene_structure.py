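"""Intron structure analysis: profiles, projection, events, state coding.

Builds the 14-exon reference gene and two derived structures, projects
their introns onto a shared protein alignment, and prints the inferred
losses/gains, the Type 1/2/3 event decomposition, and the single-letter
structure character used for ancestral reconstruction.
"""

from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from genefam.simulate import PROTEIN_LENGTH, _build_gene_model, ancestral_gene_model
from genefam.structure import (
    classify_events,
    compute_intron_profile,
    encode_character_state,
    project_introns,
)

reference = ancestral_gene_model()
# one gene lost introns 3 and 4 (a double exon fusion), one gained the
# novel exon-2 intron
fused = _build_gene_model("fused_gene", [k not in (3, 4) for k in range(1, 14)], False, [])
gained = _build_gene_model("gained_gene", [True] * 13, True, [])

seq = "M" * PROTEIN_LENGTH  # identical proteins -> trivially gap-free MSA
alignment = MultipleSeqAlignment(
    [SeqRecord(Seq(seq), id=g.gene_id, description="") for g in (reference, fused, gained)]
)

ref_profile = compute_intron_profile(reference)
print(f"reference: {len(ref_profile.introns)} introns, phases {ref_profile.phases}")

for gene in (fused, gained):
    profile = compute_intron_profile(gene)
    code = project_introns(profile, alignment, ref_profile)
    events = classify_events(code)
    state = encode_character_state(code)
    print(
        f"{gene.gene_id}: {len(profile.introns)} introns, "
        f"lost {code.lost_introns or 'none'}, "
        f"novel exon-2 intron: {code.novel_exon2_intron}, "
        f"events {[f'{e.event_type.value}{e.intron_indices}' for e in events]}, "
        f"state '{state.value}'"
    )

# The state letter condenses each structure for parsimony: 'a' is the full
# 14-exon architecture, single losses map to b..n, the exon-2 gain to 'p'.
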