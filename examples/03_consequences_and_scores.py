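"""Annotate lesions into protein consequences and genotype scores.

Shows the full scoring spectrum: a frameshift (01), a whole-exon skip from
a lost splice acceptor (02), a 7-residue deletion (04), a single missense
(05) and an untouched allele (06).
"""

from g0mosaic import annotate_consequence, assign_score
from g0mosaic.calling import DnaLesion
from g0mosaic.fixtures import (
    EXON3_LYS145_CODON_START,
    EXON3_MET141_DELETION,
    exon3_local_model,
    three_exon_model,
)

e3 = exon3_local_model()
splice = three_exon_model(middle_codons=41)
acc = splice.acceptor_interval(splice.exons[1])


def lesion(model, events, **flags):
    return DnaLesion(
        allele_id=model.allele_id,
        events=tuple(events),
        net_indel=sum(len(i) - len(d) for _, d, i in events),
        window=(0, len(model.sequence)),
        window_covered=True,
        informative=True,
        **flags,
    )


cases = [
    ("1-bp deletion", e3, lesion(e3, [(30, e3.sequence[30], "")])),
    (
        "acceptor loss, 41-aa exon",
        splice,
        lesion(
            splice,
            [(acc[0] - 1, splice.sequence[acc[0] - 1 : acc[1] + 1], "")],
            disrupts_acceptor=True,
        ),
    ),
    (
        "21-bp deletion",
        e3,
        lesion(e3, [(EXON3_MET141_DELETION[0], e3.sequence[slice(*EXON3_MET141_DELETION)], "")]),
    ),
    ("AAA->ATA missense", e3, lesion(e3, [(EXON3_LYS145_CODON_START + 1, "A", "T")])),
    ("no change", e3, lesion(e3, [])),
]

for label, model, les in cases:
    c = annotate_consequence(les, model)
    print(f"{label:<26} {c.kind:<17} {c.hgvs_p:<28} aa_changes={c.aa_changes:<3} score {assign_score(c)}")

print(
    "\nScores grade the encoded amino acid lesion: 01 frameshift/nonsense,"
    "\n02 >20 aa, 03 11-20 aa, 04 6-10 aa, 05 1-5 aa, 06 unchanged."
)
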