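"""Enumerate microhomology-mediated deletion products at the exon 6 cut.

Lists every deletion supported by a >= 2 bp direct repeat whose interval can
be placed over the cut, with its repeat, frame status, simulator weight and
protein consequence.  The stereotyped in-frame 3/9/12-bp deletions removing
1, 3 and 4 residues from the Gly269-Gly273 di-arginine loop dominate.
"""

from g0mosaic import annotate_consequence, enumerate_mmej
from g0mosaic.calling import DnaLesion
from g0mosaic.fixtures import EXON6_LOCAL_CUT, exon6_local_model

model = exon6_local_model()
products = enumerate_mmej(model.sequence, EXON6_LOCAL_CUT, min_microhomology=2, max_deletion=12)

print(f"reference: {model.sequence}  (cut at inter-base {EXON6_LOCAL_CUT})")
print(f"{'del bp':>6}  {'repeat':<8} {'frame':<9} {'weight':>6}  consequence")
for p in products:
    if p.in_frame:
        lesion = DnaLesion(
            allele_id=model.allele_id,
            events=((p.deleted_interval[0], model.sequence[slice(*p.deleted_interval)], ""),),
            net_indel=-p.deletion_size,
            window=(0, len(model.sequence)),
            window_covered=True,
            informative=True,
        )
        c = annotate_consequence(lesion, model)
        desc = f"{c.hgvs_p} ({c.aa_changes} aa)"
        frame = "in-frame"
    else:
        desc, frame = "frameshift", "shifted"
    print(f"{p.deletion_size:>6}  {p.repeat_seq:<8} {frame:<9} {p.weight:>6.3f}  {desc}")

print(
    "\nWeights are the simulator's relative draw probabilities"
    " (microhomology length x exp(-deletion/20), normalised)."
)
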