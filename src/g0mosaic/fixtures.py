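"""Reconstructed reference fixtures for the exon 6 and exon 3 target regions.

The full X. laevis adprhl1 locus sequence is not machine-readable, so these
fixtures pin only what is printed: the exon 6 spacer/PAM and 15-bp variant
window (whose frame is anchored so the window translates to the wild-type
peptide 269GGRRG273), the 264SSEGRGGRRGH274 residue numbering, the exon
lengths used in whole-exon codon arithmetic, and the exon 3 residues around
Met141..Gly147 (with Lys145 encoded AAA so the documented missense is a
single middle-base change).  All other bases — intron flanks, homeolog
SNPs, filler codons — are synthetic and deterministic.
"""

from __future__ import annotations

from .gene_model import Exon, GeneModel

# -- printed anchors -----------------------------------------------------------

EXON6_SPACER = "GAGGGAAGAGGGGGAAGAAG"
EXON6_PAM = "AGG"
EXON6_WINDOW_SEQ = "GGGGGAAGAAGAGGA"  # 15 bp including the PAM
EXON6_WT_PEPTIDE = "GGRRG"  # residues 269-273

# 24-nt local CDS: spacer + PAM + one base, frame 0, residues 266-273 (EGRGGRRG)
EXON6_LOCAL_SEQ = EXON6_SPACER + EXON6_PAM + "A"
EXON6_LOCAL_WINDOW = (9, 24)
EXON6_LOCAL_CUT = 17  # 3 bp 5' of the PAM at offset 20

# simple unambiguous reverse-translation table (synthetic filler codons)
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGA",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCA", "Q": "CAA", "R": "AGA", "S": "TCA", "T": "ACA", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}


def reverse_translate(peptide: str) -> str:
    """Deterministic stop-free codons for synthetic fixture construction."""
    return "".join(_CODON[a] for a in peptide)


def exon6_local_model(allele_id: str = "S") -> GeneModel:
    """The 24-nt exon 6 local CDS reconstructed from the printed spacer, PAM
    and variant window; single exon, residues numbered 266-273."""
    return GeneModel(
        allele_id=allele_id,
        sequence=EXON6_LOCAL_SEQ,
        exons=(Exon("e6", 0, len(EXON6_LOCAL_SEQ)),),
        residue_offset=265,
    )


# -- synthetic exon 6 amplicon (intron / 69-nt exon / intron) ------------------

_INTRON5 = "GTTTTCGGTGGTCGGCTGACGTGACTGCACACTAGTATGCATTTCTGAGTTAATCAAGAG"
_INTRON3 = "GTATTCTTGAATGTCTGTAGCCAGACCGGGCTCCTGAAGACTTATCTGGGTACGTAGAAT"

# residues 259-265 then the printed core (266-273) then 274-281 (His274 pinned)
_EXON6_UP_PEPTIDE = "TLDKQSS"  # ...Ser264 Ser265
_EXON6_DOWN_PEPTIDE = "IKELNVD"  # after His274
_EXON6_EXON_SEQ = (
    reverse_translate(_EXON6_UP_PEPTIDE)  # 21 nt, residues 259-265
    + EXON6_LOCAL_SEQ  # 24 nt, residues 266-273
    + "CAT"  # His274
    + reverse_translate(_EXON6_DOWN_PEPTIDE)  # residues 275-281
)

# homeolog SNP positions (within the introns only; two inside the first 40 nt
# so the 5'-identity chimera rule can discriminate S from L)
_L_SNPS_5 = {5: "A", 12: "T", 23: "C", 38: "A"}
_L_SNPS_3 = {10: "C", 25: "T", 40: "A"}


def _amplicon_sequence(allele_id: str) -> str:
    i5, i3 = _INTRON5, _INTRON3
    if allele_id == "L":
        i5 = "".join(_L_SNPS_5.get(i, b) for i, b in enumerate(i5))
        i3 = "".join(_L_SNPS_3.get(i, b) for i, b in enumerate(i3))
    return i5 + _EXON6_EXON_SEQ + i3


def exon6_amplicon_model(allele_id: str = "S") -> GeneModel:
    """A synthetic ~190-bp genomic amplicon around exon 6 for one homeolog.

    The 69-nt exon encodes residues 259-281 with the printed core at
    266-273; S and L differ only at a few intron positions, emulating
    homeolog divergence while sharing the gRNA site.
    """
    if allele_id not in ("S", "L"):
        raise ValueError("allele_id must be 'S' or 'L'")
    seq = _amplicon_sequence(allele_id)
    exon_start = len(_INTRON5)
    return GeneModel(
        allele_id=allele_id,
        sequence=seq,
        exons=(Exon("e6", exon_start, exon_start + len(_EXON6_EXON_SEQ)),),
        residue_offset=258,
    )


def exon6_amplicon_models() -> list[GeneModel]:
    return [exon6_amplicon_model("S"), exon6_amplicon_model("L")]


def exon6_amplicon_window(model: GeneModel) -> tuple[int, int]:
    """The 15-bp PAM-anchored variant window in amplicon coordinates."""
    start = model.sequence.index(EXON6_WINDOW_SEQ)
    return (start, start + len(EXON6_WINDOW_SEQ))


# -- synthetic exon 3 local CDS ------------------------------------------------

# 41 residues (121-161); pinned: Met141..Gly147 = MEDSKPG with Lys145 = AAA
_EXON3_PEPTIDE = "VQERLGTHFNAYWSCIDQL" + "A" + "MEDSKPG" + "T" + "RHLVNEFYSWQCI"
assert len(_EXON3_PEPTIDE) == 41


def exon3_local_model(allele_id: str = "S") -> GeneModel:
    """Synthetic 123-nt exon 3 local CDS: 41 codons, residues 121-161."""
    seq = reverse_translate(_EXON3_PEPTIDE)
    return GeneModel(
        allele_id=allele_id,
        sequence=seq,
        exons=(Exon("e3", 0, len(seq)),),
        residue_offset=120,
    )


EXON3_MET141_DELETION = (60, 81)  # codons 141-147, a 21-bp in-frame deletion
EXON3_LYS145_CODON_START = 72  # AAA; middle base -> T gives Ile


# -- multi-exon model for splice-assumption tests ------------------------------

def three_exon_model(
    allele_id: str = "S", middle_codons: int = 41
) -> GeneModel:
    """Synthetic three-exon gene with a whole-codon middle exon.

    Used to exercise the splice assumptions: losing the middle exon's
    acceptor skips ``middle_codons`` residues; losing its donor retains the
    following intron.
    """
    filler = "GTHLVQERAFNDYWSCIKMP"
    pep1 = (filler * 2)[:10]
    pep2 = (filler * 3)[:middle_codons]
    pep3 = (filler * 2)[10:20]
    e1, e2, e3 = (reverse_translate(p) for p in (pep1, pep2, pep3))
    intron1 = "GT" + "ATCTTCAACTGCATTCAGTTCTTACT" + "AG"
    intron2 = "GT" + "TCAGATTGGTACCATCTTGGTATACA" + "AG"
    seq = e1 + intron1 + e2 + intron2 + e3
    s1 = 0
    s2 = len(e1) + len(intron1)
    s3 = s2 + len(e2) + len(intron2)
    return GeneModel(
        allele_id=allele_id,
        sequence=seq,
        exons=(
            Exon("e1", s1, len(e1)),
            Exon("e2", s2, s2 + len(e2)),
            Exon("e3", s3, s3 + len(e3)),
        ),
    )


def two_exon_arithmetic_model(lengths: tuple[int, ...] = (126, 141)) -> GeneModel:
    """Whole-codon exon arithmetic fixture: exons of the given bp lengths
    joined by short introns; total codons = sum(lengths) / 3."""
    filler = "GTHLVQERAFNDYWSCIKMP"
    parts, exons, pos = [], [], 0
    for i, n in enumerate(lengths):
        if n % 3:
            raise ValueError(f"exon length {n} is not a whole number of codons")
        pep = (filler * (n // 3 // len(filler) + 1))[: n // 3]
        exon_seq = reverse_translate(pep)
        exons.append(Exon(f"x{i + 1}", pos, pos + n))
        parts.append(exon_seq)
        if i < len(lengths) - 1:
            intron = "GT" + "CATTAGATCCAATGTT" + "AG"
            parts.append(intron)
            pos += n + len(intron)
        else:
            pos += n
    return GeneModel(
        allele_id="S",
        sequence="".join(parts),
        exons=tuple(exons),
    )
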