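"""gRNA definitions, target-site location, the seed-match activity rule and
the Cas9 cut position.

SpCas9 requires an NGG protospacer-adjacent motif (PAM) immediately 3' of the
protospacer and cleaves bluntly 3 bp 5' of the PAM.  A perfect match of the
8-10 PAM-proximal spacer bases (the seed) is required for cleavage; a single
seed mismatch inactivates the guide, which is what makes the single- and
double-mismatch control guides in the bundled table useful negative controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .gene_model import GeneModel

IUPAC = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"), "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

CUT_OFFSET_FROM_PAM = 3  # canonical blunt SpCas9 cut, 3 bp 5' of the PAM


class GuideError(ValueError):
    pass


def _bases_compatible(pattern_char: str, base: str) -> bool:
    try:
        return base in IUPAC[pattern_char]
    except KeyError:
        raise GuideError(f"invalid IUPAC character {pattern_char!r}") from None


@dataclass(frozen=True)
class GuideRNA:
    """A guide: name, 18-25 nt spacer (5'->3'), PAM pattern, intended orientation."""

    name: str
    spacer: str
    pam_pattern: str = "NGG"
    intended_orientation: str = "forward"

    def __post_init__(self) -> None:
        if not 18 <= len(self.spacer) <= 25:
            raise GuideError(
                f"{self.name}: spacer length {len(self.spacer)} outside [18, 25]"
            )
        for char in self.spacer + self.pam_pattern:
            if char not in IUPAC:
                raise GuideError(f"{self.name}: invalid IUPAC character {char!r}")
        if self.intended_orientation not in ("forward", "reverse"):
            raise GuideError(
                f"{self.name}: orientation must be 'forward' or 'reverse'"
            )


@dataclass(frozen=True)
class TargetSite:
    """A located protospacer/PAM with its cut position.

    ``cut_position`` is an inter-base index in genomic (plus-strand)
    coordinates: the cut lies between positions ``cut_position - 1`` and
    ``cut_position``.  ``mismatch_positions`` are 1-based spacer positions
    counted from the spacer 5' end.
    """

    guide: GuideRNA
    allele_id: str
    strand: str
    protospacer_interval: tuple[int, int]
    pam_interval: tuple[int, int]
    cut_position: int
    mismatch_positions: tuple[int, ...] = field(default=())


def _scan_strand(
    guide: GuideRNA, seq: str, max_mismatches: int
) -> list[tuple[int, tuple[int, ...]]]:
    """All start offsets where the spacer (+PAM) matches with <= k substitutions."""
    spacer, pam = guide.spacer, guide.pam_pattern
    L, P = len(spacer), len(pam)
    out = []
    for start in range(0, len(seq) - L - P + 1):
        if not all(
            _bases_compatible(pam[j], seq[start + L + j]) for j in range(P)
        ):
            continue
        mismatches = tuple(
            i + 1
            for i in range(L)
            if not _bases_compatible(spacer[i], seq[start + i])
        )
        if len(mismatches) <= max_mismatches:
            out.append((start, mismatches))
    return out


def locate_target(
    guide: GuideRNA, model: GeneModel, max_mismatches: int = 0
) -> list[TargetSite]:
    """All sites on both strands where the spacer aligns with <= k substitutions
    and the PAM pattern matches immediately 3' of the protospacer.

    Returns an empty list (not an error) when the guide has no site.
    """
    if max_mismatches < 0:
        raise GuideError("max_mismatches must be >= 0")
    seq = model.sequence
    L, P = len(guide.spacer), len(guide.pam_pattern)
    sites: list[TargetSite] = []
    for start, mismatches in _scan_strand(guide, seq, max_mismatches):
        sites.append(
            TargetSite(
                guide=guide,
                allele_id=model.allele_id,
                strand="+",
                protospacer_interval=(start, start + L),
                pam_interval=(start + L, start + L + P),
                cut_position=start + L - CUT_OFFSET_FROM_PAM,
                mismatch_positions=mismatches,
            )
        )
    rc = str(Seq(seq).reverse_complement())
    n = len(seq)
    for start, mismatches in _scan_strand(guide, rc, max_mismatches):
        # map [start, start+L+P) on the reverse strand back to plus-strand coords
        ps_start, ps_end = n - (start + L), n - start
        pam_start, pam_end = n - (start + L + P), n - (start + L)
        sites.append(
            TargetSite(
                guide=guide,
                allele_id=model.allele_id,
                strand="-",
                protospacer_interval=(ps_start, ps_end),
                pam_interval=(pam_start, pam_end),
                cut_position=ps_start + CUT_OFFSET_FROM_PAM,
                mismatch_positions=mismatches,
            )
        )
    sites.sort(key=lambda s: (s.protospacer_interval, s.strand))
    return sites


def cut_position(site: TargetSite) -> int:
    """Blunt cut 3 bp 5' of the PAM, as an inter-base genomic index.

    Forward and reverse sites that are reverse complements of each other give
    the same physical cut point.  The 3-bp distance is PAM-relative, so 21-22
    nt spacers cut at the same PAM offset as 20-mers.
    """
    return site.cut_position


def predict_activity(site: TargetSite, seed_length: int = 10) -> str:
    """``"active"`` unless any recorded mismatch falls inside the PAM-proximal
    seed (the 3'-terminal ``seed_length`` spacer positions)."""
    L = len(site.guide.spacer)
    if seed_length > L:
        raise GuideError(f"seed_length {seed_length} exceeds spacer length {L}")
    seed_start = L - seed_length + 1  # 1-based spacer position where the seed begins
    inactive = any(pos >= seed_start for pos in site.mismatch_positions)
    return "inactive" if inactive else "active"


# -- bundled guide tables ------------------------------------------------------
# The published tyrosinase-control and adprhl1 guide reagents; spacer 5'->3',
# PAM as printed, direction "forward" (->) or "reverse" (<-) on the locus.

def _g(name: str, spacer: str, direction: str, pam: str) -> GuideRNA:
    return GuideRNA(name=name, spacer=spacer, pam_pattern=pam,
                    intended_orientation=direction)


TYROSINASE_GUIDES: dict[str, GuideRNA] = {
    g.name: g
    for g in [
        _g("tyra-T", "GGGTCGATGATAGAGAGGAC", "forward", "TGG"),
        _g("tyrb-T", "GGCCCGTAGCAGAGCTGGTG", "reverse", "AGG"),
    ]
}

PRINCIPAL_GUIDES: dict[str, GuideRNA] = {
    g.name: g
    for g in [
        _g("gAdprhl1-e3-1S", "GGGATGAGATACTGGAAACC", "forward", "AGG"),
        _g("gAdprhl1-e3-1L", "GGGATGAAATACTGGAAACC", "forward", "AGG"),
        _g("gAdprhl1-e4-1", "GGGCCGTGCACAGGGACCCA", "reverse", "AGG"),
        _g("gAdprhl1-e6-1", "GAGGGAAGAGGGGGAAGAAG", "forward", "AGG"),
        _g("gAdprhl1-e6-1Mis1", "GAGGGAAGAGGGGGAACAAG", "forward", "AGG"),
        _g("gAdprhl1-e6-1Mis2", "GAGGGAAGAGGGGGAACTAG", "forward", "AGG"),
    ]
}

ADDITIONAL_GUIDES: dict[str, GuideRNA] = {
    g.name: g
    for g in [
        _g("gAdprhl1-e1-1", "GGCAAGAAGAGCTAAAACAACT", "forward", "TGG"),
        _g("gAdprhl1-e1-2", "GGTGAGACTAGTGATTCCGCTG", "reverse", "TGG"),
        _g("gAdprhl1-e2-1", "GGCACACCCCATTCAATGAAAA", "forward", "AGG"),
        _g("gAdprhl1-i2-1L", "GGAAAGCACTTAGTGACCAG", "reverse", "TGG"),
        _g("gAdprhl1-i2-2L", "GGGAATGTAATAAAAATTAG", "reverse", "TGG"),
        _g("gAdprhl1-e4-2S", "GGAGAAACCACTTGCTCAGTG", "forward", "GGG"),
        _g("gAdprhl1-e4-2L", "GGAAAAACCACTTGTTCAGTG", "forward", "GGG"),
        _g("gAdprhl1-e4-3S", "GGAAGAAGACTATACGGCACA", "forward", "TGG"),
        _g("gAdprhl1-e4-3L", "GGAAGAAGACTATTCGGCACA", "forward", "TGG"),
        _g("gAdprhl1-e5-1S", "GGTTTTATTTTGAAGCCAAG", "forward", "TGG"),
        _g("gAdprhl1-e5-1L", "GGTTTTATTTTGAAACCAAG", "forward", "TGG"),
        _g("gAdprhl1-e7-1S", "GCAGGAGAAGGTGGTGCCAC", "forward", "TGG"),
        _g("gAdprhl1-e7-1L", "GCAGGAGAAGGTGGTGCTAC", "forward", "TGG"),
        _g("gAdprhl1-e7-2S", "GGTGTCTTTATGGATTGCTCTA", "forward", "TGG"),
        _g("gAdprhl1-e7-2L", "GGTGTCTGTATGGATTGCTCTA", "forward", "TGG"),
    ]
}

ALL_GUIDES: dict[str, GuideRNA] = {
    **TYROSINASE_GUIDES,
    **PRINCIPAL_GUIDES,
    **ADDITIONAL_GUIDES,
}
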