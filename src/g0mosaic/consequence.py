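"""Protein-consequence annotation and the 01-06 genotype score.

A DNA lesion is converted into a protein consequence against its gene
model, with two splice assumptions applied before any codon arithmetic:
loss of a splice acceptor is assumed to skip the exon, loss of a splice
donor is assumed to retain the following intron (translated until the first
stop).  Consequences are named in the parenthesised predicted-consequence
HGVS dialect, 3'-normalised, e.g. ``p.(Arg272del)``, ``p.(Gly270_Gly273del)``,
``p.(Lys145Ile)``.

The genotype score grades each allele by the size of the encoded amino acid
lesion:

====  =========================================================
code  meaning
====  =========================================================
 01   inactive mutant: frameshift-stop or nonsense
 02   in-frame mutant, more than 20 amino acid changes
 03   in-frame mutant, 11-20 amino acid changes
 04   in-frame mutant, 6-10 amino acid changes
 05   in-frame mutant, 1-5 amino acid changes
 06   normal amino acid sequence
====  =========================================================

"Amino acid changes" counts substituted + inserted + deleted residues
(a delins counts ``max(deleted, inserted)``).  A lesion combining a
frameshifting event with anything else scores 01: the frameshift dominates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from Bio.SeqUtils import seq3

from .calling import DnaLesion
from .gene_model import Exon, GeneModel, translate

IN_FRAME_KINDS = frozenset(
    {"synonymous", "missense", "inframe_deletion", "inframe_insertion",
     "inframe_delins", "wildtype"}
)


class ConsequenceError(ValueError):
    pass


@dataclass(frozen=True)
class ProteinConsequence:
    kind: str
    aa_changes: int
    hgvs_p: str
    affected_residues: tuple[int, int] | None = None
    truncating: bool = False  # premature stop / lost frame (splice read-through)


@dataclass(frozen=True)
class GenotypeScore:
    code: int

    def __post_init__(self) -> None:
        if self.code not in (1, 2, 3, 4, 5, 6):
            raise ConsequenceError(f"invalid genotype score {self.code}")

    def __int__(self) -> int:
        return self.code

    def __str__(self) -> str:
        return f"{self.code:02d}"


def _aa3(residue: str) -> str:
    return "*" if residue == "*" else seq3(residue)


def _res(pep: str, index0: int, offset: int) -> str:
    return f"{_aa3(pep[index0])}{offset + index0 + 1}"


def hgvs_name(
    ref_pep: str,
    alt_pep: str,
    residue_offset: int = 0,
    *,
    frameshift: bool = False,
) -> str:
    """3'-normalised HGVS protein notation for a reference/alternate peptide pair.

    Handles identity, missense, stop gain, in-frame deletion / insertion /
    delins and frameshift (``p.(Xnnn Yfs*k)``).
    """
    off = residue_offset
    if frameshift:
        p = _common_prefix(ref_pep, alt_pep)
        if p >= len(ref_pep):  # divergence beyond the reference peptide
            return "p.(=)"
        new = alt_pep[p] if p < len(alt_pep) else "*"
        if new == "*":
            return f"p.({_res(ref_pep, p, off)}*)"
        stop = alt_pep.find("*", p)
        k = f"{stop - p + 1}" if stop != -1 else "?"
        return f"p.({_res(ref_pep, p, off)}{_aa3(new)}fs*{k})"

    if ref_pep == alt_pep:
        return "p.(=)"

    stop = alt_pep.find("*")
    if stop != -1 and stop < len(ref_pep) and "*" not in ref_pep[: stop + 1]:
        return f"p.({_res(ref_pep, stop, off)}*)"

    p = _common_prefix(ref_pep, alt_pep)
    s = _common_suffix(ref_pep, alt_pep, p)
    deleted = ref_pep[p : len(ref_pep) - s]
    inserted = alt_pep[p : len(alt_pep) - s]
    if deleted and not inserted:
        if len(deleted) == 1:
            return f"p.({_res(ref_pep, p, off)}del)"
        return f"p.({_res(ref_pep, p, off)}_{_res(ref_pep, p + len(deleted) - 1, off)}del)"
    if inserted and not deleted:
        left = _res(ref_pep, p - 1, off)
        right = _res(ref_pep, p, off)
        ins3 = "".join(_aa3(a) for a in inserted)
        return f"p.({left}_{right}ins{ins3})"
    if len(deleted) == 1 and len(inserted) == 1:
        return f"p.({_res(ref_pep, p, off)}{_aa3(inserted)})"
    span = (
        _res(ref_pep, p, off)
        if len(deleted) == 1
        else f"{_res(ref_pep, p, off)}_{_res(ref_pep, p + len(deleted) - 1, off)}"
    )
    ins3 = "".join(_aa3(a) for a in inserted)
    return f"p.({span}delins{ins3})"


def _common_prefix(a: str, b: str) -> int:
    p = 0
    while p < len(a) and p < len(b) and a[p] == b[p]:
        p += 1
    return p


def _common_suffix(a: str, b: str, prefix: int) -> int:
    s = 0
    while (
        s < len(a) - prefix
        and s < len(b) - prefix
        and a[len(a) - 1 - s] == b[len(b) - 1 - s]
    ):
        s += 1
    return s


# -- CDS projection of events --------------------------------------------------

def _coding_positions(model: GeneModel) -> list[int]:
    positions: list[int] = []
    for exon in model.exons:
        positions.extend(range(exon.start, exon.end))
    positions = positions[model.cds_start_offset :]
    return positions[: len(positions) - len(positions) % 3]


def _apply_events_to_cds(
    model: GeneModel, events: Sequence[tuple[int, str, str]]
) -> tuple[str, int]:
    """Mutated CDS and the net coding indel after projecting genomic events.

    Events entirely inside introns (away from splice dinucleotides) do not
    change the protein and are dropped by the projection.
    """
    positions = _coding_positions(model)
    index_of = {pos: i for i, pos in enumerate(positions)}
    bases: list[str] = [model.sequence[pos] for pos in positions]
    inserts: dict[int, str] = {}
    deleted_idx: set[int] = set()
    for pos, deleted, inserted in events:
        if deleted and inserted:  # substitution / delins block
            for k, alt_base in enumerate(inserted[: len(deleted)]):
                idx = index_of.get(pos + k)
                if idx is not None:
                    bases[idx] = alt_base
            for k in range(len(inserted), len(deleted)):
                idx = index_of.get(pos + k)
                if idx is not None:
                    deleted_idx.add(idx)
            if len(inserted) > len(deleted):
                idx = index_of.get(pos + len(deleted) - 1)
                if idx is not None:
                    inserts[idx + 1] = inserts.get(idx + 1, "") + inserted[len(deleted):]
        elif deleted:
            for k in range(len(deleted)):
                idx = index_of.get(pos + k)
                if idx is not None:
                    deleted_idx.add(idx)
        elif inserted:
            idx = index_of.get(pos)
            if idx is not None and index_of.get(pos - 1) is not None:
                inserts[idx] = inserts.get(idx, "") + inserted
    out: list[str] = []
    for i, base in enumerate(bases):
        if i in inserts:
            out.append(inserts[i])
        if i not in deleted_idx:
            out.append(base)
    if len(bases) in inserts:
        out.append(inserts[len(bases)])
    alt_cds = "".join(out)
    return alt_cds, len(alt_cds) - len(bases)


# -- splice consequences -------------------------------------------------------

def _affected_exon(model: GeneModel, lesion: DnaLesion, acceptor: bool) -> Exon:
    events = lesion.events + lesion.out_of_window_events
    for exon in model.exons:
        interval = (
            model.acceptor_interval(exon) if acceptor else model.donor_interval(exon)
        )
        if interval is None:
            continue
        for pos, deleted, _ in events:
            if deleted and pos < interval[1] and pos + len(deleted) > interval[0]:
                return exon
    raise ConsequenceError("no splice-disrupting event found for flagged lesion")


def _exon_skip(model: GeneModel, exon: Exon) -> ProteinConsequence:
    from .gene_model import residues_of_span

    if exon.length % 3 != 0:
        # skipping shifts the downstream frame: inactive
        first, _, _ = residues_of_span(model, exon.start, exon.start + 1)
        return ProteinConsequence(
            kind="frameshift",
            aa_changes=0,
            hgvs_p=f"p.({_aa3(model.peptide[first - model.residue_offset - 1])}{first}fs*?)",
            affected_residues=None,
            truncating=True,
        )
    first, last, _ = residues_of_span(model, exon.start, exon.end)
    pep = model.peptide
    off = model.residue_offset
    name = (
        f"p.({_res(pep, first - off - 1, off)}_{_res(pep, last - off - 1, off)}del)"
    )
    return ProteinConsequence(
        kind="exon_skip",
        aa_changes=exon.length // 3,
        hgvs_p=name,
        affected_residues=(first, last),
    )


def _intron_retention(model: GeneModel, exon: Exon) -> ProteinConsequence:
    idx = model.exons.index(exon)
    if idx == len(model.exons) - 1:
        raise ConsequenceError("donor of the last exon has no following intron")
    nxt = model.exons[idx + 1]
    intron = model.sequence[exon.end : nxt.start]
    positions = _coding_positions(model)
    upstream = sum(1 for p in positions if p < exon.end)
    prefix = "".join(model.sequence[p] for p in positions[:upstream])
    downstream = "".join(model.sequence[p] for p in positions[upstream:])
    readthrough = prefix + intron + downstream
    pep = translate(readthrough)
    n_prefix_res = len(prefix) // 3  # whole codons before the junction
    intron_region = pep[n_prefix_res : (len(prefix) + len(intron)) // 3 + 1]
    if len(intron) % 3 == 0 and "*" not in intron_region:
        first = model.residue_offset + n_prefix_res
        ref_pep = model.peptide
        name = hgvs_name(ref_pep, pep[: len(ref_pep) + len(intron) // 3], model.residue_offset)
        return ProteinConsequence(
            kind="intron_retention",
            aa_changes=len(intron) // 3,
            hgvs_p=name,
            affected_residues=(first, first + 1),
        )
    # translation runs into the intron and hits a stop or loses frame
    stop = pep.find("*", n_prefix_res if len(prefix) % 3 == 0 else n_prefix_res)
    return ProteinConsequence(
        kind="intron_retention",
        aa_changes=0,
        hgvs_p=f"p.({_res(model.peptide, min(n_prefix_res, len(model.peptide) - 1), model.residue_offset)}fs*{stop - n_prefix_res + 1 if stop != -1 else '?'})",
        affected_residues=None,
        truncating=True,
    )


# -- main annotation -----------------------------------------------------------

def annotate_consequence(lesion: DnaLesion, model: GeneModel) -> ProteinConsequence:
    """Classify a normalised lesion against its gene model.

    Splice flags take precedence: a lost acceptor skips the exon, a lost
    donor retains the following intron.  Otherwise events are projected onto
    the CDS and classified by net indel and codon-level peptide diff; a
    premature stop anywhere in the mutated CDS is nonsense.
    """
    if lesion.allele_id and lesion.allele_id != model.allele_id:
        raise ConsequenceError(
            f"lesion allele {lesion.allele_id!r} does not match model {model.allele_id!r}"
        )
    if lesion.disrupts_acceptor:
        return _exon_skip(model, _affected_exon(model, lesion, acceptor=True))
    if lesion.disrupts_donor:
        return _intron_retention(model, _affected_exon(model, lesion, acceptor=False))

    events = list(lesion.events) + list(lesion.out_of_window_events)
    alt_cds, net = _apply_events_to_cds(model, events)
    ref_pep = model.peptide
    off = model.residue_offset

    if net % 3 != 0:
        alt_pep = translate(alt_cds)
        name = hgvs_name(ref_pep, alt_pep, off, frameshift=True)
        kind = "nonsense" if name.endswith("*)") else "frameshift"
        return ProteinConsequence(kind=kind, aa_changes=0, hgvs_p=name, truncating=True)

    alt_pep = translate(alt_cds)
    ref_stop = ref_pep.find("*")
    body = alt_pep if ref_stop == -1 else alt_pep  # compare full peptides
    premature = body.find("*")
    if premature != -1 and (ref_stop == -1 or premature < ref_stop):
        return ProteinConsequence(
            kind="nonsense",
            aa_changes=0,
            hgvs_p=f"p.({_res(ref_pep, min(premature, len(ref_pep) - 1), off)}*)",
            truncating=True,
        )

    p = _common_prefix(ref_pep, alt_pep)
    s = _common_suffix(ref_pep, alt_pep, p)
    deleted = ref_pep[p : len(ref_pep) - s]
    inserted = alt_pep[p : len(alt_pep) - s]
    name = hgvs_name(ref_pep, alt_pep, off)

    if not deleted and not inserted:
        ref_cds = "".join(model.sequence[p] for p in _coding_positions(model))
        kind = "synonymous" if alt_cds != ref_cds else "wildtype"
        return ProteinConsequence(kind=kind, aa_changes=0, hgvs_p="p.(=)")
    if deleted and not inserted:
        return ProteinConsequence(
            kind="inframe_deletion",
            aa_changes=len(deleted),
            hgvs_p=name,
            affected_residues=(off + p + 1, off + p + len(deleted)),
        )
    if inserted and not deleted:
        return ProteinConsequence(
            kind="inframe_insertion",
            aa_changes=len(inserted),
            hgvs_p=name,
            affected_residues=(off + p, off + p + 1),
        )
    if len(deleted) == 1 and len(inserted) == 1:
        return ProteinConsequence(
            kind="missense",
            aa_changes=1,
            hgvs_p=name,
            affected_residues=(off + p + 1, off + p + 1),
        )
    return ProteinConsequence(
        kind="inframe_delins",
        aa_changes=max(len(deleted), len(inserted)),
        hgvs_p=name,
        affected_residues=(off + p + 1, off + p + len(deleted)),
    )


def assign_score(consequence: ProteinConsequence) -> GenotypeScore:
    """Deterministic 01-06 code for a protein consequence."""
    if consequence.truncating or consequence.kind in ("frameshift", "nonsense"):
        return GenotypeScore(1)
    n = consequence.aa_changes
    if n == 0:
        return GenotypeScore(6)
    if n <= 5:
        return GenotypeScore(5)
    if n <= 10:
        return GenotypeScore(4)
    if n <= 20:
        return GenotypeScore(3)
    return GenotypeScore(2)
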