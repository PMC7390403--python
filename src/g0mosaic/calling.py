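"""Amplicon read lesion calling on homeologous alleles.

Each read is assigned to a homeolog (S or L), aligned, and reduced to a
normalised :class:`DnaLesion`: the set of substitution/indel events inside a
PAM-anchored variant window, with indels right-aligned (3'-shifted) within
repeats so that physically distinct junctions of the same product collapse
to one representation.  Wild-type status follows the peptide-level
definition: a read is wild type iff its realised window sequence translates,
in frame, to the reference window peptide (``GGRRG`` for the exon 6 site) —
so synonymous substitutions inside the window still count as wild type.

Reads carrying N inside the window are uninformative rather than mutant;
reads that do not span the window are uninformative as well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .alignment import AlleleAlignment, make_aligner
from .gene_model import GeneModel, GeneModelError, translate

logger = logging.getLogger(__name__)

TIE_THRESHOLD = 4.0  # score gap at or below one mismatch triggers the 5' rule
FIVE_PRIME_K = 40


class CallingError(ValueError):
    pass


@dataclass(frozen=True)
class AmpliconRead:
    read_id: str
    sequence: str
    qualities: tuple[int, ...] | None = None
    source: str = "sanger_clone"  # sanger_clone | ngs
    orientation: str = "unknown"  # forward | reverse | unknown

    def __post_init__(self) -> None:
        if not self.sequence:
            raise CallingError(f"read {self.read_id}: empty sequence")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise CallingError(f"read {self.read_id}: invalid characters {sorted(bad)}")


@dataclass(frozen=True)
class DnaLesion:
    """Normalised variant events for one read against one allele.

    ``events`` are ``(ref_start, deleted_seq, inserted_seq)`` triples in
    reference coordinates, right-aligned, restricted to the variant window;
    ``out_of_window_events`` keeps the rest for reporting.  ``window_sequence``
    is the read's realised sequence across the window (None when the window
    is not fully covered); ``informative`` is False for uncovered windows and
    for N bases inside the window.
    """

    allele_id: str
    events: tuple[tuple[int, str, str], ...]
    net_indel: int
    window: tuple[int, int]
    window_covered: bool
    window_sequence: str | None = None
    informative: bool = True
    disrupts_acceptor: bool = False
    disrupts_donor: bool = False
    out_of_window_events: tuple[tuple[int, str, str], ...] = field(default=())


def read_fasta(path: str | Path, source: str = "sanger_clone") -> list[AmpliconRead]:
    return [
        AmpliconRead(rec.id, str(rec.seq).upper(), source=source)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def read_fastq(path: str | Path, source: str = "ngs") -> list[AmpliconRead]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = tuple(rec.letter_annotations["phred_quality"])
        reads.append(AmpliconRead(rec.id, str(rec.seq).upper(), quals, source=source))
    return reads


# -- event extraction and normalisation ---------------------------------------

def events_from_alignment(
    aln: AlleleAlignment, reference: str, read: str
) -> list[tuple[int, str, str]]:
    """Raw (ref_start, deleted, inserted) events from an alignment.

    Terminal indels (not flanked by aligned blocks on both sides) are
    coverage artifacts — an unspanned reference tail or clipped read — and
    are excluded; window coverage is judged separately.
    """
    ops = aln.operations
    events: list[tuple[int, str, str]] = []
    for idx, op in enumerate(ops):
        if op.op == "mismatch":
            for k in range(op.length):
                events.append(
                    (op.ref_pos + k, reference[op.ref_pos + k], read[op.read_pos + k])
                )
        elif op.op in ("deletion", "insertion"):
            if idx == 0 or idx == len(ops) - 1:
                continue
            if op.op == "deletion":
                events.append((op.ref_pos, reference[op.ref_pos : op.ref_pos + op.length], ""))
            else:
                events.append((op.ref_pos, "", read[op.read_pos : op.read_pos + op.length]))
    return events


def normalize_events(
    reference: str, events: Iterable[tuple[int, str, str]]
) -> list[tuple[int, str, str]]:
    """Right-align (3'-shift) indels within repeats; idempotent.

    A deletion shifts right while the base entering the junction equals the
    base leaving it; an insertion shifts right while its first base equals
    the next reference base (rotating the inserted string).
    """
    out: list[tuple[int, str, str]] = []
    for pos, deleted, inserted in events:
        if deleted and not inserted:
            L = len(deleted)
            while pos + L < len(reference) and reference[pos] == reference[pos + L]:
                pos += 1
            deleted = reference[pos : pos + L]
        elif inserted and not deleted:
            while pos < len(reference) and inserted[0] == reference[pos]:
                inserted = inserted[1:] + inserted[0]
                pos += 1
        out.append((pos, deleted, inserted))
    out.sort(key=lambda e: (e[0], len(e[1]), e[2]))
    return out


def realize_window(
    reference: str,
    events: Sequence[tuple[int, str, str]],
    window: tuple[int, int],
) -> str:
    """Apply normalised events to the reference restricted to a window.

    Canonical (placement-invariant) reconstruction of the read sequence
    realised across the window: deleted reference positions contribute
    nothing, substituted positions contribute the alternate base, and
    insertions whose junction lies strictly inside the window contribute
    their inserted string.
    """
    ws, we = window
    parts: list[str] = []
    for pos in range(ws, we):
        for q, deleted, inserted in events:
            if not deleted and inserted and q == pos and ws < q < we:
                parts.append(inserted)
        hit = False
        for q, deleted, inserted in events:
            if deleted and q <= pos < q + len(deleted):
                hit = True
                if inserted and pos - q < len(inserted):  # substitution / delins
                    parts.append(inserted[pos - q])
                break
        if not hit:
            parts.append(reference[pos])
    return "".join(parts)


def _event_in_window(event: tuple[int, str, str], window: tuple[int, int]) -> bool:
    pos, deleted, inserted = event
    ws, we = window
    if deleted and inserted:  # substitution / delins
        return pos < we and pos + len(deleted) > ws
    if deleted:
        return pos < we and pos + len(deleted) > ws
    return ws < pos < we  # pure insertion, junction strictly inside


def _splice_flags(
    model: GeneModel, events: Sequence[tuple[int, str, str]]
) -> tuple[bool, bool]:
    acceptor = donor = False
    for exon in model.exons:
        for interval, is_acceptor in (
            (model.acceptor_interval(exon), True),
            (model.donor_interval(exon), False),
        ):
            if interval is None:
                continue
            for pos, deleted, _ in events:
                if deleted and pos < interval[1] and pos + len(deleted) > interval[0]:
                    if is_acceptor:
                        acceptor = True
                    else:
                        donor = True
    return acceptor, donor


def call_lesion(
    aln: AlleleAlignment,
    window: tuple[int, int],
    *,
    reference: str,
    read: str,
    model: GeneModel | None = None,
) -> DnaLesion:
    """Extract the normalised lesion within a reference window.

    Events are right-aligned first and re-tested for window intersection, so
    a deletion whose physical junction lies left of the window but whose
    3'-shifted representation enters it is still captured.
    """
    ws, we = window
    if not (0 <= ws < we <= len(reference)):
        raise CallingError(f"window [{ws}, {we}) outside reference of length {len(reference)}")
    raw = events_from_alignment(aln, reference, read)
    events = normalize_events(reference, raw)
    in_window = tuple(e for e in events if _event_in_window(e, window))
    out_window = tuple(e for e in events if not _event_in_window(e, window))
    span = aln.ref_span
    covered = span[0] <= ws and span[1] >= we
    window_seq = realize_window(reference, events, window) if covered else None
    informative = covered and "N" not in (window_seq or "")
    acceptor = donor = False
    if model is not None:
        acceptor, donor = _splice_flags(model, events)
    net = sum(len(ins) - len(dele) for _, dele, ins in in_window)
    return DnaLesion(
        allele_id=aln.allele_id,
        events=in_window,
        net_indel=net,
        window=window,
        window_covered=covered,
        window_sequence=window_seq,
        informative=informative,
        disrupts_acceptor=acceptor,
        disrupts_donor=donor,
        out_of_window_events=out_window,
    )


# -- wild-type definition ------------------------------------------------------

def is_wildtype_read(
    lesion: DnaLesion, model: GeneModel, window: tuple[int, int] | None = None
) -> bool:
    """Peptide-level wild-type test: the realised window sequence translates
    to the reference window peptide.  Requires a codon-aligned window and a
    covered, informative read."""
    window = window or lesion.window
    ws, we = window
    cmap = model.codon_map()
    if (we - ws) % 3 != 0 or not cmap.is_coding(ws) or cmap.residue_at(ws)[1] != 0:
        raise GeneModelError(f"window [{ws}, {we}) is not codon-aligned")
    if not lesion.window_covered or not lesion.informative:
        return False
    ref_window = model.sequence[ws:we]
    ref_pep = translate(ref_window)
    seq = lesion.window_sequence or ""
    if len(seq) % 3 != 0:
        return False
    try:
        return translate(seq) == ref_pep
    except GeneModelError:  # stray non-ACGT outside N-check
        return False


def reference_window_peptide(model: GeneModel, window: tuple[int, int]) -> str:
    return translate(model.sequence[window[0] : window[1]])


def snap_window_to_codons(model: GeneModel, start: int, end: int) -> tuple[int, int]:
    """Snap a genomic window outward to codon boundaries; records the snap."""
    cmap = model.codon_map()
    while not (cmap.is_coding(start) and cmap.residue_at(start)[1] == 0):
        start -= 1
        if start < 0:
            raise GeneModelError("cannot snap window start to a codon boundary")
    while not (cmap.is_coding(end - 1) and cmap.residue_at(end - 1)[1] == 2):
        end += 1
        if end > len(model.sequence):
            raise GeneModelError("cannot snap window end to a codon boundary")
    logger.debug("window snapped to codon-aligned [%d, %d)", start, end)
    return start, end


# -- allele assignment ---------------------------------------------------------

def _oriented(read: AmpliconRead) -> dict[str, str]:
    fwd = read.sequence
    return {"forward": fwd, "reverse": str(Seq(fwd).reverse_complement())}


def assign_read(
    read: AmpliconRead,
    models: Sequence[GeneModel],
    *,
    tie_threshold: float = TIE_THRESHOLD,
    k: int = FIVE_PRIME_K,
    mode: str = "global",
) -> tuple[str, str]:
    """(allele_id, orientation) for a read against candidate homeolog models.

    The allele with the higher alignment score wins; on near-ties (score gap
    <= ``tie_threshold``, about one mismatch) the call falls back to identity
    over the 5'-terminal ``k`` bases — the rule used to split PCR-chimeric
    reads by the homeolog identity at the 5' end of the product.  Returns
    ``("ambiguous", orientation)`` when that fails too.
    """
    if not models:
        raise CallingError("at least one model required")
    aligner = make_aligner(mode)
    scores: dict[tuple[str, str], float] = {}
    for orientation, seq in _oriented(read).items():
        for model in models:
            scores[(model.allele_id, orientation)] = float(
                aligner.score(model.sequence, seq)
            )
    (best_allele, best_orient), best_score = max(scores.items(), key=lambda kv: kv[1])
    rivals = {
        allele: s
        for (allele, orient), s in scores.items()
        if orient == best_orient and allele != best_allele
    }
    if rivals:
        runner_up, second = max(rivals.items(), key=lambda kv: kv[1])
        if best_score - second <= tie_threshold:
            oriented = _oriented(read)[best_orient]
            def mism(model: GeneModel) -> int:
                ref = model.sequence[:k]
                return sum(a != b for a, b in zip(oriented[:k], ref)) + abs(
                    len(ref) - len(oriented[:k])
                )
            by_model = {m.allele_id: mism(m) for m in models}
            ranked = sorted(by_model.items(), key=lambda kv: kv[1])
            if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
                return "ambiguous", best_orient
            return ranked[0][0], best_orient
    return best_allele, best_orient


def assign_allele(read: AmpliconRead, models: Sequence[GeneModel], **kwargs) -> str:
    return assign_read(read, models, **kwargs)[0]


def orientation_filter(
    reads: Sequence[AmpliconRead], keep: str = "both"
) -> list[AmpliconRead]:
    """Retain reads by mapped orientation; discarded counts are logged.

    ``keep="reverse"`` mirrors counting only reverse-strand reads when the
    gRNA site sits toward the 3' end of the sequenced product.
    """
    if keep not in ("forward", "reverse", "both"):
        raise CallingError(f"keep must be forward/reverse/both, got {keep!r}")
    if keep == "both":
        return list(reads)
    kept = [r for r in reads if r.orientation == keep]
    logger.info(
        "orientation filter keep=%s: retained %d, discarded %d",
        keep, len(kept), len(reads) - len(kept),
    )
    return kept


# -- tabular output ------------------------------------------------------------

def events_to_string(events: Sequence[tuple[int, str, str]]) -> str:
    """VCF-like 1-based POS:REF>ALT triplets, ';'-joined."""
    return ";".join(f"{pos + 1}:{d or '-'}>{i or '-'}" for pos, d, i in events)


def write_calls_tsv(calls: Sequence, path: str | Path) -> pd.DataFrame:
    """Write per-read calls (pipeline ReadCall objects) to TSV."""
    rows = []
    for c in calls:
        rows.append(
            {
                "read_id": c.read_id,
                "allele": c.allele_id,
                "events": events_to_string(c.lesion.events),
                "net_indel": c.lesion.net_indel,
                "wildtype": c.is_wildtype,
                "orientation": c.orientation,
                "kind": c.consequence.kind if c.consequence else "",
                "hgvs_p": c.consequence.hgvs_p if c.consequence else "",
                "score": c.score,
            }
        )
    frame = pd.DataFrame(rows)
    frame.to_csv(path, sep="\t", index=False)
    return frame
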