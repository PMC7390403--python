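"""Pairwise alignment of amplicon reads to reference alleles.

A thin wrapper around :class:`Bio.Align.PairwiseAligner` (affine gaps).
Sanger clone inserts are full amplicons and get end-to-end global alignment;
short NGS reads get semi-global alignment with free end gaps on the
reference, so an unspanned reference tail is not penalised (or called as a
deletion).

The wrapper converts the aligner's coordinate pairs into an explicit
operation list (match/mismatch/insertion/deletion with reference and read
offsets), which is what lesion calling consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from Bio import Align

DEFAULT_SCORES = {
    "match_score": 2.0,
    "mismatch_score": -4.0,
    "open_gap_score": -10.0,
    "extend_gap_score": -1.0,
}

MIN_READ_LENGTH = 20


@dataclass(frozen=True)
class AlignOp:
    """One alignment operation; ``ref_pos``/``read_pos`` are the 0-based
    coordinates where the operation starts."""

    op: str  # match | mismatch | insertion | deletion
    length: int
    ref_pos: int
    read_pos: int


@dataclass(frozen=True)
class AlleleAlignment:
    allele_id: str
    score: float
    operations: tuple[AlignOp, ...]
    ref_length: int
    read_length: int
    mode: str = "global"

    @property
    def ref_span(self) -> tuple[int, int]:
        """Reference interval covered by aligned (non-end-gap) operations."""
        aligned = [o for o in self.operations if o.op in ("match", "mismatch")]
        if not aligned:
            return (0, 0)
        return (aligned[0].ref_pos, aligned[-1].ref_pos + aligned[-1].length)


def make_aligner(mode: str = "global", **overrides) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    scores = {**DEFAULT_SCORES, **overrides}
    for key, value in scores.items():
        setattr(aligner, key, value)
    if mode == "semi_global":
        # free end gaps where the read does not span the reference
        aligner.end_deletion_score = 0.0
    elif mode != "global":
        raise ValueError(f"unknown alignment mode {mode!r}")
    return aligner


def _operations(alignment, ref: str, read: str) -> tuple[AlignOp, ...]:
    """Expand Biopython aligned blocks into match/mismatch/indel operations."""
    ops: list[AlignOp] = []
    ref_blocks, read_blocks = alignment.aligned
    prev_ref_end, prev_read_end = 0, 0
    for (rs, re), (qs, qe) in zip(ref_blocks, read_blocks):
        if rs > prev_ref_end:
            ops.append(AlignOp("deletion", rs - prev_ref_end, prev_ref_end, prev_read_end))
        if qs > prev_read_end:
            ops.append(AlignOp("insertion", qs - prev_read_end, rs, prev_read_end))
        # split the aligned block into runs of match / mismatch
        run_start = 0
        run_is_match = None
        for k in range(re - rs):
            is_match = ref[rs + k] == read[qs + k]
            if run_is_match is None:
                run_is_match = is_match
            elif is_match != run_is_match:
                ops.append(
                    AlignOp(
                        "match" if run_is_match else "mismatch",
                        k - run_start,
                        rs + run_start,
                        qs + run_start,
                    )
                )
                run_start, run_is_match = k, is_match
        if run_is_match is not None:
            ops.append(
                AlignOp(
                    "match" if run_is_match else "mismatch",
                    (re - rs) - run_start,
                    rs + run_start,
                    qs + run_start,
                )
            )
        prev_ref_end, prev_read_end = re, qe
    if len(ref) > prev_ref_end:
        ops.append(AlignOp("deletion", len(ref) - prev_ref_end, prev_ref_end, prev_read_end))
    if len(read) > prev_read_end:
        ops.append(AlignOp("insertion", len(read) - prev_read_end, len(ref), prev_read_end))
    return tuple(ops)


def align_read(
    read_sequence: str,
    reference: str,
    *,
    allele_id: str = "",
    mode: str = "global",
    aligner: Align.PairwiseAligner | None = None,
) -> AlleleAlignment:
    """Optimal pairwise alignment of a read against one reference allele.

    Ties between co-optimal alignments are broken by the aligner's
    deterministic enumeration order; indel placement is standardised later by
    right-normalisation during lesion calling, so the choice does not affect
    called lesions.
    """
    if not read_sequence or not reference:
        raise ValueError("read and reference must be non-empty")
    if len(read_sequence) < MIN_READ_LENGTH:
        warnings.warn(
            f"read of length {len(read_sequence)} < {MIN_READ_LENGTH} nt; "
            "alignment may be unreliable",
            stacklevel=2,
        )
    if aligner is None:
        aligner = make_aligner(mode)
    alignments = aligner.align(reference, read_sequence)
    best = alignments[0]
    return AlleleAlignment(
        allele_id=allele_id,
        score=float(best.score),
        operations=_operations(best, reference, read_sequence),
        ref_length=len(reference),
        read_length=len(read_sequence),
        mode=mode,
    )


def alignment_score(read_sequence: str, reference: str, mode: str = "global") -> float:
    """Score only (cheaper than building the operation list)."""
    return float(make_aligner(mode).score(reference, read_sequence))
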