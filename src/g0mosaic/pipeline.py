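"""End-to-end analysis: reads -> per-read calls -> embryo records -> cohort stats.

The per-read chain is: assign the read to a homeolog (with the 5'-identity
fallback for PCR chimeras), align it (global for Sanger clones, semi-global
for shorter NGS reads), extract the normalised lesion in the PAM-anchored
variant window, annotate the protein consequence with the splice
assumptions, and assign the 01-06 genotype score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .alignment import align_read, make_aligner
from .calling import (
    AmpliconRead,
    DnaLesion,
    assign_read,
    call_lesion,
    is_wildtype_read,
    orientation_filter,
    snap_window_to_codons,
)
from .cohort import (
    AssociationResult,
    CohortSummary,
    EmbryoRecord,
    score_frequencies,
    summarize_embryo,
    wildtype_phenotype_association,
)
from .consequence import ProteinConsequence, annotate_consequence, assign_score
from .gene_model import GeneModel
from .guides import GuideRNA, TargetSite, locate_target


class PipelineError(ValueError):
    pass


@dataclass(frozen=True)
class ReadCall:
    """Everything the pipeline derives from one read."""

    read_id: str
    allele_id: str
    orientation: str
    lesion: DnaLesion
    consequence: ProteinConsequence | None
    score: int
    is_wildtype: bool


def variant_window(
    site: TargetSite, model: GeneModel, length: int = 15, *, snap: bool = True
) -> tuple[int, int]:
    """The PAM-anchored variant window: ``length`` bases ending one base 3'
    of the PAM, snapped outward to codon boundaries when requested."""
    if site.strand == "+":
        end = site.pam_interval[1] + 1
        start = end - length
    else:
        start = site.pam_interval[0] - 1
        end = start + length
    if snap:
        start, end = snap_window_to_codons(model, start, end)
    return start, end


def windows_for_guide(
    guide: GuideRNA, models: Sequence[GeneModel], length: int = 15
) -> dict[str, tuple[int, int]]:
    windows: dict[str, tuple[int, int]] = {}
    for model in models:
        sites = locate_target(guide, model, max_mismatches=0)
        if not sites:
            raise PipelineError(f"guide {guide.name} has no site on {model.allele_id}")
        windows[model.allele_id] = variant_window(sites[0], model, length)
    return windows


def call_reads(
    reads: Sequence[AmpliconRead],
    models: Sequence[GeneModel],
    windows: Mapping[str, tuple[int, int]],
    *,
    mode: str | None = None,
) -> list[ReadCall]:
    """Run the full per-read chain; reads assigned "ambiguous" are skipped.

    ``mode`` defaults per read source: global for Sanger clones, semi-global
    for NGS reads.
    """
    by_id = {m.allele_id: m for m in models}
    aligners = {
        "global": make_aligner("global"),
        "semi_global": make_aligner("semi_global"),
    }
    calls: list[ReadCall] = []
    for read in reads:
        read_mode = mode or ("semi_global" if read.source == "ngs" else "global")
        allele_id, orientation = assign_read(read, models, mode=read_mode)
        if allele_id == "ambiguous":
            continue
        model = by_id[allele_id]
        seq = read.sequence
        if orientation == "reverse":
            from Bio.Seq import Seq

            seq = str(Seq(seq).reverse_complement())
        aln = align_read(
            seq, model.sequence, allele_id=allele_id,
            mode=read_mode, aligner=aligners[read_mode],
        )
        window = windows[allele_id]
        lesion = call_lesion(aln, window, reference=model.sequence, read=seq, model=model)
        if lesion.informative:
            consequence = annotate_consequence(lesion, model)
            score = assign_score(consequence).code
            wildtype = is_wildtype_read(lesion, model)
        else:
            consequence, score, wildtype = None, 0, False
        calls.append(
            ReadCall(
                read_id=read.read_id,
                allele_id=allele_id,
                orientation=orientation,
                lesion=lesion,
                consequence=consequence,
                score=score,
                is_wildtype=wildtype,
            )
        )
    return calls


@dataclass(frozen=True)
class CohortAnalysis:
    records: list[EmbryoRecord]
    summary: CohortSummary
    association: AssociationResult | None


def analyze_cohort(
    reads_by_embryo: Mapping[str, Sequence[AmpliconRead]],
    phenotypes: Mapping[str, str],
    models: Sequence[GeneModel],
    guide: GuideRNA,
    *,
    keep_orientation: str = "both",
    window_length: int = 15,
) -> CohortAnalysis:
    """Genotype every embryo and compute cohort tables plus the wild-type /
    phenotype association (skipped when one phenotype group is empty)."""
    windows = windows_for_guide(guide, models, window_length)
    records: list[EmbryoRecord] = []
    for embryo_id, reads in reads_by_embryo.items():
        reads = orientation_filter(reads, keep_orientation)
        calls = call_reads(reads, models, windows)
        records.append(summarize_embryo(calls, phenotypes[embryo_id], embryo_id))
    summary = score_frequencies(records)
    has_both = any(r.has_defect for r in records) and any(
        not r.has_defect for r in records
    )
    association = wildtype_phenotype_association(records) if has_both else None
    return CohortAnalysis(records=records, summary=summary, association=association)
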