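"""Per-embryo mosaic spectra and cohort-level statistics.

A G0-injected embryo is a mosaic of differently repaired alleles; each
embryo is summarised as its distinct in-window allele sequences with counts
and genotype scores, a wild-type-presence flag, and its heart phenotype
class.  At the cohort level the package tabulates genotype-score
frequencies (overall and split defect vs normal) and tests the association
between wild-type-allele presence and a normal heart with a one-sided
Fisher exact test computed from the hypergeometric distribution — no
asymptotic approximation, appropriate at n = 16 embryos.

Exactly one pre-specified association test is run per cohort; no
multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

PHENOTYPES = ("inert_ventricle", "thin_wall_ventricle", "other_malformation", "normal")
DEFECT_PHENOTYPES = frozenset(PHENOTYPES[:3])


class CohortError(ValueError):
    pass


@dataclass(frozen=True)
class EmbryoRecord:
    """Mosaic allele spectrum and phenotype for one embryo.

    ``alleles`` maps each distinct (allele_id, in-window sequence) group to
    ``(count, score)``; ``score_tally`` counts informative reads per
    genotype code.
    """

    embryo_id: str
    phenotype: str
    alleles: tuple[tuple[str, str, int, int], ...]  # (allele_id, window_seq, count, score)
    distinct_sequences: int
    wildtype_present: bool
    score_tally: Mapping[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise CohortError(
                f"embryo {self.embryo_id}: unknown phenotype {self.phenotype!r}"
            )

    @property
    def has_defect(self) -> bool:
        return self.phenotype in DEFECT_PHENOTYPES

    @property
    def n_reads(self) -> int:
        return sum(count for _, _, count, _ in self.alleles)


@dataclass(frozen=True)
class AssociationResult:
    table: pd.DataFrame  # rows: normal/defect, cols: wt_present/wt_absent
    odds_ratio: float | None
    degenerate: bool
    p_value: float
    alternative: str = "wildtype enriched in normal group"


@dataclass(frozen=True)
class CohortSummary:
    counts: pd.DataFrame  # per-score counts, columns: overall/defect/normal
    frequencies: pd.DataFrame  # same shape, columns sum to 1
    association: AssociationResult | None = None


def summarize_embryo(calls: Sequence, phenotype: str, embryo_id: str = "") -> EmbryoRecord:
    """Group informative per-read calls into an embryo's allele spectrum.

    ``calls`` are pipeline ReadCall objects (lesion + score + wildtype flag).
    Alleles are grouped by exact in-window sequence identity per homeolog, so
    distinct junctions with identical repaired products merge.
    """
    informative = [c for c in calls if c.lesion.informative]
    if not informative:
        raise CohortError(f"embryo {embryo_id or '<unnamed>'}: no informative calls")
    groups: dict[tuple[str, str], list] = {}
    for c in informative:
        groups.setdefault((c.allele_id, c.lesion.window_sequence or ""), []).append(c)
    alleles = tuple(
        sorted(
            (allele_id, seq, len(members), int(members[0].score))
            for (allele_id, seq), members in groups.items()
        )
    )
    tally: dict[int, int] = {}
    for c in informative:
        tally[int(c.score)] = tally.get(int(c.score), 0) + 1
    return EmbryoRecord(
        embryo_id=embryo_id,
        phenotype=phenotype,
        alleles=alleles,
        distinct_sequences=len(alleles),
        wildtype_present=any(c.is_wildtype for c in informative),
        score_tally=tally,
    )


def score_frequencies(
    cohort: Sequence[EmbryoRecord], grouping: str = "dichotomy"
) -> CohortSummary:
    """Per-code counts and proportions, overall and per phenotype group.

    ``grouping="dichotomy"`` splits heart-defect vs normal (the two
    parts-of-whole groups); ``grouping="phenotype"`` keeps all four classes.
    """
    if not cohort:
        raise CohortError("empty cohort")
    rows = []
    for rec in cohort:
        for code, count in rec.score_tally.items():
            rows.append(
                {
                    "code": code,
                    "count": count,
                    "group": ("defect" if rec.has_defect else "normal")
                    if grouping == "dichotomy"
                    else rec.phenotype,
                }
            )
    frame = pd.DataFrame(rows)
    counts = (
        frame.pivot_table(index="code", columns="group", values="count", aggfunc="sum", fill_value=0)
        .reindex(range(1, 7), fill_value=0)
    )
    counts.insert(0, "overall", counts.sum(axis=1))
    freqs = counts / counts.sum(axis=0).replace(0, np.nan)
    return CohortSummary(counts=counts, frequencies=freqs)


def fisher_exact_one_sided(table: Sequence[Sequence[int]]) -> float:
    """One-sided Fisher exact p for a 2x2 table, by hypergeometric tail.

    Table layout ``[[a, b], [c, d]]``; the alternative is that the
    upper-left cell is large (positive association of row 1 with column 1).
    The p-value is the exact sum P(X >= a) under fixed margins.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise CohortError("table entries must be non-negative")
    n_total = a + b + c + d
    col1 = a + c
    row1 = a + b
    return float(hypergeom.sf(a - 1, n_total, col1, row1))


def wildtype_phenotype_association(cohort: Sequence[EmbryoRecord]) -> AssociationResult:
    """2x2 wild-type presence x (normal vs defect), odds ratio, one-sided exact p.

    Tests whether wild-type-allele presence is enriched among embryos with a
    normal heart.  Zero-cell odds ratios are flagged degenerate rather than
    reported as infinity.
    """
    normal = [r for r in cohort if not r.has_defect]
    defect = [r for r in cohort if r.has_defect]
    if not normal or not defect:
        raise CohortError("association test needs both phenotype groups non-empty")
    a = sum(r.wildtype_present for r in normal)
    b = len(normal) - a
    c = sum(r.wildtype_present for r in defect)
    d = len(defect) - c
    table = pd.DataFrame(
        [[a, b], [c, d]],
        index=["normal", "defect"],
        columns=["wt_present", "wt_absent"],
    )
    degenerate = b * c == 0  # odds ratio denominator vanishes
    odds = None if degenerate else (a * d) / (b * c)
    p = fisher_exact_one_sided([[a, b], [c, d]])
    return AssociationResult(table=table, odds_ratio=odds, degenerate=degenerate, p_value=p)
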