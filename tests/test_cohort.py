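"""Embryo summaries, score-frequency tables and the exact association test."""

from math import comb

import pytest
from scipy.stats import fisher_exact as scipy_fisher

from g0mosaic import (
    EmbryoRecord,
    fisher_exact_one_sided,
    score_frequencies,
    summarize_embryo,
    wildtype_phenotype_association,
)
from g0mosaic.cohort import CohortError


def oracle_fisher(a, b, c, d):
    """Brute-force one-sided p: enumerate every table with the same margins
    and sum the hypergeometric probabilities of tables at least as extreme
    (upper-left cell >= a)."""
    row1, row2, col1 = a + b, c + d, a + c
    n = a + b + c + d
    denom = comb(n, row1)
    p = 0.0
    for x in range(max(0, col1 - row2), min(row1, col1) + 1):
        if x >= a:
            p += comb(col1, x) * comb(n - col1, row1 - x) / denom
    return p


class _FakeCall:
    def __init__(self, allele_id, window_seq, score, wildtype=False, informative=True):
        class L:
            pass

        self.allele_id = allele_id
        self.lesion = L()
        self.lesion.informative = informative
        self.lesion.window_sequence = window_seq
        self.score = score
        self.is_wildtype = wildtype


def _record(embryo_id, phenotype, wildtype, tally):
    return EmbryoRecord(
        embryo_id=embryo_id,
        phenotype=phenotype,
        alleles=tuple(("S", f"seq{code}", n, code) for code, n in tally.items()),
        distinct_sequences=len(tally),
        wildtype_present=wildtype,
        score_tally=tally,
    )


class TestSummarizeEmbryo:
    def test_distinct_sequences_counted_by_window_identity(self):
        calls = (
            [_FakeCall("S", "AAA", 5)] * 10
            + [_FakeCall("S", "CCC", 1)] * 6
            + [_FakeCall("L", "AAA", 5)] * 4
        )
        rec = summarize_embryo(calls, "normal", "t1")
        assert rec.distinct_sequences == 3
        assert rec.n_reads == 20

    def test_single_wildtype_read_sets_presence_flag(self):
        calls = [_FakeCall("S", "AAA", 1)] * 9 + [_FakeCall("S", "GGG", 6, wildtype=True)]
        rec = summarize_embryo(calls, "thin_wall_ventricle", "t2")
        assert rec.wildtype_present

    def test_uninformative_calls_excluded(self):
        calls = [_FakeCall("S", "AAA", 5)] * 3 + [
            _FakeCall("S", None, 0, informative=False)
        ]
        rec = summarize_embryo(calls, "normal", "t3")
        assert rec.n_reads == 3

    def test_zero_informative_calls_names_the_embryo(self):
        with pytest.raises(CohortError, match="t4"):
            summarize_embryo([_FakeCall("S", None, 0, informative=False)], "normal", "t4")

    def test_unknown_phenotype_rejected(self):
        with pytest.raises(CohortError, match="odd"):
            summarize_embryo([_FakeCall("S", "AAA", 5)], "odd", "t5")


class TestScoreFrequencies:
    def test_all_wildtype_cohort_is_100_percent_code_6(self):
        cohort = [_record(f"e{i}", "normal", True, {6: 20}) for i in range(4)]
        summary = score_frequencies(cohort)
        assert summary.frequencies.loc[6, "overall"] == 1.0

    def test_frequencies_sum_to_one_per_chart(self):
        cohort = [
            _record("e1", "normal", True, {6: 5, 5: 3, 1: 2}),
            _record("e2", "thin_wall_ventricle", False, {1: 7, 5: 2}),
            _record("e3", "inert_ventricle", False, {1: 4, 2: 1}),
        ]
        summary = score_frequencies(cohort)
        for col in summary.frequencies.columns:
            assert summary.frequencies[col].sum() == pytest.approx(1.0, abs=1e-12)

    def test_single_embryo_proportions_equal_its_tally(self):
        cohort = [_record("e1", "normal", True, {6: 6, 5: 4})]
        summary = score_frequencies(cohort)
        assert summary.frequencies.loc[6, "overall"] == pytest.approx(0.6)
        assert summary.frequencies.loc[5, "overall"] == pytest.approx(0.4)


class TestExactAssociation:
    def test_published_style_table(self):
        """normal: 5 WT / 0 without; defect: 3 WT / 8 without -> exact
        hypergeometric tail C(8,5)C(8,0)/C(16,5)."""
        p = fisher_exact_one_sided([[5, 0], [3, 8]])
        assert p == pytest.approx(comb(8, 5) / comb(16, 5))
        assert p == pytest.approx(oracle_fisher(5, 0, 3, 8))

    def test_identical_proportions_are_never_significant(self):
        # one-sided tail includes the observed table, so p >= P(X = a) and
        # the balanced table is far from rejection
        p = fisher_exact_one_sided([[4, 4], [4, 4]])
        assert p > 0.5
        assert p == pytest.approx(oracle_fisher(4, 4, 4, 4))
        # with nothing in the favoured cell the tail is the whole space
        assert fisher_exact_one_sided([[0, 5], [0, 5]]) == pytest.approx(1.0)

    def test_matches_enumeration_oracle_on_random_small_tables(self, rng):
        for _ in range(300):
            a, b, c, d = (int(x) for x in rng.integers(0, 8, 4))
            if (a + b) == 0 or (c + d) == 0:
                continue
            assert fisher_exact_one_sided([[a, b], [c, d]]) == pytest.approx(
                oracle_fisher(a, b, c, d), rel=1e-12, abs=1e-15
            )

    def test_matches_scipy_one_sided_greater(self, rng):
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 10, 4))
            expected = scipy_fisher([[a, b], [c, d]], alternative="greater").pvalue
            assert fisher_exact_one_sided([[a, b], [c, d]]) == pytest.approx(expected)

    def test_association_wrapper_builds_table_and_flags_degenerate(self):
        cohort = [_record(f"n{i}", "normal", True, {6: 5}) for i in range(5)] + [
            _record(f"d{i}", "thin_wall_ventricle", i < 3, {1: 5}) for i in range(11)
        ]
        result = wildtype_phenotype_association(cohort)
        assert result.table.loc["normal", "wt_present"] == 5
        assert result.table.loc["defect", "wt_absent"] == 8
        assert result.degenerate and result.odds_ratio is None
        assert result.p_value == pytest.approx(comb(8, 5) / comb(16, 5))

    def test_single_group_cohort_rejected(self):
        cohort = [_record(f"n{i}", "normal", True, {6: 5}) for i in range(5)]
        with pytest.raises(CohortError):
            wildtype_phenotype_association(cohort)

    def test_rejects_under_strong_lineage_effect_with_good_power(self, rng):
        """Self-consistency: when normal hearts require wild-type alleles in
        the cardiac lineage, the one-sided exact test rejects at alpha=0.05
        in most 16-embryo cohorts."""
        rejections = 0
        reps = 200
        for _ in range(reps):
            records = []
            n_normal = 0
            for i in range(16):
                wt_frac = float(rng.beta(1.2, 4.0))
                normal = wt_frac >= 0.2
                detected_wt = bool(rng.random() < (0.98 if wt_frac > 0 else 0.0) if normal
                                   else rng.random() < 0.25)
                n_normal += normal
                records.append(
                    _record(
                        f"e{i}",
                        "normal" if normal else "thin_wall_ventricle",
                        detected_wt,
                        {6: 3, 1: 7} if detected_wt else {1: 10},
                    )
                )
            if n_normal in (0, 16):
                continue
            if wildtype_phenotype_association(records).p_value < 0.05:
                rejections += 1
        assert rejections / reps >= 0.8
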