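"""Lesion calling: normalisation, window logic, wild-type rule, allele assignment."""

import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from g0mosaic import (
    AmpliconRead,
    align_read,
    assign_allele,
    call_lesion,
    is_wildtype_read,
    normalize_events,
    orientation_filter,
)
from g0mosaic.calling import CallingError
from g0mosaic.fixtures import exon6_amplicon_window
from g0mosaic.gene_model import GeneModelError


def _call(read_seq, model, window=None):
    window = window or exon6_amplicon_window(model)
    aln = align_read(read_seq, model.sequence, allele_id=model.allele_id)
    return call_lesion(aln, window, reference=model.sequence, read=read_seq, model=model)


class TestNormalization:
    def test_deletion_right_aligned_within_repeat(self):
        ref = "AACTTTTGG"
        # deleting any single T is reported at the 3'-most T
        for pos in (3, 4, 5, 6):
            assert normalize_events(ref, [(pos, "T", "")]) == [(6, "T", "")]

    def test_insertion_right_aligned_and_rotated(self):
        ref = "AACTTTTGG"
        assert normalize_events(ref, [(3, "", "T")]) == [(7, "", "T")]

    @settings(derandomize=True, max_examples=150, deadline=None)
    @given(
        st.text(alphabet="ACGT", min_size=10, max_size=40),
        st.integers(0, 35),
        st.integers(1, 4),
        st.text(alphabet="ACGT", min_size=0, max_size=4),
    )
    def test_idempotent(self, ref, pos, size, inserted):
        pos = min(pos, len(ref) - size)
        if pos < 0:
            return
        deleted = "" if inserted else ref[pos : pos + size]
        events = [(pos, deleted, inserted)]
        once = normalize_events(ref, events)
        assert normalize_events(ref, once) == once


class TestCallLesion:
    def test_unmutated_read_has_no_events(self, e6_amplicons):
        model = e6_amplicons[0]
        lesion = _call(model.sequence, model)
        assert lesion.events == () and lesion.net_indel == 0
        assert lesion.window_covered and lesion.informative

    def test_12bp_deletion_in_window(self, e6_amplicons):
        model = e6_amplicons[0]
        ref = model.sequence
        # remove 12 bp across the cut (amplicon offset 92..104)
        read = ref[:92] + ref[104:]
        lesion = _call(read, model)
        assert lesion.net_indel == -12
        assert len(lesion.events) == 1 and len(lesion.events[0][1]) == 12

    def test_deletion_placement_invariance_within_repeat(self, e6_amplicons):
        """A deletion inside a repeat run yields one lesion no matter which
        physical copy was removed."""
        model = e6_amplicons[0]
        ref = model.sequence
        lesions = set()
        for start in (96, 99):  # two placements of the AGA-repeat 3-bp deletion
            read = ref[:start] + ref[start + 3 :]
            lesions.add(_call(read, model).events)
        assert len(lesions) == 1

    def test_truncated_read_is_uninformative(self, e6_amplicons):
        model = e6_amplicons[0]
        read = model.sequence[:95]  # stops inside the window
        aln = align_read(read, model.sequence, mode="semi_global")
        lesion = call_lesion(
            aln, exon6_amplicon_window(model),
            reference=model.sequence, read=read, model=model,
        )
        assert not lesion.window_covered and not lesion.informative

    def test_n_base_in_window_is_uninformative_not_mutant(self, e6_amplicons):
        model = e6_amplicons[0]
        read = model.sequence[:95] + "N" + model.sequence[96:]
        lesion = _call(read, model)
        assert lesion.window_covered and not lesion.informative

    def test_out_of_window_events_reported_separately(self, e6_amplicons):
        model = e6_amplicons[0]
        ref = model.sequence
        read = ref[:10] + ref[13:]  # 3-bp deletion in the 5' intron
        lesion = _call(read, model)
        assert lesion.events == ()
        assert len(lesion.out_of_window_events) == 1

    def test_window_outside_reference_rejected(self, e6_amplicons):
        model = e6_amplicons[0]
        aln = align_read(model.sequence, model.sequence)
        with pytest.raises(CallingError):
            call_lesion(aln, (180, 400), reference=model.sequence, read=model.sequence)

    def test_acceptor_deletion_sets_splice_flag(self, splice_model):
        ref = splice_model.sequence
        acc = splice_model.acceptor_interval(splice_model.exons[1])
        read = ref[: acc[0] - 1] + ref[acc[1] + 1 :]
        aln = align_read(read, ref)
        lesion = call_lesion(aln, (0, 30), reference=ref, read=read, model=splice_model)
        assert lesion.disrupts_acceptor and not lesion.disrupts_donor


class TestWildTypeRule:
    def test_unmutated_read_is_wildtype(self, e6_amplicons):
        model = e6_amplicons[0]
        assert is_wildtype_read(_call(model.sequence, model), model)

    def test_3bp_deletion_is_not_wildtype(self, e6_amplicons):
        model = e6_amplicons[0]
        read = model.sequence[:96] + model.sequence[99:]
        lesion = _call(read, model)
        assert not is_wildtype_read(lesion, model)

    def test_synonymous_substitution_still_wildtype(self, e6_amplicons):
        """The wild-type definition is peptide-level: GGG->GGA at Gly269
        leaves the window peptide GGRRG intact."""
        model = e6_amplicons[0]
        ws, _ = exon6_amplicon_window(model)
        pos = ws + 2  # third base of the Gly269 codon (GGG)
        assert model.sequence[pos] == "G"
        read = model.sequence[:pos] + "A" + model.sequence[pos + 1 :]
        lesion = _call(read, model)
        assert lesion.events != ()  # a real DNA change...
        assert is_wildtype_read(lesion, model)  # ...but silent at peptide level

    def test_uncovered_window_is_not_wildtype(self, e6_amplicons):
        model = e6_amplicons[0]
        read = model.sequence[:95]
        aln = align_read(read, model.sequence, mode="semi_global")
        lesion = call_lesion(
            aln, exon6_amplicon_window(model),
            reference=model.sequence, read=read, model=model,
        )
        assert not is_wildtype_read(lesion, model)

    def test_non_codon_aligned_window_rejected(self, e6_amplicons):
        model = e6_amplicons[0]
        lesion = _call(model.sequence, model)
        with pytest.raises(GeneModelError, match="codon-aligned"):
            is_wildtype_read(lesion, model, window=(91, 105))


class TestAssignAllele:
    def test_exact_amplicons_assigned_to_their_locus(self, e6_amplicons):
        s_model, l_model = e6_amplicons
        assert assign_allele(AmpliconRead("r1", s_model.sequence), e6_amplicons) == "S"
        assert assign_allele(AmpliconRead("r2", l_model.sequence), e6_amplicons) == "L"

    def test_reverse_complement_read_still_assigned(self, e6_amplicons):
        s_model = e6_amplicons[0]
        rc = str(Seq(s_model.sequence).reverse_complement())
        assert assign_allele(AmpliconRead("r", rc), e6_amplicons) == "S"

    def test_chimeric_read_follows_five_prime_identity(self, e6_amplicons):
        s_model, l_model = e6_amplicons
        half = len(s_model.sequence) // 2
        chimera = s_model.sequence[:half] + l_model.sequence[half:]
        assert assign_allele(AmpliconRead("r", chimera), e6_amplicons) == "S"
        chimera_l = l_model.sequence[:half] + s_model.sequence[half:]
        assert assign_allele(AmpliconRead("r", chimera_l), e6_amplicons) == "L"

    def test_identical_references_are_ambiguous(self, e6_amplicons):
        s_model = e6_amplicons[0]
        twin = s_model.__class__(
            allele_id="S2",
            sequence=s_model.sequence,
            exons=s_model.exons,
            residue_offset=s_model.residue_offset,
        )
        read = AmpliconRead("r", s_model.sequence)
        assert assign_allele(read, [s_model, twin]) == "ambiguous"


class TestOrientationFilter:
    def _reads(self):
        fwd = [AmpliconRead(f"f{i}", "ACGT" * 10, orientation="forward") for i in range(5)]
        rev = [AmpliconRead(f"r{i}", "ACGT" * 10, orientation="reverse") for i in range(10)]
        return fwd + rev

    def test_keep_reverse(self):
        kept = orientation_filter(self._reads(), keep="reverse")
        assert len(kept) == 10 and all(r.orientation == "reverse" for r in kept)

    def test_keep_both_is_identity(self):
        reads = self._reads()
        assert orientation_filter(reads, keep="both") == reads

    def test_invalid_keep_rejected(self):
        with pytest.raises(CallingError):
            orientation_filter(self._reads(), keep="upside_down")
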