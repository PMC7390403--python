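"""Simulator contracts: determinism, repair-outcome structure, error model."""

import numpy as np
import pytest

from g0mosaic import (
    MosaicModel,
    RepairModel,
    enumerate_mmej,
    inject_sequencing_error,
    simulate_cohort,
    translate,
)
from g0mosaic.fixtures import (
    EXON6_WINDOW_SEQ,
    exon6_amplicon_model,
    exon6_amplicon_window,
)
from g0mosaic.simulate import SimulationError, TruthManifest


@pytest.fixture(scope="module")
def models():
    return [exon6_amplicon_model("S"), exon6_amplicon_model("L")]


class TestDeterminism:
    def test_fixed_seed_reproduces_reads_byte_identically(self, models, e6_guide):
        kwargs = dict(n_embryos=4, reads_per_embryo=10, seed=7)
        d1 = simulate_cohort(models, e6_guide, **kwargs)
        d2 = simulate_cohort(models, e6_guide, **kwargs)
        for embryo in d1.reads_by_embryo:
            assert [r.sequence for r in d1.reads_by_embryo[embryo]] == [
                r.sequence for r in d2.reads_by_embryo[embryo]
            ]
        assert d1.phenotypes == d2.phenotypes

    def test_different_seeds_differ(self, models, e6_guide):
        d1 = simulate_cohort(models, e6_guide, n_embryos=4, reads_per_embryo=10, seed=1)
        d2 = simulate_cohort(models, e6_guide, n_embryos=4, reads_per_embryo=10, seed=2)
        r1 = [r.sequence for reads in d1.reads_by_embryo.values() for r in reads]
        r2 = [r.sequence for reads in d2.reads_by_embryo.values() for r in reads]
        assert r1 != r2

    def test_manifest_json_round_trip(self, models, e6_guide, tmp_path):
        d = simulate_cohort(models, e6_guide, n_embryos=2, reads_per_embryo=5, seed=3)
        path = tmp_path / "manifest.json"
        d.manifest.to_json(path)
        loaded = TruthManifest.from_json(path)
        assert loaded.seed == d.manifest.seed
        assert [e.phenotype for e in loaded.embryos] == [
            e.phenotype for e in d.manifest.embryos
        ]
        assert loaded.embryos[0].alleles[0].events == d.manifest.embryos[0].alleles[0].events


class TestRepairStructure:
    def test_pure_mmej_alleles_are_enumerated_products(self, models, e6_guide):
        repair = RepairModel(
            p_mmej=1.0, p_substitution=0.0, max_deletion=12, min_microhomology=2
        )
        mosaic = MosaicModel(p_wildtype_escape=0.0)
        d = simulate_cohort(
            models, e6_guide, n_embryos=8, reads_per_embryo=5,
            repair=repair, mosaic=mosaic, seed=11,
        )
        from g0mosaic.guides import locate_target

        product_seqs = {
            m.allele_id: {
                p.product_sequence
                for p in enumerate_mmej(
                    m.sequence, locate_target(e6_guide, m)[0].cut_position, 2, 12
                )
            }
            for m in models
        }
        sizes = set()
        for embryo in d.manifest.embryos:
            for allele in embryo.alleles:
                assert allele.sequence in product_seqs[allele.homeolog]
                (pos, deleted, inserted) = allele.events[0]
                assert inserted == ""
                if len(deleted) % 3 == 0:
                    sizes.add(len(deleted))
        # the repeat structure of this site admits exactly these in-frame sizes
        assert sizes <= {3, 6, 9, 12}
        assert {3, 9} <= sizes

    def test_wildtype_escape_one_gives_all_normal(self, models, e6_guide):
        mosaic = MosaicModel(p_wildtype_escape=1.0)
        d = simulate_cohort(
            models, e6_guide, n_embryos=5, reads_per_embryo=8, mosaic=mosaic, seed=13
        )
        assert set(d.phenotypes.values()) == {"normal"}
        for embryo in d.manifest.embryos:
            assert all(a.is_wildtype for a in embryo.alleles)
        for reads in d.reads_by_embryo.values():
            for read in reads:
                assert EXON6_WINDOW_SEQ in read.sequence  # intact window peptide

    def test_allele_counts_within_one_to_six_per_homeolog(self, models, e6_guide):
        d = simulate_cohort(models, e6_guide, n_embryos=20, reads_per_embryo=4, seed=17)
        for embryo in d.manifest.embryos:
            for hom in ("S", "L"):
                n = sum(1 for a in embryo.alleles if a.homeolog == hom)
                assert 1 <= n <= 6

    def test_guide_absent_from_model_is_an_error(self, e6_guide, e3_local):
        with pytest.raises(SimulationError, match="not found"):
            simulate_cohort([e3_local], e6_guide, n_embryos=1, seed=1)

    def test_inframe_probability_recovered_from_simulation(self, models, e6_guide):
        """With p_mmej=0.8 and default weighting the realised fraction of
        in-frame mutant alleles over 200 embryos tracks the analytic
        generative probability within +/- 0.05."""
        repair = RepairModel(p_mmej=0.8)
        d = simulate_cohort(
            models, e6_guide, n_embryos=200, reads_per_embryo=1,
            repair=repair, mosaic=MosaicModel(p_wildtype_escape=0.0), seed=23,
        )
        from g0mosaic.guides import locate_target

        cut = locate_target(e6_guide, models[0])[0].cut_position
        expected = repair.inframe_probability(repair.mmej_products(models[0], cut))
        mutants = [
            a for e in d.manifest.embryos for a in e.alleles if not a.is_wildtype
        ]
        observed = np.mean([
            (sum(len(i) - len(dl) for _, dl, i in a.events) % 3 == 0)
            for a in mutants
        ])
        assert abs(observed - expected) <= 0.05


class TestSequencingError:
    def test_rate_zero_is_identity(self, rng):
        seq = "ACGT" * 30
        out, errors = inject_sequencing_error(seq, 0.0, rng)
        assert out == seq and errors == ()

    def test_error_count_within_three_sigma_of_binomial(self, rng):
        n_reads, length, rate = 10_000, 100, 0.01
        seq = "".join(rng.choice(list("ACGT"), length))
        total = 0
        for _ in range(n_reads):
            _, errors = inject_sequencing_error(seq, rate, rng)
            total += len(errors)
        mean = n_reads * length * rate
        sigma = (n_reads * length * rate * (1 - rate)) ** 0.5
        assert abs(total - mean) <= 3 * sigma

    def test_rate_bounds_enforced(self, rng):
        with pytest.raises(SimulationError):
            inject_sequencing_error("ACGT", 0.5, rng)

    def test_window_errors_convert_wildtype_to_apparent_mutant(self, models, e6_guide, rng):
        """Substitution errors inside the 15-bp window flip true wild-type
        reads to apparent mutants at a rate predicted by the per-position
        count of non-synonymous single-base changes."""
        model = models[0]
        ws, we = exon6_amplicon_window(model)
        window = model.sequence[ws:we]
        ref_pep = translate(window)
        # expected flip probability, first order in the error rate
        rate = 0.01
        p_flip = 0.0
        for k in range(len(window)):
            non_syn = 0
            for alt in "ACGT":
                if alt == window[k]:
                    continue
                mutated = window[:k] + alt + window[k + 1 :]
                if translate(mutated) != ref_pep:
                    non_syn += 1
            p_flip += rate * non_syn / 3
        n = 20_000
        flips = 0
        for _ in range(n):
            seq, errors = inject_sequencing_error(window, rate, rng)
            if errors and translate(seq) != ref_pep:
                flips += 1
        sigma = (n * p_flip * (1 - p_flip)) ** 0.5
        assert abs(flips - n * p_flip) <= 3.5 * sigma


class TestNgsReads:
    def test_only_reverse_reads_span_a_three_prime_window(self, e6_guide):
        # pad the 5' end so the gRNA site sits toward the 3' of the product,
        # as in the real sequenced amplicon
        from g0mosaic.gene_model import Exon, GeneModel

        base = exon6_amplicon_model("S")
        pad = ("ACGTTGCA" * 13)[:100]
        exon = base.exons[0]
        model = GeneModel(
            "S", pad + base.sequence,
            (Exon("e6", exon.start + 100, exon.end + 100),),
            residue_offset=base.residue_offset,
        )
        d = simulate_cohort(
            [model], e6_guide, n_embryos=3, reads_per_embryo=40,
            source="ngs", read_length=120, seed=29,
            mosaic=MosaicModel(p_wildtype_escape=1.0),
        )
        from Bio.Seq import Seq

        for reads in d.reads_by_embryo.values():
            for read in reads:
                spans = (
                    EXON6_WINDOW_SEQ in read.sequence
                    or EXON6_WINDOW_SEQ in str(Seq(read.sequence).reverse_complement())
                )
                assert spans == (read.orientation == "reverse")
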