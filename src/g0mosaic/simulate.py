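"""Synthetic mosaic G0 embryo datasets with a full ground-truth manifest.

The generator emulates the statistical structure of CRISPR mutagenesis at
the one-cell stage in an allotetraploid: each embryo carries 1-6 distinct
repaired alleles per homeologous locus (mass concentrated at four or
fewer), repair outcomes at repeat-rich cut sites are biased toward
microhomology-mediated deletions with the remainder NHEJ indels or 1-bp
substitutions, a small per-allele probability of escaping unrepaired
(wild type), and a Beta-distributed cardiac-lineage share that decides
which alleles reach heart tissue.  The phenotype rule operationalises the
lineage argument minimally: a heart forms normally iff the functional-
allele fraction reaching the cardiac lineage is at least a threshold θ.

Every read in the emitted dataset is traceable: the manifest records the
source allele, its true events, consequence and genotype score, and any
injected sequencing errors, so pipeline recovery can be checked exactly.
All randomness flows from a single seed through ``numpy.random.default_rng``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .calling import AmpliconRead
from .consequence import annotate_consequence, assign_score
from .calling import DnaLesion, normalize_events, _splice_flags
from .gene_model import GeneModel
from .guides import GuideRNA, locate_target
from .mmej import MMEJProduct, enumerate_mmej

_BASES = "ACGT"


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class RepairModel:
    """Stochastic model of DSB repair outcomes at one cut site.

    ``p_mmej`` is the probability a repair uses a microhomology-mediated
    deletion (drawn by product weight); otherwise NHEJ produces a deletion
    or insertion with truncated-geometric sizes (deletions up to 24 bp,
    insertions up to 6 bp, matching the size range seen in cloned mutant
    sequences), and ``p_substitution`` yields a 1-bp substitution at the cut.

    The MMEJ pool defaults to deletions of at most 12 bp supported by at
    least 3 bp of microhomology: the stereotyped short products of annealing
    at strong direct repeats.  Larger deletions arise through the NHEJ arm.
    """

    p_mmej: float = 0.7
    p_substitution: float = 0.04
    p_insertion_vs_deletion: float = 0.2
    nhej_del_geom_p: float = 0.25
    nhej_del_max: int = 24
    nhej_ins_geom_p: float = 0.45
    nhej_ins_max: int = 6
    min_microhomology: int = 3
    max_deletion: int = 12

    def __post_init__(self) -> None:
        for name in ("p_mmej", "p_substitution", "p_insertion_vs_deletion"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name}={v} outside [0, 1]")

    def _truncated_geometric(self, rng: np.random.Generator, p: float, upper: int) -> int:
        while True:
            size = int(rng.geometric(p))
            if size <= upper:
                return size

    def mmej_products(self, model: GeneModel, cut: int) -> list[MMEJProduct]:
        return enumerate_mmej(
            model.sequence, cut,
            min_microhomology=self.min_microhomology,
            max_deletion=self.max_deletion,
        )

    def draw_repair(
        self, rng: np.random.Generator, model: GeneModel, cut: int,
        products: Sequence[MMEJProduct] | None = None,
    ) -> tuple[int, str, str]:
        """One repair outcome as a (ref_start, deleted, inserted) event."""
        seq = model.sequence
        if rng.random() < self.p_substitution:
            pos = cut - 1
            ref_base = seq[pos]
            alt = rng.choice([b for b in _BASES if b != ref_base])
            return (pos, ref_base, str(alt))
        if products is None:
            products = self.mmej_products(model, cut)
        if products and rng.random() < self.p_mmej:
            weights = np.array([p.weight for p in products])
            product = products[int(rng.choice(len(products), p=weights / weights.sum()))]
            a, b = product.deleted_interval
            return (a, seq[a:b], "")
        if rng.random() < self.p_insertion_vs_deletion:
            size = self._truncated_geometric(rng, self.nhej_ins_geom_p, self.nhej_ins_max)
            ins = "".join(rng.choice(list(_BASES), size))
            return (cut, "", ins)
        size = self._truncated_geometric(rng, self.nhej_del_geom_p, self.nhej_del_max)
        start = cut - int(rng.integers(0, size + 1))
        start = max(0, min(start, len(seq) - size))
        return (start, seq[start : start + size], "")

    def inframe_probability(self, products: Sequence[MMEJProduct]) -> float:
        """Analytic probability that a mutant allele is in-frame (no premature
        stop considerations; pure frame arithmetic), given this model and a
        product pool.  Used for parameter-recovery checks."""
        w = sum(p.weight for p in products if p.in_frame)
        total = sum(p.weight for p in products)
        p_mmej_inframe = w / total if total else 0.0

        def trunc_geom_pmf(p: float, upper: int) -> np.ndarray:
            k = np.arange(1, upper + 1)
            pmf = (1 - p) ** (k - 1) * p
            return pmf / pmf.sum()

        del_pmf = trunc_geom_pmf(self.nhej_del_geom_p, self.nhej_del_max)
        ins_pmf = trunc_geom_pmf(self.nhej_ins_geom_p, self.nhej_ins_max)
        p_del_if = sum(del_pmf[k] for k in range(self.nhej_del_max) if (k + 1) % 3 == 0)
        p_ins_if = sum(ins_pmf[k] for k in range(self.nhej_ins_max) if (k + 1) % 3 == 0)
        p_nhej_if = (
            self.p_insertion_vs_deletion * p_ins_if
            + (1 - self.p_insertion_vs_deletion) * p_del_if
        )
        p_mut_mmej = (1 - self.p_substitution) * self.p_mmej
        p_mut_nhej = (1 - self.p_substitution) * (1 - self.p_mmej)
        # substitutions are in-frame by definition
        return (
            self.p_substitution
            + p_mut_mmej * p_mmej_inframe
            + p_mut_nhej * p_nhej_if
        )


@dataclass(frozen=True)
class MosaicModel:
    """Per-embryo mosaicism: allele counts, frequencies, wild-type escape,
    cardiac-lineage share and the phenotype threshold.

    ``functional_scores`` defines which genotype codes count as functional
    for the phenotype rule.  The default is wild type only ({6}): at the
    exon 6 target the common small in-frame (score 05) deletions remove the
    essential di-arginine loop, so only unmutated alleles preserve function.
    """

    n_alleles_probs: tuple[float, ...] = (0.15, 0.30, 0.25, 0.15, 0.10, 0.05)
    dirichlet_alpha: float = 1.5
    p_wildtype_escape: float = 0.12
    cardiac_beta: tuple[float, float] = (12.0, 2.0)
    phenotype_threshold: float = 0.1
    functional_scores: frozenset[int] = frozenset({6})
    defect_probs: tuple[float, ...] = (0.25, 0.6, 0.15)  # inert / thin-wall / other

    def __post_init__(self) -> None:
        if abs(sum(self.n_alleles_probs) - 1.0) > 1e-9:
            raise SimulationError("n_alleles_probs must sum to 1")
        if not 0.0 <= self.p_wildtype_escape <= 1.0:
            raise SimulationError("p_wildtype_escape outside [0, 1]")


@dataclass
class AlleleTruth:
    allele_index: int
    homeolog: str
    sequence: str
    frequency: float
    is_wildtype: bool
    events: tuple[tuple[int, str, str], ...]
    kind: str
    hgvs_p: str
    score: int
    reaches_cardiac: bool
    read_count: int = 0


@dataclass
class EmbryoTruth:
    embryo_id: str
    phenotype: str
    alleles: list[AlleleTruth]
    cardiac_fraction: float
    functional_cardiac_fraction: float
    wildtype_present: bool  # among emitted reads


@dataclass
class ReadTruth:
    read_id: str
    embryo_id: str
    homeolog: str
    allele_index: int
    orientation: str
    error_positions: tuple[int, ...] = ()


@dataclass
class TruthManifest:
    seed: int
    embryos: list[EmbryoTruth] = field(default_factory=list)
    reads: list[ReadTruth] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        raw = json.loads(Path(path).read_text())
        manifest = cls(seed=raw["seed"])
        for e in raw["embryos"]:
            alleles = [
                AlleleTruth(**{**a, "events": tuple(tuple(ev) for ev in a["events"])})
                for a in e["alleles"]
            ]
            manifest.embryos.append(EmbryoTruth(**{**e, "alleles": alleles}))
        manifest.reads = [
            ReadTruth(**{**r, "error_positions": tuple(r["error_positions"])})
            for r in raw["reads"]
        ]
        return manifest


def _apply_events(sequence: str, events: Sequence[tuple[int, str, str]]) -> str:
    out, cursor = [], 0
    for pos, deleted, inserted in sorted(events):
        out.append(sequence[cursor:pos])
        out.append(inserted)
        cursor = pos + len(deleted)
    out.append(sequence[cursor:])
    return "".join(out)


def inject_sequencing_error(
    sequence: str, rate: float, rng: np.random.Generator
) -> tuple[str, tuple[int, ...]]:
    """Uniform per-base substitution errors; returns (sequence, error positions)."""
    if not 0.0 <= rate <= 0.1:
        raise SimulationError(f"error rate {rate} outside [0, 0.1]")
    if rate == 0.0:
        return sequence, ()
    flips = np.flatnonzero(rng.random(len(sequence)) < rate)
    if flips.size == 0:
        return sequence, ()
    seq = list(sequence)
    for pos in flips:
        seq[pos] = rng.choice([b for b in _BASES if b != seq[pos]])
    return "".join(seq), tuple(int(p) for p in flips)


def _truth_lesion(
    model: GeneModel, events: Sequence[tuple[int, str, str]]
) -> DnaLesion:
    """Ground-truth lesion (whole-reference window) for annotation."""
    norm = tuple(normalize_events(model.sequence, events))
    acceptor, donor = _splice_flags(model, norm)
    return DnaLesion(
        allele_id=model.allele_id,
        events=norm,
        net_indel=sum(len(i) - len(d) for _, d, i in norm),
        window=(0, len(model.sequence)),
        window_covered=True,
        window_sequence=None,
        informative=True,
        disrupts_acceptor=acceptor,
        disrupts_donor=donor,
    )


def simulate_embryo(
    models: Sequence[GeneModel],
    guide: GuideRNA,
    repair: RepairModel,
    mosaic: MosaicModel,
    rng: np.random.Generator,
    *,
    embryo_id: str = "embryo",
    n_reads: int = 30,
    source: str = "sanger_clone",
    read_length: int = 150,
    error_rate: float = 0.0,
) -> tuple[list[AmpliconRead], EmbryoTruth, list[ReadTruth]]:
    """Simulate one mosaic embryo across the given homeolog models.

    Sanger clones are full-length amplicons in forward orientation; NGS
    reads are ``read_length``-nt single-end reads from either product end,
    with only reverse-orientation reads spanning a 3'-proximal target site.
    """
    sites_and_products = []
    for model in models:
        sites = locate_target(guide, model, max_mismatches=0)
        if not sites:
            raise SimulationError(
                f"guide {guide.name} not found on allele {model.allele_id}"
            )
        site = sites[0]
        sites_and_products.append((model, site.cut_position, repair.mmej_products(model, site.cut_position)))

    alleles: list[AlleleTruth] = []
    cardiac = float(rng.beta(*mosaic.cardiac_beta))
    for model, cut, products in sites_and_products:
        n_alleles = 1 + int(rng.choice(len(mosaic.n_alleles_probs), p=mosaic.n_alleles_probs))
        freqs = rng.dirichlet([mosaic.dirichlet_alpha] * n_alleles)
        for i in range(n_alleles):
            if rng.random() < mosaic.p_wildtype_escape:
                events: tuple[tuple[int, str, str], ...] = ()
            else:
                events = (repair.draw_repair(rng, model, cut, products),)
            lesion = _truth_lesion(model, events)
            consequence = annotate_consequence(lesion, model)
            score = assign_score(consequence).code
            alleles.append(
                AlleleTruth(
                    allele_index=len(alleles),
                    homeolog=model.allele_id,
                    sequence=_apply_events(model.sequence, events),
                    frequency=float(freqs[i]) / len(models),
                    is_wildtype=not events,
                    events=lesion.events,
                    kind=consequence.kind,
                    hgvs_p=consequence.hgvs_p,
                    score=score,
                    reaches_cardiac=bool(rng.random() < cardiac),
                )
            )

    cardiac_weight = sum(a.frequency for a in alleles if a.reaches_cardiac)
    if cardiac_weight > 0:
        functional_cardiac = sum(
            a.frequency
            for a in alleles
            if a.reaches_cardiac and a.score in mosaic.functional_scores
        ) / cardiac_weight
    else:
        functional_cardiac = 0.0
    if functional_cardiac >= mosaic.phenotype_threshold:
        phenotype = "normal"
    else:
        idx = int(rng.choice(3, p=mosaic.defect_probs))
        phenotype = ("inert_ventricle", "thin_wall_ventricle", "other_malformation")[idx]

    # emit reads
    reads: list[AmpliconRead] = []
    read_truths: list[ReadTruth] = []
    freqs = np.array([a.frequency for a in alleles])
    freqs = freqs / freqs.sum()
    choices = rng.choice(len(alleles), size=n_reads, p=freqs)
    for r, allele_idx in enumerate(choices):
        allele = alleles[int(allele_idx)]
        allele.read_count += 1
        read_id = f"{embryo_id}:read{r:04d}"
        if source == "sanger_clone":
            seq, orientation = allele.sequence, "forward"
        elif source == "ngs":
            from Bio.Seq import Seq as _Seq

            if rng.random() < 0.5:
                orientation = "reverse"
                seq = str(_Seq(allele.sequence[-read_length:]).reverse_complement())
            else:
                orientation = "forward"
                seq = allele.sequence[:read_length]
        else:
            raise SimulationError(f"unknown read source {source!r}")
        seq, errors = inject_sequencing_error(seq, error_rate, rng)
        reads.append(
            AmpliconRead(read_id, seq, source=source, orientation=orientation)
        )
        read_truths.append(
            ReadTruth(
                read_id=read_id,
                embryo_id=embryo_id,
                homeolog=allele.homeolog,
                allele_index=allele.allele_index,
                orientation=orientation,
                error_positions=errors,
            )
        )

    truth = EmbryoTruth(
        embryo_id=embryo_id,
        phenotype=phenotype,
        alleles=alleles,
        cardiac_fraction=cardiac,
        functional_cardiac_fraction=functional_cardiac,
        wildtype_present=any(a.is_wildtype and a.read_count > 0 for a in alleles),
    )
    return reads, truth, read_truths


@dataclass
class CohortDataset:
    reads_by_embryo: dict[str, list[AmpliconRead]]
    phenotypes: dict[str, str]
    manifest: TruthManifest


def simulate_cohort(
    models: Sequence[GeneModel],
    guide: GuideRNA,
    *,
    n_embryos: int = 16,
    reads_per_embryo: int = 31,
    repair: RepairModel | None = None,
    mosaic: MosaicModel | None = None,
    seed: int = 0,
    source: str = "sanger_clone",
    read_length: int = 150,
    error_rate: float = 0.0,
) -> CohortDataset:
    """Simulate an independent cohort of mosaic embryos with one shared seed.

    Defaults mirror the scale of the exon 6 experiment: 16 embryos and
    ~500 clones in total.
    """
    if n_embryos < 1:
        raise SimulationError("n_embryos must be >= 1")
    repair = repair or RepairModel()
    mosaic = mosaic or MosaicModel()
    rng = np.random.default_rng(seed)
    manifest = TruthManifest(seed=seed)
    reads_by_embryo: dict[str, list[AmpliconRead]] = {}
    phenotypes: dict[str, str] = {}
    for e in range(n_embryos):
        embryo_id = f"embryo{e:03d}"
        reads, truth, read_truths = simulate_embryo(
            models, guide, repair, mosaic, rng,
            embryo_id=embryo_id, n_reads=reads_per_embryo,
            source=source, read_length=read_length, error_rate=error_rate,
        )
        reads_by_embryo[embryo_id] = reads
        phenotypes[embryo_id] = truth.phenotype
        manifest.embryos.append(truth)
        manifest.reads.extend(read_truths)
    return CohortDataset(reads_by_embryo, phenotypes, manifest)


def write_cohort(dataset: CohortDataset, out_dir: str | Path) -> None:
    """Write FASTA/FASTQ per embryo, a phenotype TSV and the manifest JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for embryo_id, reads in dataset.reads_by_embryo.items():
        is_fastq = reads and reads[0].source == "ngs"
        path = out / f"{embryo_id}.{'fastq' if is_fastq else 'fasta'}"
        with open(path, "w") as handle:
            for read in reads:
                if is_fastq:
                    quals = "I" * len(read.sequence)
                    handle.write(f"@{read.read_id}\n{read.sequence}\n+\n{quals}\n")
                else:
                    handle.write(f">{read.read_id}\n{read.sequence}\n")
        rows.append({"embryo_id": embryo_id, "phenotype": dataset.phenotypes[embryo_id]})
    import pandas as pd

    pd.DataFrame(rows).to_csv(out / "phenotypes.tsv", sep="\t", index=False)
    dataset.manifest.to_json(out / "truth_manifest.json")
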