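"""Reference gene models for homeologous alleles.

A :class:`GeneModel` holds one allele's genomic sequence together with its
exon structure and coding frame.  Everything downstream — gRNA target
location, lesion calling, protein-consequence annotation — works against
this container, in CDS orientation (reverse-strand genes are flipped into
CDS orientation at load time, so there is a single code path).

Coordinates are 0-based half-open internally; user-facing residue numbers
and HGVS strings are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

_DNA = frozenset("ACGT")

STOP = "*"


class GeneModelError(ValueError):
    """Raised when a gene model or an operation on it is invalid."""


def translate(nt: str, frame_offset: int = 0, *, to_stop: bool = False) -> str:
    """Translate a nucleotide string with the standard genetic code.

    The incomplete trailing codon is dropped.  Stop codons render as ``*``;
    with ``to_stop=True`` translation halts at the first stop (the stop
    itself is not included).

    Raises
    ------
    GeneModelError
        If a non-ACGT character is present (the position is reported).
    """
    if frame_offset not in (0, 1, 2):
        raise GeneModelError(f"frame_offset must be 0, 1 or 2, got {frame_offset}")
    for i, base in enumerate(nt):
        if base not in _DNA:
            raise GeneModelError(f"non-ACGT character {base!r} at position {i}")
    coding = nt[frame_offset:]
    coding = coding[: len(coding) - len(coding) % 3]
    pep = str(Seq(coding).translate())
    if to_stop and STOP in pep:
        pep = pep[: pep.index(STOP)]
    return pep


@dataclass(frozen=True)
class Exon:
    exon_id: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """One allele: sequence, exon structure and codon frame.

    Parameters
    ----------
    allele_id:
        Homeolog label, e.g. ``"S"`` or ``"L"`` for the two allotetraploid loci.
    sequence:
        Genomic sequence in CDS orientation, over ``{A,C,G,T}``.
    exons:
        Ordered ``(exon_id, start, end)`` triples, 0-based half-open, sorted,
        non-overlapping, within the sequence.
    cds_start_offset:
        Index of the first coding base *within the spliced exon
        concatenation* (0 for fixtures that are pure CDS).
    strand:
        Strand of the original genomic record.  Sequences are always stored
        in CDS orientation; this is bookkeeping only.
    residue_offset:
        Number of protein residues encoded upstream of this model, so that
        local residue 1 reports as ``residue_offset + 1``.  Lets a local
        fixture (e.g. an exon 6 amplicon) carry the full-protein numbering.
    """

    allele_id: str
    sequence: str
    exons: tuple[Exon, ...]
    cds_start_offset: int = 0
    strand: str = "+"
    residue_offset: int = 0

    def __post_init__(self) -> None:
        for i, base in enumerate(self.sequence):
            if base not in _DNA:
                raise GeneModelError(
                    f"allele {self.allele_id}: non-ACGT character {base!r} at position {i}"
                )
        if self.strand not in ("+", "-"):
            raise GeneModelError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise GeneModelError(f"allele {self.allele_id}: no exons")
        prev_end = 0
        for exon in self.exons:
            if exon.start < 0 or exon.end > len(self.sequence):
                raise GeneModelError(
                    f"exon {exon.exon_id} [{exon.start}, {exon.end}) outside "
                    f"sequence of length {len(self.sequence)}"
                )
            if exon.end <= exon.start:
                raise GeneModelError(f"exon {exon.exon_id} is empty or reversed")
            if exon.start < prev_end:
                raise GeneModelError(f"exon {exon.exon_id} overlaps the previous exon")
            prev_end = exon.end
        if self.cds_length < 3:
            raise GeneModelError(
                f"allele {self.allele_id}: CDS length {self.cds_length} < 3"
            )

    # -- spliced / coding views -------------------------------------------------

    @property
    def spliced(self) -> str:
        return "".join(self.sequence[e.start : e.end] for e in self.exons)

    @property
    def cds(self) -> str:
        return self.spliced[self.cds_start_offset :]

    @property
    def cds_length(self) -> int:
        return len(self.cds)

    @property
    def protein_length(self) -> int:
        """Number of whole codons in the CDS."""
        return self.cds_length // 3

    @property
    def peptide(self) -> str:
        return translate(self.cds)

    def exon(self, exon_id: str) -> Exon:
        for e in self.exons:
            if e.exon_id == exon_id:
                return e
        raise GeneModelError(f"no exon {exon_id!r} in allele {self.allele_id}")

    def exon_codon_count(self, exon_id: str) -> int:
        """Whole codons contributed by one exon (errors if not codon-multiple)."""
        e = self.exon(exon_id)
        if e.length % 3:
            raise GeneModelError(
                f"exon {exon_id} is {e.length} bp, not a whole number of codons"
            )
        return e.length // 3

    # -- splice junctions -------------------------------------------------------

    def acceptor_interval(self, exon: Exon) -> tuple[int, int] | None:
        """Genomic interval of the acceptor dinucleotide 5' of an exon."""
        if exon is self.exons[0] or exon.start < 2:
            return None
        return (exon.start - 2, exon.start)

    def donor_interval(self, exon: Exon) -> tuple[int, int] | None:
        """Genomic interval of the donor dinucleotide 3' of an exon."""
        if exon is self.exons[-1] or exon.end + 2 > len(self.sequence):
            return None
        return (exon.end, exon.end + 2)

    def codon_map(self) -> "CodonMap":
        return CodonMap.from_model(self)


@dataclass(frozen=True)
class CodonMap:
    """Bijection between genomic coding positions and (residue, codon offset).

    ``residue_index`` is 1-based and includes the model's ``residue_offset``;
    ``codon_offset`` is 0, 1 or 2.
    """

    model: GeneModel
    _pos_to_codon: Mapping[int, tuple[int, int]] = field(repr=False)
    _codon_to_pos: Mapping[tuple[int, int], int] = field(repr=False)

    @classmethod
    def from_model(cls, model: GeneModel) -> "CodonMap":
        spliced_positions: list[int] = []
        for exon in model.exons:
            spliced_positions.extend(range(exon.start, exon.end))
        coding = spliced_positions[model.cds_start_offset :]
        coding = coding[: len(coding) - len(coding) % 3]
        pos_to_codon: dict[int, tuple[int, int]] = {}
        codon_to_pos: dict[tuple[int, int], int] = {}
        for cds_index, pos in enumerate(coding):
            residue = model.residue_offset + cds_index // 3 + 1
            offset = cds_index % 3
            pos_to_codon[pos] = (residue, offset)
            codon_to_pos[(residue, offset)] = pos
        return cls(model, pos_to_codon, codon_to_pos)

    def residue_at(self, genomic_pos: int) -> tuple[int, int]:
        """(residue_index, codon_offset) for one genomic coding position."""
        try:
            return self._pos_to_codon[genomic_pos]
        except KeyError:
            raise GeneModelError(
                f"position {genomic_pos} is not a coding position"
            ) from None

    def is_coding(self, genomic_pos: int) -> bool:
        return genomic_pos in self._pos_to_codon

    def codon_positions(self, residue_index: int) -> tuple[int, int, int]:
        try:
            return tuple(  # type: ignore[return-value]
                self._codon_to_pos[(residue_index, k)] for k in range(3)
            )
        except KeyError:
            raise GeneModelError(f"residue {residue_index} not in codon map") from None

    def codon_sequence(self, residue_index: int) -> str:
        return "".join(self.model.sequence[p] for p in self.codon_positions(residue_index))

    @property
    def first_residue(self) -> int:
        return self.model.residue_offset + 1

    @property
    def last_residue(self) -> int:
        return self.model.residue_offset + self.model.protein_length


def residues_of_span(
    model: GeneModel, start: int, end: int
) -> tuple[int, int, list[int]]:
    """Residues touched by a genomic span ``[start, end)`` within the CDS.

    Returns ``(first_residue, last_residue, codon_offsets)`` where the residue
    indices are 1-based (including the model's numbering offset) and
    ``codon_offsets`` lists the codon position of every coding base in the
    span, in order.
    """
    if end <= start:
        raise GeneModelError(f"empty span [{start}, {end})")
    cmap = model.codon_map()
    hits = [cmap.residue_at(p) for p in range(start, end) if cmap.is_coding(p)]
    if len(hits) != end - start:
        raise GeneModelError(f"span [{start}, {end}) is not fully within the CDS")
    residues = [r for r, _ in hits]
    return min(residues), max(residues), [k for _, k in hits]


# -- loading ------------------------------------------------------------------

EXON_TABLE_COLUMNS = ("allele_id", "exon_id", "start", "end")


def load_gene_model(
    fasta_path: str | Path,
    exon_table_path: str | Path,
    *,
    allele_id: str | None = None,
    cds_start_offset: int = 0,
    strand: str = "+",
    residue_offset: int = 0,
) -> GeneModel:
    """Load one allele from a FASTA record and a TSV exon table.

    The exon table needs columns ``allele_id, exon_id, start, end`` (0-based
    half-open).  If ``allele_id`` is not given, the first FASTA record is
    used and its id must appear in the table.  Reverse-strand genes
    (``strand="-"``) are reverse-complemented into CDS orientation and their
    exon coordinates flipped, so the returned model is always CDS-oriented.
    """
    records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if not records:
        raise GeneModelError(f"no FASTA records in {fasta_path}")
    if allele_id is None:
        allele_id = next(iter(records))
    if allele_id not in records:
        raise GeneModelError(f"allele {allele_id!r} not found in {fasta_path}")
    sequence = records[allele_id]

    table = pd.read_csv(exon_table_path, sep="\t", comment="#")
    missing = set(EXON_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise GeneModelError(f"exon table missing columns: {sorted(missing)}")
    rows = table[table["allele_id"].astype(str) == str(allele_id)]
    if rows.empty:
        raise GeneModelError(f"no exon rows for allele {allele_id!r}")
    exons = [
        Exon(str(r.exon_id), int(r.start), int(r.end))
        for r in rows.itertuples(index=False)
    ]
    return build_gene_model(
        allele_id,
        sequence,
        exons,
        cds_start_offset=cds_start_offset,
        strand=strand,
        residue_offset=residue_offset,
    )


def build_gene_model(
    allele_id: str,
    sequence: str,
    exons: Iterable[Exon | tuple[str, int, int]],
    *,
    cds_start_offset: int = 0,
    strand: str = "+",
    residue_offset: int = 0,
) -> GeneModel:
    """Construct a validated GeneModel, flipping '-'-strand input into CDS orientation."""
    exon_list = [e if isinstance(e, Exon) else Exon(*e) for e in exons]
    exon_list.sort(key=lambda e: e.start)
    if strand == "-":
        n = len(sequence)
        sequence = str(Seq(sequence).reverse_complement())
        exon_list = [Exon(e.exon_id, n - e.end, n - e.start) for e in reversed(exon_list)]
        exon_list.sort(key=lambda e: e.start)
    return GeneModel(
        allele_id=allele_id,
        sequence=sequence.upper(),
        exons=tuple(exon_list),
        cds_start_offset=cds_start_offset,
        strand=strand,
        residue_offset=residue_offset,
    )


def load_gene_model_gff3(
    fasta_path: str | Path,
    gff3_path: str | Path,
    *,
    allele_id: str | None = None,
    feature: str = "exon",
    **kwargs,
) -> GeneModel:
    """Load a model using exon/CDS features from a GFF3-like file.

    Only ``seqid``, ``type``, ``start`` and ``end`` columns are used; GFF3
    coordinates (1-based inclusive) are converted to 0-based half-open.
    """
    cols = ["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"]
    table = pd.read_csv(gff3_path, sep="\t", comment="#", names=cols, header=None)
    records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if allele_id is None:
        allele_id = next(iter(records))
    rows = table[(table["seqid"].astype(str) == str(allele_id)) & (table["type"] == feature)]
    if rows.empty:
        raise GeneModelError(f"no {feature!r} features for {allele_id!r} in {gff3_path}")
    strands = set(rows["strand"])
    strand = kwargs.pop("strand", strands.pop() if strands <= {"+", "-"} and len(strands) == 1 else "+")
    exons = [
        Exon(f"{feature}{i + 1}", int(r.start) - 1, int(r.end))
        for i, r in enumerate(rows.sort_values("start").itertuples(index=False))
    ]
    if allele_id not in records:
        raise GeneModelError(f"allele {allele_id!r} not found in {fasta_path}")
    return build_gene_model(allele_id, records[allele_id], exons, strand=strand, **kwargs)
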