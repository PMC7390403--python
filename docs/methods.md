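# Methods

This note describes the models implemented in g0mosaic, the assumptions
behind them, the parameters that matter, and what the synthetic-data
generator does and does not emulate.

## Reference models and coordinates

A `GeneModel` is one allele of a homeologous pair: genomic sequence in CDS
orientation, sorted non-overlapping exons (0-based half-open), a CDS start
offset within the spliced transcript, and a `residue_offset` so that local
fixtures carry full-protein residue numbering.  Reverse-strand input is
reverse-complemented at load time so all downstream logic has one
orientation.  The `CodonMap` is a bijection between genomic coding positions
and (1-based residue, codon offset) pairs; every residue/HGVS number in the
package flows through it.  User-facing reports are 1-based; internal
arithmetic is half-open.

The exon 6 fixtures are reconstructions from printed sequences only: the
24-nt local CDS is spacer + PAM + one base, with the reading frame anchored
by the requirement that the 15-bp PAM-containing variant window translate to
the wild-type peptide GGRRG (residues 269–273).  The surrounding synthetic
amplicon (intron / 69-nt exon / intron, ~190 bp) pins the printed core and
the His274 codon and fills the rest with generated sequence; the S and L
homeolog versions differ at a few intron positions (two inside the first
40 nt so the 5′-identity rule can discriminate them).  The exon 3 fixture is
a synthetic 123-nt, 41-codon exon pinning only the printed residues
(Met141 … Lys145[AAA] Pro146 Gly147).  Passing tests therefore validate the
algorithms on locus-faithful local context, not the full genomic loci.

## Cut sites and the seed rule

SpCas9 sites are located by IUPAC-aware scanning of both strands for
spacer matches with at most *k* substitutions followed immediately by the
PAM pattern (default NGG).  The cut is modelled as blunt, 3 bp 5′ of the PAM
(the canonical SpCas9 position; the biology allows 3–4 bp and the distance
is PAM-relative, so 21–22-nt spacers behave identically).  A guide is called
*inactive* when any recorded spacer mismatch falls within the PAM-proximal
seed, default 10 bases (the literature range is 8–10; configurable).  This
reproduces the behaviour of the single- and double-mismatch control guides,
which differ from the active guide only at seed positions 17–18.

## MMEJ enumeration

A deletion of size *d* is MMEJ-compatible when the *m* bases entering the
junction equal the *m* bases leaving it for some *m* ≥ `min_microhomology` —
equivalently, when identical *m*-mers start *d* apart.  Because a deletion
within a repeat can be placed at several physical positions that yield the
same repaired molecule, products are handled as equivalence classes: the
full contiguous placement run is computed, a product is kept when **some**
placement contains or abuts the cut, and products are deduplicated by
product sequence (the stored `deleted_interval` is the 3′-most placement,
consistent with lesion normalisation).  A strict "contains the cut" test
would wrongly drop the 3-bp AGA-repeat deletion, whose interval can only
abut the cut.  Microhomology lengths are maximal common extensions and may
exceed *d* inside tandem repeats; that is real repeat structure, not an
artifact.

Enumeration defaults (`min_microhomology=2`, `max_deletion=30`) are
deliberately permissive for prediction.  On the exon 6 site with
`max_deletion=12` the in-frame products are exactly the 3/6/6/9/9/12-bp
deletions removing 1, 2, 2, 3, 3 and 4 residues from within residues
269–273 — the three stereotyped products (1, 3, 4 aa) plus two rarer 2-aa
products, all confined to the di-arginine loop.

Each product carries a weight `mh_length × exp(−d / L)` (L = 20 bp,
normalised).  The weighting is a stated, monotone convenience — longer
homology up, longer deletion down — used **only** by the repair simulator to
draw outcomes; the caller and annotator never consult it.

## Read calling

Sanger clone inserts are full amplicons and get end-to-end global alignment;
NGS reads shorter than the amplicon get semi-global alignment (free end gaps
on the unspanned reference).  Scores: match +2, mismatch −4, gap open −10,
gap extend −1 (a length-L gap costs −10 −(L−1)); alignment is delegated to
Biopython's PairwiseAligner and verified against a brute-force affine DP on
short strings.  Indel placement ties are resolved by the aligner's
deterministic enumeration order and then erased by normalisation: all events
are right-aligned (3′-shifted) within repeats, matching the HGVS convention,
so the stereotyped exon 6 deletions name identically regardless of physical
junction.

Homeolog assignment takes the higher alignment score; a near-tie (score gap
≤ 4, about one mismatch) falls back to identity over the 5′-terminal 40
bases — the rule used to split PCR-chimeric reads by the homeolog identity
at the 5′ end of the product — and reads that remain unresolved are
"ambiguous" (a value, not an error).

The lesion of a read is the set of normalised events intersecting the
variant window (15 bp ending one base 3′ of the PAM, snapped outward to
codon boundaries); out-of-window events are kept separately and still feed
consequence annotation, so a frameshift outside the window is not missed.
The realised window sequence is reconstructed canonically from the
normalised events (placement-invariant), which is what makes noise-free
round-trip recovery exact.  Reads that do not span the window, or that
carry N inside it, are *uninformative* — never counted as mutant.
Wild-type status is peptide-level by definition: window sequence length a
multiple of three and translating to the reference window peptide.  A
documented consequence is that synonymous substitutions inside the window
count as wild type.  Out-of-window substitutions do not affect wild-type
status; they are reported separately.

## Consequences and scores

Splice flags take precedence over codon arithmetic.  A deletion removing an
acceptor dinucleotide is assumed to skip its exon: if the exon length is a
codon multiple the consequence is an in-frame loss of `length/3` residues,
otherwise a frameshift.  A deletion removing a donor is assumed to retain
the following intron, evaluated by literal read-through translation: a stop
(or lost frame) truncates the protein and scores 01; a codon-multiple,
stop-free intron is an in-frame insertion of `length/3` residues.

Otherwise events are projected onto the CDS (intron-interior events away
from splice dinucleotides are protein-silent), the mutated CDS is
translated, and the peptide diff — maximal common prefix, then suffix, the
3′-most description — classifies the lesion: frameshift (net indel not a
multiple of 3), nonsense (premature stop anywhere in the mutated CDS, not
just the window), in-frame deletion / insertion / delins / missense,
synonymous, or wild type.  "Amino acid changes" counts substituted +
inserted + deleted residues summed over events; a delins counts
max(deleted, inserted).  The genotype score is then a deterministic table:
frameshift/nonsense/truncating → 01; in-frame changes of >20, 11–20, 6–10,
1–5 residues → 02–05; no peptide change → 06.  The score grades sequence
change, not function: a conserved missense at a critical residue still
scores 05 even when the biology says it is inactivating.

## Cohort statistics

Embryo summaries group informative calls by exact in-window sequence
identity per homeolog, so distinct junctions with identical products merge.
Score frequencies are tabulated overall and split heart-defect vs normal
(four phenotype classes are retained in records; the dichotomy pools the
three defect classes).  The wild-type/phenotype association is one
pre-specified one-sided Fisher exact test per cohort — the exact
hypergeometric tail P(X ≥ a), no approximation, appropriate at n = 16 —
with zero-cell odds ratios flagged degenerate rather than infinite.  No
multiple-testing correction is applied, and none is needed for a single
pre-specified test.  Note that a one-sided exact p for a balanced table is
about 0.69, not 1: the tail includes the observed table.

## The simulator

The generator is phenomenological: it draws the *observed* statistical
structure of mosaic G0 animals rather than mechanistically simulating
S-phase replication at the 1→2-cell transition.

Per homeolog, an embryo carries 1–6 distinct alleles with probabilities
(0.15, 0.30, 0.25, 0.15, 0.10, 0.05) — mass concentrated at ≤ 4 — and
symmetric Dirichlet(1.5) frequencies.  Each allele escapes unrepaired
(wild type) with probability 0.12; otherwise one repair outcome is drawn:
a 1-bp substitution at the cut (p = 0.04), an MMEJ deletion (p = 0.7 of
mutagenic repairs, drawn by product weight from the pool of ≤ 12-bp
deletions with ≥ 3 bp microhomology — annealing at strong repeats; on the
exon 6 site this pool is entirely in-frame), or an NHEJ indel (truncated
geometric sizes: deletions up to 24 bp, insertions up to 6 bp, matching the
printed size ranges).  Under these defaults roughly three quarters of
mutant alleles at the exon 6 site are in-frame — the qualitative dominance
of in-frame deletions; the generative in-frame probability is exposed
analytically (`RepairModel.inframe_probability`) and is not asserted to
equal any published percentage.

Phenotype follows a minimal operationalisation of the lineage argument:
each embryo draws a cardiac-lineage share c ~ Beta(12, 2) (most alleles
reach heart tissue; exclusion is the exception), each allele reaches the
cardiac lineage with probability c, and the heart forms normally iff the
*functional* allele fraction among cardiac-reaching alleles is at least
θ = 0.1.  `functional_scores` defaults to {6}: at this target the common
score-05 in-frame deletions remove the essential di-arginine loop, so only
wild-type alleles rescue.  (Scoring 05–06 as functional is appropriate at
permissive sites and remains one configuration flag away.)  These defaults
were chosen to reproduce the reported cohort structure — about a third of
embryos normal, wild-type alleles detected in essentially every normal
embryo but only ~a fifth to a quarter of defect embryos — and they give
the pre-specified association test ~90% power at n = 16.

Sequencing error is uniform per-base substitution (rate ≤ 0.1), recorded
per read in the manifest.  NGS reads are fixed-length single-end reads from
either product end, so only reverse-orientation reads span a 3′-proximal
target site — the situation the orientation filter exists for.  The truth
manifest records, per allele: sequence, frequency, events, consequence,
score, lineage reach; per read: source allele, orientation, injected
errors.  All randomness flows from a single `numpy.random.default_rng`
seed; outputs are byte-identical across runs.

What the simulator does **not** emulate: PCR chimera formation (the 5′-rule
is exercised on constructed fixtures), quality-score structure, indel
sequencing errors, coverage bias, more than one repair event per allele,
and true lineage topology (reach is i.i.d. Bernoulli per allele, not a cell
genealogy).  Passing round-trip tests therefore demonstrate correctness of
the calling/annotation chain on realistic allele spectra, not robustness to
every artifact of real amplicon data.

## Numerical and degenerate-input choices

- Windows are snapped outward to codon boundaries and must translate to a
  whole peptide; non-codon-aligned windows are errors, not warnings.
- Terminal alignment indels are coverage artifacts, excluded from events;
  coverage is judged on the aligned reference span.
- Normalisation is idempotent; all invariants are enforced by property
  tests seeded with fixed generators.
- Empty exons, overlapping exons, out-of-range coordinates, CDS < 3 nt,
  invalid IUPAC characters, cut positions outside the sequence, windows
  outside the reference, unknown phenotype labels and single-group cohorts
  all raise typed errors naming the offending object.
- Problem sizes in the default test run (16 × ~31 clones for round-trip;
  200 × 16-embryo cohorts for power; 1000 alignment pairs, 500 random
  40-mers and every 2×2 table with n ≤ 30 for the oracles) keep the whole
  suite under a minute while leaving the statistical checks well-powered.

## Known limitations

- Wild-type classification is strictly window-scoped; reads wild type in
  the window but substituted elsewhere are reported via their
  out-of-window events, not reclassified.
- The annotator scores one allele at a time; multi-lesion alleles are
  supported, but a frameshift dominates regardless of other events.
- Exon-skip and intron-retention consequences assume the printed splice
  rules; no splice-strength model is attempted.
- The MMEJ weighting is a stated convenience, not a learned repair model;
  genome-wide off-target search and bulge alignment are out of scope.
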