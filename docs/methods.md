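# Methods

This note documents the models, rules and numerical choices behind
`glutenscan`, and what its synthetic benchmarks do and do not show.

## In silico digestion

Cleavage is modelled as C-terminal to a specificity set: K/R for
trypsin, the broad set F/W/Y/L/M for chymotrypsin. The exact
chymotryptic specificity in any given experiment is uncertain (narrow
F/W/Y definitions are also in use), so the residue set is configurable
(`DigestSpec.cleavage_residues`); the broad default is consistent with
observed chymotryptic prolamin peptides ending in L, Y and F. The
proline rule (no cleavage when the next residue is P) is on by default:
prolamin repeats are proline-rich, and peptides monitored in practice —
`DVSPGCRPITVSPGTR` with its internal RP, `PDEKDAEGQLPSR` with a genuine
missed K-D cleavage — require it. A proline-suppressed position is not
a cleavage site at all and therefore does not count as a missed
cleavage.

Defaults `max_missed_cleavages = 2` and `min_length = 5` are
community-standard search settings; both are explicit parameters.
N-terminal Met is never stripped (no silent sequence edits), and the
ambiguity code X neither cleaves nor matches inside motifs.

Invariants enforced by tests: the missed-cleavage-0 peptides
concatenate exactly to the parent; every peptide contains exactly its
declared number of internal sites; the digest agrees with a brute-force
substring oracle on random sequences; disabling the proline rule never
removes sites.

## Epitope model

Three motif classes:

* **R5** — the 5-mer recognition motifs of the R5 monoclonal antibody
  (QQPFP, QQQFP, QLPFP, LQPFP). A full occurrence is required
  (`min_core_match` = motif length).
* **DQ_core** — 9-mer HLA-DQ2.5/DQ8 cores; a peptide-level hit
  requires the complete 9-mer.
* **immunogenic_Tcell** — longer confirmed T-cell epitope regions; a
  peptide-level hit requires ≥ 9 contiguous residues of the region (the
  intact-core criterion), operationalised as the longest common
  contiguous substring between peptide and region, threshold 9. The
  exact matching algorithm behind published counts is not specified
  anywhere we could adopt it from; longest-common-substring is the most
  conservative reading of "at least nine residues of the epitope
  region". Ties resolve to the earliest motif substring and the
  earliest peptide position, keeping reports byte-stable.

Protein-level scanning reports **every** start position including
overlapping occurrences. Prolamin repeat regions make overlapping
motifs the norm; counting each occurrence is the only convention under
which instance counts are additive over concatenation and invariant to
input order, both of which are property-tested.

The shipped motif list is a curated starter set: the four R5 motifs,
canonical DQ2.5/DQ8 cores in Sollid nomenclature, and curated T-cell
region entries (including the 13-mer `PQQPFPQPQQPFP` recorded against
IEDB epitope 226653 and C-hordein repeat-region entries related to the
symptom-eliciting R15/B29 peptide families). It is a screening default,
not a clinical registry; regulatory users should supply their own list
via `motif_list`. Deamidated (Q→E) variants are deliberately not
matched: scanning is over unmodified sequences, and tissue
transglutaminase chemistry is outside the model.

Census conventions: *instances* = total occurrences summed over motifs;
*carriers* = distinct proteins (or protein groups, when a group map is
supplied) with ≥ 1 occurrence; peptide censuses deduplicate by sequence
first. Protein grouping is an externally supplied map because grouping
algorithms are search-engine-specific; the default (one group per
accession) makes the census independent of any search software. The
R5/DQ overlap is reported both pooled (DQ_core ∪ immunogenic_Tcell vs
R5) and as the full class-subset lattice, so either pooling convention
is recoverable.

## MRM aggregation

Within one technical replicate, a peptide's abundance is the sum of its
transition peak areas over all transitions and over both Met redox
forms — the oxidised (+16 Da) and reduced precursors are two
observations of the same molecule and reporting them separately would
double-count. Per sample, `summed_area` is the mean of replicate-level
sums and `cv` their sample standard deviation (n−1) over the mean.
A peptide missing from some of a sample's replicates has those
replicate sums treated as 0 and is flagged in the log; a missing
transition within a replicate simply contributes nothing (exports
routinely omit below-noise transitions, and zero-filling whole
replicates invisibly would deflate means without a trace).

Class summaries report mean, SD and net (summed) area over member
peptide abundances per sample and class. Net hordein is the sum over
the B-, C-, D- and γ-hordein classes only; ALPs (avenin-like proteins)
belong to the prolamin family but are not hordeins and never enter the
net total. Summing means-over-replicates rather than per-replicate sums
is equivalent in expectation and keeps the net total a deterministic
function of the published per-peptide table.

Detection is `summed_area > threshold` with threshold 0 by default; the
heatmap export encodes undetected cells as a distinguished missing
marker (NaN / "NA") rather than 0, matching the grey-cell convention of
heatmap tools.

## ELISA concordance

The concordance report computes label-group means (rounded to 1
decimal, with raw values preserved), the low-gluten group mean as a
percentage of the highest control value (nearest integer), a Spearman
rank correlation between ELISA mg/kg and net hordein MS area, and a
mismatch table of samples whose ascending ranks under the two
techniques differ by more than `rank_margin` (default 3). Spearman is
used because the MS signal is a relative measure with
peptide-dependent ionisation efficiency: only the ordering is
comparable across techniques. With fewer than 3 paired samples the
correlation is omitted with a warning.

On the shipped 14-beer survey table the low-gluten mean is
53.9/9 = 5.99 mg/kg and the ratio to the 146.3 mg/kg control is 4.09 %
→ 4 %. (Published summaries of this arithmetic print 5.9, a truncation
of the same quantity; the package reports the computed value.)

## Synthetic data

`simulate_proteins` builds Q/P-rich sequences from prolamin-like repeat
units plus weighted background residues, scrubs accidental occurrences
of every planted motif by point substitution (with a residue absent
from all planted motifs, so scrubbing cannot create occurrences),
splices in the planted copies at random anchors, and verifies final
counts with an independent naive scanner — redrawing up to a retry
limit and failing loudly if the plant density is unsatisfiable. Plans
in which one planted motif is a substring of another are rejected up
front (exact counts would be unsatisfiable by construction). The truth
table is therefore exact, and census recovery tests against it are
non-circular.

`simulate_transitions` models a peptide's transition areas as
`true_abundance × transition_fraction × met_share × exp(N(0, σ²))`,
with one lognormal factor per (peptide, replicate): transitions of one
injection co-vary on a real instrument, and this choice makes the
replicate CV equal the lognormal CV √(exp σ² − 1) ≈ σ for small σ,
which the tests check against a Monte-Carlo band. Defaults mirror the
targeted-assay design the package consumes: 3 transitions (fractions
0.5/0.3/0.2), 4 technical replicates, met-oxidised share 0.1,
σ = 0.1. At σ = 0 the aggregation pipeline recovers true abundances
exactly (fractions and the redox split are conservation-by-
construction), which pins the arithmetic; at σ = 0.1 the benchmark
requires Spearman(estimate, truth) > 0.95 over 20 peptides spanning
two orders of magnitude.

`simulate_study` chains the two: proteins are digested, the first three
fully-specific peptides per protein form the monitored panel and
inherit the parent's class; per-sample hordein levels are log-spaced
over two orders of magnitude and shuffled; the ELISA-like readout is a
linear (hence monotone) transform of the true net hordein abundance,
scaled so the highest sample reads ≈ 150 mg/kg, with an optional
multiplicative suppression factor on designated samples. Suppression
is a rank-distortion device, not an antibody model: it exists so the
mismatch-table logic has a controlled positive case.

What the synthetic benchmarks do **not** show: real transition
interference and chromatographic integration error, search-engine
peptide-detection bias, matrix-dependent ELISA chemistry, or real
prolamin haplotype diversity. Passing them demonstrates that the
*arithmetic and logic* of the pipeline are correct, not that any
particular beer is safe.

## Problem sizes

The bundled benchmarks use proteomes of 60–100 synthetic proteins,
panels of ~20–30 peptides, 4 replicates and 6–9 samples — sizes chosen
so the full suite and the acceptance script run in seconds while still
exercising every code path, overlap case and aggregation level. All
generators accept larger sizes unchanged; census of a full reference
proteome (≈ 36k entries) is a single `glutenscan census` run over the
corresponding FASTA.

## Known limitations

* The curated motif list is a starter set; published per-sample epitope
  counts depend on the exact epitope inventory and protein-grouping
  software used, neither of which this package pins.
* The wheat marker default list covers 7 wheat-specific peptides; a
  full regulatory panel should be supplied by the user.
* Absolute gluten quantitation (mg/kg from MS signal) is out of scope:
  peak areas are relative and peptide-specific.
* Semi-specific and non-specific digestion are not modelled; peptides
  with one non-enzymatic terminus (as process-derived hydrolysis can
  produce) must be supplied in detected-peptide lists rather than
  predicted.
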