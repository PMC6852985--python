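# Methods

`mirseed` implements the desk side of a plant small-RNA study that
contrasts two genotypes of a grass with different reproductive modes
(a sexual cultivar, genotype `O`, and an apomictic cultivar, genotype
`T`), from raw sequencing reads to candidate miRNA–mRNA regulatory
pairs.  This note records the models, the parameters that matter, the
numerical choices, and what the synthetic data do and do not show.

## Read cleanup and sequence tags

Raw reads are 3′-adapter-trimmed at the **leftmost position where the
read's suffix matches a prefix of the adapter with at least 8 nt of
overlap** (a read ending inside the adapter is still recognized).
Trimming repeats until no such suffix remains, which makes the
operation idempotent even when the insert itself happens to end in an
adapter prefix; the rare cost is clipping a genuine insert that mimics
the adapter.  Trailing bases below Q20 (Phred+33) are then removed.
Inserts outside the 17–33 nt window, and reads containing `N`, are
discarded — every downstream comparison is an exact, ungapped match
over `{A,C,G,T}`, so ambiguity codes have no sensible semantics here.
`U` and `T` are identified throughout; the internal canonical alphabet
is DNA.

Clean reads of each library are collapsed into **sequence tags**
(unique sequence + per-library read count, labelled `<LIB>_<count>`),
and tags with a per-library count below 3 are discarded.  Two details
matter:

* The minimum count is applied **per library** (libraries are
  collapsed separately), matching how the per-library tag tables are
  built.
* A tag that passes the filter in at least one library keeps its
  **untruncated** counts everywhere.  Zeroing a replicate's true count
  of 1–2 because it fell below the threshold would manufacture
  replicate variance out of nothing; in practice it inflated the
  moment estimate of the negative-binomial dispersion by an order of
  magnitude and destroyed differential-expression power, which is why
  the count matrix is assembled this way.

## Depuration (contamination subtraction)

Tags are subtracted in the fixed order **mitochondria → chloroplast →
ncRNA families**, using end-to-end ungapped alignment with 0
mismatches by default (configurable).  Organellar references are
searched on both strands (they are DNA genomes); ncRNA references only
in the forward orientation (they are transcribed molecules).  Each
stage reports aligned/non-aligned counts and percentages **relative to
that stage's input**, so the report nests the same way the depuration
statistics of such studies are usually tabulated.  Correctness is
defined by the exhaustive sliding-window scan; the implementation uses
a substring fast path at 0 mismatches and a vectorized window
comparison otherwise, and the tests hold it to the brute-force
contract.

## Conserved-miRNA classification

A tag is **conserved** if it has an ungapped local alignment to a
mature or precursor miRNA database entry with ≤ 2 substitutions
covering ≥ 90 % of the **tag** length.  Coverage is defined on the tag
(not the database entry) because tags are much shorter than hairpin
precursors.  Mature-set hits take precedence over hairpin-only hits;
among equals, the best hit (fewest mismatches, longest alignment,
smallest identifier) decides the family, and each tag is counted
exactly once.  Families are parsed from the `miR<number>` token of
database identifiers.

The search is seeded with a shared-k-mer diagonal index: with ≥ 16
aligned positions and ≤ 2 mismatches every qualifying alignment must
contain an exact run of ≥ 5 nt (pigeonhole), so a k = 5 index loses
nothing; when relaxed thresholds void that guarantee (e.g. the
naming search below) the code falls back to full diagonal enumeration.
An equivalence test holds the seeded path to the exhaustive one.

Family members are aligned to their anchoring database entry and
summarized by **positional majority consensus**; distinct consensus
clusters within a family are lettered `a, b, …` in descending
total-count order and named with the species prefix (default `ecu`),
e.g. `ecu-miR156a`.  Majority ties break toward the alphabetically
smallest base, which keeps the output deterministic.

## Novel-miRNA discovery and the degradation filter

Non-conserved depured tags are mapped to the reference transcriptome
**exactly** (no mismatches, no gaps, forward strand only — transcripts
are oriented mRNA).  Each hit transcript gets a read-count-weighted
coverage profile; covered runs separated by ≤ 5 nt merge into loci.
A transcript is called a **degradation product** when

* coverage breadth ≥ 0.8 (the operationalization of "reads across the
  transcript's entire length"; the original call was visual, so the
  threshold is configurable and recorded in report headers), or
* more than 2 loci, or
* any locus wider than 30 nt.

Because tags are ≥ 17 nt, any merge of two distinct loci produces a
locus wider than 30 nt, so adding coverage can never rescue a
degradation call — the classification is monotone in coverage.
Surviving loci each yield one candidate represented by the
highest-count member tag.  Candidates are named after the family of
their best relaxed homology hit (≤ 5 mismatches, ≥ 70 % coverage)
against the known-miRNA set, or serially (`ecu-novel-N`) when no
relative exists.  Hairpin-precursor folding is deliberately **not**
performed: in this design novel miRNAs are corroborated through their
predicted targets, not through secondary structure.

## Target scoring

A miRNA (5′→3′) is aligned antiparallel against each transcript window
(3′→5′).  Per-position penalties follow the plant target-prediction
convention: Watson–Crick 0, G:U wobble 0.5, mismatch 1.0, miRNA-side
bulge 2.0, all **doubled within the seed** (miRNA positions 2–13,
1-based from the 5′ end).  The penalty total is the **expectation**;
sites above 2.5 are rejected.  Additional hard rules:

* any true mismatch in the seed rejects the duplex — G:U wobbles in
  the seed are penalized but allowed, which is what lets a non-WC pair
  occupy the central window (9–11 ⊂ 2–13) at all;
* bulges on the target side are not allowed (window length may be at
  most one less than the miRNA length, i.e. one miRNA bulge);
* a non-WC pair at positions 9–11 switches the predicted silencing
  mode from cleavage to translational inhibition.

Scanning evaluates **every** window offset (widths m and m−1); a
vectorized pass pre-filters windows with the same penalty table and
each surviving window is re-scored by the scalar reference
implementation, so the scan is bit-identical to exhaustive
enumeration (and tested as such).  Overlapping accepted sites are
reduced to the local minimum-expectation site (ties: leftmost).

Site accessibility (the energy to unpair the site plus 17 nt upstream
and 13 nt downstream of flank, cutoff 20) is a pluggable callable.
The shipped default is a deterministic, structure-free GC-content
proxy (`28·GC + 4`, so an average-composition region passes the
cutoff and strongly GC-enriched regions do not); it ranks openability
sensibly but is *not* a partition-function calculation, and any
thermodynamic folder with the same call signature can be substituted.
Accessibility filtering is off unless a backend is supplied.

One symmetry caveat: expectation is invariant under exchanging the
two strands of a duplex only for wobble-free duplexes, because a G:U
pair maps to C:A (a mismatch) under complementation; the property
tests therefore check strand-exchange invariance on wobble-free
instances.

## Differential expression

Counts are normalized to counts per million of the depured library
totals.  The genotype test is an **exact conditional
negative-binomial test**: replicate libraries are scaled to the
geometric-mean library size and summed within genotype; conditional on
the pooled total *n*, the p-value is the summed probability of every
split no more likely than the observed one (ties included —
conservative).  With *n_A* and *n_B* summed libraries per genotype and
common dispersion φ, each genotype sum is negative binomial with size
*n_g*/φ and the success probability cancels in the conditional law; at
φ = 0 the conditional law is Binomial(n, n_A/(n_A+n_B)).  φ is a
pooled method-of-moments estimate over within-genotype replicates,
floored at 0, with a Poisson fallback (and warning) when no genotype
has replicates.  This is a deliberate, documented approximation of the
exact test popularized by count-based DE packages — numerical identity
with any particular package is neither claimed nor tested.

Fold changes use a 0.5 pseudo-count per side so that tags detected in
only one genotype get a finite log2 fold change (and an all-zero tag
gets exactly 0).  Benjamini–Hochberg adjustment is the step-up
procedure; calls require adjusted p < 0.01 **and** |log2FC| > 2, both
strict (a fold change of exactly 2 is not called).

## qPCR quantification

Technical replicates are averaged per biological sample; ΔCt = target
− reference-gene Ct per sample, ΔΔCt subtracts the calibrator
genotype's mean ΔCt, and relative expression is 2^−ΔΔCt with
amplification efficiency fixed at 2.0 (instrument-software efficiency
correction is out of scope).  Genotype means are compared with a
two-sided Student's t-test (pooled variance; Welch available by
flag); p < 0.05 is flagged significant.

## The synthetic study

The generator emulates the marginal statistics of four spikelet
small-RNA libraries (2 genotypes × 2 replicates, named
`O2P1/O2P2/T3P1/T3P2`) rather than any real sequence content:

* **Reads** are insert + 3′ adapter + random fill, truncated to a
  50 nt instrument read length, so every insert ≤ 33 nt carries
  adapter sequence and the trimmer is always exercised.  The default
  adapter is the standard Illumina small-RNA 3′ adapter
  (`TGGAATTCTCGGGTGCCAAGG`); the kit used in real studies of this
  kind is proprietary, so the adapter is configurable and tests pass
  it explicitly.
* **Insert lengths** follow a two-mode mixture peaking at 21 and 24 nt
  (weights 0.55/0.45, ±2 nt spread), reproducing the canonical bimodal
  small-RNA length profile.
* **Class composition** per library: 0.45 % organellar fragments
  (both strands), 4.5 % ncRNA fragments, 0.4 % conserved-miRNA reads,
  3 % degradation tiles, 0.4 % novel-miRNA reads, rest random
  background.  These match the depuration and annotation fractions
  such libraries typically report.  All classes draw from a fixed,
  seed-determined pool of insert sequences via one multinomial per
  library; 18 % of the background mass is a stream of fresh random
  singletons whose tags the minimum-count filter is designed to
  remove, which lands the discarded-read fraction near the ~20 %
  such studies report.
* **Conserved reads** are drawn from 5 miRNA families (1–3 members
  each, database-style identifiers such as `osa-miR156a-5p`) with
  fixed variants at 0/1/2 substitutions (probabilities 0.7/0.2/0.1);
  hairpin precursors embed each mature sequence in 25 nt flanks.
* **Degradation** transcripts are tiled with 60 overlapping 17–30 nt
  windows on a start grid spanning the whole transcript.
* **Novel loci** are exact 21 nt slices of four ordinary transcripts.
* **Planted target sites** are perfect reverse complements of the four
  novel loci and three mature miRNAs, implanted into otherwise
  untouched transcripts.
* **Fold-change spikes**: two novel loci are scaled 2³ = 8× (one per
  genotype) before the library draw; global weight renormalization
  keeps the realized fold change within ~1 % of the nominal one.
  A companion Ct table encodes the same spikes (one cycle per
  doubling) with 0.05-cycle Gaussian jitter around target Ct 25 and
  reference Ct 20.

Identical configurations (seed included) give byte-identical FASTQ,
FASTA, and truth outputs.

**What passing on synthetic data does not show.**  The generator has
no sequencing-error model beyond none, uniform Q40 qualities, no PCR
duplicates, no isomiR end-heterogeneity, no genomic repeat structure,
and background sequences are uniform random — far easier to separate
from references than real intergenic reads.  Recovery of all planted
signals therefore validates the *logic and arithmetic* of every stage,
not its robustness to real-library noise.

## Problem sizes and defaults

The default simulation draws 50 000 reads per library (200 000 reads
total), 40 transcripts, a 6 000-tag background pool — sizes chosen so
a full end-to-end run completes in well under a minute while every
per-library statistic (0.4 % conserved, ~20 % discarded) is estimated
from hundreds of reads or more.  The test suite reuses a single
session-scoped study at 35 000 reads per library, which keeps planted
differential tags above ~30 reads per library in the unscaled
genotype.  Statistical acceptance checks use 10⁴ simulated null tags
(empirical type-I error), 10⁴ random p-vectors (BH equivalence), and
all splits of totals up to 200 (exact-test equivalence).

## Known limitations

* The dispersion estimator is a pooled moment estimator; for very few
  tags or very low counts it is noisy, and it is floored at 0 rather
  than shrunk toward a trend.
* The accessibility backend is a heuristic proxy; UPE values are not
  comparable to thermodynamic energies.
* Consensus naming anchors members to database entries; families whose
  members hit disjoint database entries with identical consensus are
  merged, but partially overlapping anchors can still split a cluster.
* The exact test conditions on summed, size-equalized genotype counts;
  with highly unequal library sizes the integer rounding of scaled
  counts discards a small amount of information.
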