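# Methods

This note documents the models and estimators implemented in
`overlapqc`, the parameters that matter, the synthetic-data generator
the test suite is built on, and the numerical choices made where the
design was genuinely open.

## The non-sense read model

Genomic DNA fragments at random during library preparation, so at
depth d the number of true overlaps of a genuine read is of order d
(every other read covering part of the same locus). Artifact reads —
pore noise, chemistry failures, reads with catastrophic error — share
no sequence with any other molecule in the library. We call a read
**non-sense** when it has at most `nonsense_max_partners` (default 2)
distinct overlapping partners among the accepted read-to-read
overlaps. The dataset-level noise estimate is the flagged fraction of
a uniform subsample, with a 95% Wilson score interval (chosen over the
normal approximation for its behaviour at counts near 0 and n).

The classifier is a pure function of the partner count and threshold;
with a fixed subsampling seed the whole pipeline is deterministic.

Two distinct notions of "coverage" are kept apart deliberately:
classification uses the *partner count*; plots and standardization use
the *mean depth* of the stacked overlap intervals along the read.

## Overlap engine

Reads are sketched with (w,k)-minimizers (defaults k = 15, w = 10,
common long-read overlap practice): in every window of w consecutive
k-mers the k-mer with the smallest 64-bit hash of its canonical
(strand-symmetric) 2-bit packing is selected; ties go to the leftmost;
k-mers containing N are never selected; a read with fewer than w
k-mers uses a single window. The hash is a fixed splitmix64 mixer —
deterministic across runs and platforms. Canonicality makes sketches
strand-invariant (a property-tested invariant).

All reads are indexed; hashes occurring in more distinct reads than
`max(100, 99.9th percentile of the per-hash read-count distribution)`
are masked. Masking is the standard control against repeat-induced
spurious overlaps, and it is also what makes un-trimmed adapters
visible downstream (see below).

Query minimizers matching the index are grouped per (target read,
relative strand) and chained: the longest subset with strictly
increasing query and target positions, positional gaps at most
`max_gap` (2,000), and diagonal drift between consecutive anchors at
most `max_diag_drift` (500 — an indel budget; long-read indel drift
over a 2 kb gap is ~tens of bases, so the band is generous while
keeping off-diagonal anchors, e.g. shared terminal artifact sequence,
out of genuine chains). Chaining is a simple O(n²) DP per group with a
fast path for already-monotone hit runs — contract equivalence with
production overlappers, not performance parity, is the goal.

A candidate overlap is accepted iff

1. it has ≥ `min_shared` (4) chained shared minimizers;
2. its **dovetail-projected span** is ≥ `min_span` (500 bases). The
   anchor chain starts and stops short of the true overlap boundary by
   the anchor sampling gap, so the raw anchor span systematically
   underestimates the overlap length (by ~k + two mean gaps, i.e.
   tens of bases even on error-free data). Extending each end along
   the diagonal by the smaller of the two reads' remaining flanks
   projects the chain to the point where one read ends; for a genuine
   dovetail or containment this equals the true overlap length, and
   the span filter is applied to it. Reported coordinates remain
   anchor-based (adapter detection depends on that).
3. it is *proper*: each flank reaches within `terminal_slack` (1,000)
   of a read end on the query or the target. Purely internal matches
   are repeat artifacts and are dropped.

At most one overlap is kept per (target, strand): largest shared-anchor
count, ties by span, then target id. Self-hits are always discarded.

Measured against an exhaustive shared-canonical-k-mer oracle on small
instances (50 reads of ~1.9 kb, five seeds pooled), the engine recovers
100% of oracle-confirmed true overlaps ≥ 500 bases at 5% total error
and ~87% at 10%. The 10% figure is a property of the sketch density,
not of the implementation: a 500-base overlap at 10% per-read error
retains on average ~20 intact k-mers, of which only ~18% are sampled
as minimizers — below the min_shared threshold — so near-threshold
overlaps are intrinsically hard at that error rate. The engine-level
acceptance checks therefore exercise the 5% regime.

## Per-read error estimation

For each accepted overlap of a sampled read, let m be the number of
chained shared minimizers and M the number of the query's minimizers
inside the overlap window; the survival fraction f = m/M (clamped to
(0, 1]) estimates the probability that a k-mer is error-free in *both*
reads. With independent per-base errors at symmetric per-read rate e,
f ≈ (1 − e)^{2k}, so each overlap contributes ê = 1 − f^{1/(2k)} and
the read's estimate is the median over its overlaps (robust to the
occasional mis-chained or repeat-contaminated overlap). A multiplicative
calibration constant can absorb residual minimizer-sampling bias; on
parameter-recovery runs at 5/10/15% substitution truth the raw
estimator returned 0.053/0.102/0.135, within the targeted ±0.03 band,
so the constant ships as 1.0. Two opposing small biases roughly cancel:
minimizer selection is imperfectly conserved between the two erroneous
copies (inflating ê), while conditioning on accepted overlaps
(m ≥ min_shared) selects luckier overlaps at high error (deflating ê).

Reads with no accepted overlap get no estimate (reported as missing) —
for random artifact reads there is simply no internal evidence to
measure error against.

## Adapter-like boundary detection

If every read carries the same un-trimmed terminal adapter, the
adapter's minimizer hashes occur in essentially all reads and are
masked by the high-frequency filter, so overlap anchors can only start
at or after the adapter/insert junction. For well-covered reads
(≥ 3 partners) the uncovered terminal length is then the adapter
length plus one-sided positive noise (the gap to the first shared
anchor), occasionally contaminated *below* by rare adapter-junction
k-mers that are selected as minimizers in too few reads to cross the
masking cutoff. The boundary estimator is therefore the median of the
modal 5-base histogram bin (± one bin) of the margin distribution: the
sharp pile-up at the adapter length dominates both diffuse noise
flanks. A simple median is biased upward by the mean anchor gap
(~+18 bases at default error), and a low quantile is sensitive to the
below-boundary contamination; both alternatives were measured and
rejected. The modal estimate recovers a 45-base adapter as 48 ± 0.5
bases across seeds.

A side is reported as 0 when the estimate does not exceed the sketch
noise floor w + k + 5 (= 30 bases at defaults — margins of that order
arise on adapter-free data from minimizer spacing alone), and as
undetermined (with a warning) when fewer than 50 reads contribute.

## Descriptive statistics

* **Lengths** — N50 by descending cumulative sum (always an observed
  read length); the median of an even-sized sample is the lower middle
  value, so it, too, is observed.
* **GC** — (G+C)/(A+C+G+T) per read, Ns excluded; histogram modes via
  peak detection (3-bin smoothed 1%-bin histogram, prominence
  ≥ max(5, 0.5% of reads), ≥ 0.05 separation). Two or more modes flag
  a mixed library.
* **Per-read QV** — arithmetic mean of the read's Phred values, i.e.
  the quality "as assigned by the sequencer"; the alternative (Phred of
  the mean error probability) is deliberately not used, since the
  point of this statistic is to echo the sequencer's own claim, which
  the error estimator then cross-examines. Absent without Phred input
  (FASTA, Sequel-style data).
* **Complexity** — mean Shannon entropy over 64-base windows of A/C/G/T
  frequencies, bits in [0, 2]; windows under 1.0 bit count as
  low-complexity. Entropy was chosen over DUST-style scores for its
  fixed scale and trivial interpretability; the threshold (two-symbol
  uniform composition) marks di-nucleotide-repeat-or-worse sequence.

Rank correlations reported by analysis helpers define the degenerate
case (constant input, < 3 pairs) as 0 — no variation, no evidence of
association.

## Synthetic data generator

The generator emulates exactly the features the estimators measure,
with ground truth for each:

* i.i.d. random genome at a target GC (default 0.45);
* reads: uniform start positions, log-normal lengths (default mean
  ~8 kb, σ_log = 0.5, minimum 500), both strands equiprobably,
  truncated at the genome end; number of reads = depth ×
  genome_length / mean_length (default depth 25x);
* per-base errors: substitution/insertion/deletion, default
  5%/2.5%/2.5% (10% total, a typical raw long-read error rate);
  optionally a per-read total-error range for QV-vs-error analyses;
* non-sense reads: with probability `nonsense_fraction` a read is
  replaced by i.i.d. uniform random sequence — the purest testable
  form of "overlaps nothing"; a `high_error` mode (genomic origin at
  35% error) covers the extreme-error variant; `short_fragment_mode`
  draws their lengths from a short (mean 1 kb) distribution to mimic
  failed-library signatures;
* adapters: a verbatim, error-free sequence attached to read starts
  and/or ends (reverse complement on the right, hairpin-style);
* contamination: short reads (mean ~4 kb) drawn from one window
  (default 50 kb) of a second, GC-divergent genome;
* qualities: each read's Phred values are the Phred equivalent of its
  true per-base error rate; non-sense reads get a fixed, misleadingly
  high QV of 10 (artifact reads with good sequencer quality and no
  signal).

What the generator does *not* model: platform error profiles
(homopolymer-length errors, chimeras, signal-level artifacts),
sequence-dependent error, real genome repeat structure. Passing tests
therefore demonstrate estimator correctness under the stated model,
not platform-calibrated accuracy on real data; on real libraries the
noise-fraction estimate in particular inherits whatever repeat masking
and proper-overlap filtering cannot fully absorb.

## Problem sizes and determinism

The test suite runs entirely on simulated data generated at test time.
Full-scale recovery checks use a 1 Mb genome at 25x (~3,100 reads);
engine-vs-oracle comparisons use 50 reads of ~1.9 kb where exhaustive
k-mer counting is feasible; remaining scenarios use 200–500 kb genomes
— sizes chosen so each estimator is exercised at a sample size where
its stated tolerance is statistically meaningful. Every stochastic
step takes an explicit seed (subsampling default 7), and rerunning
with the same inputs and seeds reproduces reports byte-identically
(timestamps excluded).

## Known limitations

* Sensitivity to near-threshold overlaps degrades above ~8% per-read
  error (sketch density, see above); partner counts remain far above
  the non-sense threshold at realistic depths, so noise-fraction
  estimates are unaffected, but the error estimator's overlap support
  thins at 15%+ error.
* The error estimator assumes errors are shared symmetrically between
  the two reads of an overlap; a library mixing very different
  per-read error rates will see individual estimates shrink toward the
  pairwise mean.
* Adapter detection requires the adapter to be long enough to clear
  the noise floor (w + k + 5 bases) and present on most reads.
* GC mode detection flags contamination only when the contaminant's
  GC composition diverges by more than the per-read GC spread
  (roughly ≥ 0.05 for multi-kb reads).
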