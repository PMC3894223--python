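# Methods

## Copy-number model and coordinate conventions

All genomic intervals are 0-based half-open internally; SEG files on disk are
1-based inclusive and BED files 0-based half-open, converted only at the I/O
boundary. Copy number is absolute (diploid = 2.0); a derived `seg.log2`
column (log2 of cn/2, cn floored at 1e-3) is written for conventional SEG
consumers and ignored on read. The chromosome universe is chr1–chr22 + chrX
by default and configurable everywhere; counting does not exclude sex
chromosomes unless the caller restricts the universe, since no exclusion rule
is part of the method definition.

## Independent CNAs and the burden statistic

A segment is *abnormal* when its copy number lies strictly outside the closed
normal interval [1.7, 2.3] — values exactly at a boundary are normal. Two
abnormal segments are *contiguous* when they are adjacent rows of the segment
table with zero genomic gap (`end == start`) and no intervening normal
segment. Contiguous runs whose copy numbers agree within `cn_tolerance`
(default 5e-3) merge into one event with marker-weighted mean copy number;
contiguous segments with unequal copy number remain separate events. The
per-tumor burden is the plain count of events.

Numerical choices:

* **Tolerance.** Estimated copy numbers are floats; "identical" is equality
  within 5e-3, below any plausible estimation granularity. Configurable.
* **Gaps.** Segments separated by an un-probed gap are never merged by
  default (`merge_across_gaps=False`); the conservative reading yields more,
  smaller events, consistent with treating every copy-number step as an
  independent event. Centromere/assembly-gap behaviour follows from the same
  rule.
* **Direction.** Gain iff the event's (weighted-mean) copy number exceeds
  2.3; loss iff below 1.7. Merged members always lie on one side, so the
  direction is well defined.

Event sizes are summarized in six left-closed bins with edges at 1 kb, 10 kb,
100 kb, 1 Mb and 10 Mb.

## Segmentation stand-in

The segmenter that produced the motivating data is proprietary; only its
operating constraints are public (minimum 20 genomic markers, p < 0.0005,
signal-to-noise 0.7, expected diploid range 1.7–2.3, 1 Mb GC window). The
package implements those constraints in a documented two-stage procedure per
chromosome:

1. **Candidate scan.** At every interior probe index, Welch's unequal-
   variance t-test compares the `min_markers` probes on the left with the
   `min_markers` on the right. Indices passing the acceptance rule are
   thinned greedily (largest |t| first, minimum separation `min_markers`),
   so every provisional segment spans at least `min_markers` probes.
2. **Bottom-up pruning.** The weakest surviving boundary whose two flanking
   segments do not differ — Welch p ≥ `p_threshold` *or* standardized mean
   difference < `signal_to_noise` — is deleted; repeat to a fixed point.

"Signal-to-noise 0.7" is interpreted as the standardized mean difference
|Δ| / pooled within-segment SD ≥ 0.7; the original parameter's formula is not
public, and this reading is stated prominently rather than guessed silently.
Segment boundaries snap to the midpoint between flanking probes
(deterministic and probe-spacing invariant); segments partition each
chromosome's probe extent exactly, segment copy number is the mean probe
value, and chromosomes with fewer than `min_markers` probes are emitted as a
single segment. Adequacy is defined by simulation: on planted events covering
≥ `min_markers` probes with amplitude ≥ 3× the probe noise SD, ≥ 95 % of
breakpoints are recovered within ±5 probes (the acceptance suite measures
~98–99 %). A plain best-single-split recursion was evaluated first and
recovered only ~26 % of breakpoints (single-split statistics dilute short
interior events), which motivated the windowed scan.

GC correction averages probe GC over a centered 1 Mb window, fits a
binned-median curve of copy number against windowed GC (up to 41 GC-quantile
bins, linearly interpolated), divides the curve out, and rescales so each
sample's genome-wide median copy number is exactly preserved. Constant GC
makes the fit impossible and the correction is the identity (logged). The
multiplicative removal slightly under-corrects probes far from cn = 2 when
the underlying bias is additive; residual |correlation| with GC is < 0.05
under the generator's default bias amplitude.

## Recurrence heuristic

Extreme CNA is copy number strictly outside [1.474, 3.025]. Fixed thresholds
are the default so region/gene semantics are reproducible without a cohort;
percentile mode recomputes them as the 10th/90th percentile (type-7 linear
interpolation) of all abnormal-segment copy numbers, pooled across samples
and unweighted by size or marker count (the weighting convention is not
derivable from the method description; the unweighted variant is implemented,
with the pooled segment table as input so alternatives are easy to add).

Region discovery is a sweep-line: breakpoints of all extreme events of one
direction partition the chromosome into atoms; per-atom support counts
*distinct samples* (a sample's overlapping events are unioned first), which
is what makes "N of 41 cases" coherent. A maximal run of atoms with support
≥ `min_flank` (default 2) containing at least one atom with support ≥
`min_core` (default 3) is one region; flank-only runs are discarded. Gains
and losses are analyzed independently. Gene-level frequency counts distinct
samples with ≥ 1 extreme event overlapping the gene span by ≥ 1 bp
(half-open); the kinase union (ERBB2/HER2, EGFR, MET, KRAS) uses set-union
semantics over samples.

## Survival stratification

Quartile cuts Q1/Q3 of the count vector use the Hyndman–Fan **type-6**
(SPSS weighted-average) empirical quantile; assignment is boundary-inclusive
(count ≤ Q1 → low, ≥ Q3 → high, otherwise intermediate). Type 6 is the rule
that reproduces the 10/21/10 split on a 41-sample vector of distinct counts;
the more common type-7 convention puts the cuts exactly on order statistics
and gives 11/19/11 under the same tie rule.

Overall-survival analyses exclude patients flagged as perioperative deaths
within 3 months of surgery; recurrence analyses use time to first recurrence
censored at the last evaluation and apply no such exclusion. Kaplan–Meier
curves and the k-group log-rank test come from lifelines; Cox models fit the
binary intermediate-vs-rest indicator (the primary contrast, since the
burden–hazard relation is non-monotonic), screen each candidate covariate
(age, nodal involvement, angioinvasion, tumor size, grade, lymph-node count)
by its own univariate Cox p < 0.2, and refit the indicator with the retained
covariates. Hazard ratios are exp(β) with Wald 95 % CIs; non-convergence is
reported and partial results withheld. Group–covariate association uses
chi-square (exact when any expected cell < 5: Fisher for 2×2, seeded
Monte-Carlo permutation of the chi-square statistic for larger tables —
SciPy provides no r×c exact test), Kruskal–Wallis across the three groups,
and pairwise Mann–Whitney against the low group.

## Synthetic cohort generator

The generator's defaults *are* the study conditions: 41 tumors; per-tumor
independent-CNA counts log-uniform on [11, 433] (median ≈ 82 and the right
order-of-magnitude spread; only range/median/IQR are treated as calibration
anchors since the full count distribution is unknown); event sizes from the
categorical mixture (0.016, 0.202, 0.351, 0.179, 0.179, 0.072) over the six
size bins, log-uniform within bin; gains:losses 1.7:1; gain copy numbers
uniform on [2.4, 8] and losses on [0.5, 1.6]; planted recurrent loci at the
prevalences of the default gene scenario (e.g. FHIT-type loss in 23/41,
ERBB2-type gain in 8/41), each carrier's event covering the locus plus
random flanks with a direction-appropriate extreme copy number. Probe copy
number is truth + `amplitude × (gc − mean gc)` + Gaussian noise
(SD 0.2 by default — formalin-fixed archival arrays are noisy; bias
amplitude 0.3 so the correction has a recoverable signal; no bias form is
prescribed by the method, so the linear-in-GC form is a modeling choice).

Placement is rejection sampling without overlap, largest events first, with
≥ 1 kb of diploid genome between events, so the ground-truth event count
equals the requested count exactly — the counting oracle behind the test
suite. Design choices worth flagging:

* **Genome size.** The default genome carries full-length hg19 chromosome
  sizes (~3.04 Gb). With the absolute size mixture and counts up to 433 the
  expected per-tumor event footprint reaches ~1–2 Gb, which simply cannot be
  placed without overlap in a few-hundred-Mb miniature; `toy_genome(scale)`
  provides scaled genomes for fast tests, whose callers also scale counts or
  restrict the size mixture.
* **Size tail.** The >10 Mb bin is truncated at 50 Mb by default. Real
  cohorts contain rare arm-scale events beyond that, but an untruncated
  log-uniform tail makes high-count genomes unplaceable; the truncation
  affects only the within-bin size distribution, not the bin fractions.
* **No nesting.** Planted events never overlap, so complex nested amplicons
  are out of the generator's scope (the caller can still hand the pipeline
  adjacent unequal-cn segments directly). Tumor purity, subclonality,
  allele-specific signal and chromothripsis are likewise not simulated.

Clinical outcomes are exponential: baseline death hazard 0.008/month with a
×3.7 multiplier for the intermediate group, recurrence hazard 0.004/month
with ×7.3, uniform administrative censoring on [24, 104] months, and two
perioperative deaths within 3 months. All covariates are drawn independently
of the burden group (frequencies matching the study population), so the
simulated cohort has no group–covariate association by construction.
Passing tests therefore demonstrate calibration and internal consistency of
the pipeline under these laws — they do not validate the biological claims
on real data, where noise is non-Gaussian, events nest, and covariates
confound.

## Problem sizes used by the automated checks

Oracle equivalence of the merge rule runs on 1,000 random small segment
tables; truth counting on 100 random generator configurations; sweep-line
vs. per-base counting on 500 random 10 kb toy genomes plus planted-locus
recovery on 20 simulated cohorts; segmentation recovery on ≥ 200 planted
events at noise SD ≤ amplitude/3; Cox calibration on 100 replicates of 300
subjects per arm (estimate within [3.0, 4.5] in ≥ 90 % of replicates); and
the default 41-tumor cohort for the generative laws. The acceptance script
uses one default cohort, a 30-replicate hazard-recovery study, and a
4-profile probe-level demonstration on a 0.05-scale genome.

## Known limitations

* The segmentation stand-in shares only its published operating constraints
  with the original proprietary algorithm; absolute counts from real arrays
  will differ with segmentation parameters, though relative differences
  between tumors should persist.
* Fixed extreme thresholds (1.474/3.025) are cohort-derived constants; for a
  new cohort, percentile mode should be used and the thresholds reported.
* The exact r×c test is Monte-Carlo, not the network algorithm; p-values
  carry simulation error of order (p(1−p)/5000)^1/2.
* The generator's count law, bias form, survival model and censoring law are
  modeling choices documented above, not estimated from data.
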