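# Methods

This note records the models, conventions and design choices behind each
stage of the package, including the points where the procedure was
genuinely open and a choice had to be made.

## Coordinates and input conventions

All coordinates are 0-based half-open (BED convention) in memory and on
disk; 1-based inputs are converted on read via a flag. Chromosome names
are compared literally ("chr17" ≠ "17"), with optional prefix
normalization on read — silent renaming hides data errors. Strand is
ignored everywhere except the TSS definition (start for `+`, end − 1 for
`-`), because only TSS positions enter the pipeline. Readers are strict:
malformed lines raise with the line number; rows are never silently
dropped, so record counts are conserved between disk and memory.

## SE clustering and candidate prioritization

Two SE calls belong to one cluster iff they are connected by a chain of
pairwise relations — overlap, or a gap of at most `max_gap` (default
500 bp, measured between half-open interval ends). On a line this
transitive closure is exactly what a sorted sweep computes; a dense
O(n²) closure oracle backs this equivalence in the tests and in a
1,000-instance simulation study.

Within-sample SE ranks, when not supplied, are assigned by descending
signal (1 = strongest), ties to the leftmost start. A cluster's median
rank is taken over its *member* samples only — a cluster absent from a
cell line has no rank there. When one sample contributes several calls
to a cluster, its strongest call represents it, so recurrence counts
distinct samples.

The top-N cut sorts by median rank with deterministic tie-breaking
(higher recurrence, then leftmost interval); the recurrence bound
(default ≥ 20 of 26 lines) is inclusive. The ranking-then-recurrence
order of operations, and the choice to rank *clusters* rather than
individual per-sample SEs, are design decisions; both knobs are exposed.

Gene annotation uses TSS-to-cluster distance ≤ 500 kb, inclusive, with
distance 0 inside the span. The active-TSS filter requires an H3K27ac
peak overlapping TSS ± 1 kb (the peak-at-TSS window is not standardized
anywhere; 1 kb is a promoter-scale default and is configurable) in every
cell line harboring the SE. For a gene annotated to several clusters,
"harboring" is read as the *union* of member samples across its clusters
(default); a per-cluster mode is available. A harboring sample with no
peak table at all is an error, never a silent fail.

Candidates are ranked by the raw log-rank p-value; BH-adjusted values
are reported alongside but do not drive the order, matching practice in
candidate screens where the list, not a significance claim, is the
output. Candidates lacking expression are retained with a missing
p-value and sort last.

## Survival

The median split sends values strictly above the median to the high
group, ties to low (deterministic; a constant vector cannot be split and
errors). The two-group log-rank statistic is the standard
(Σ(O − E))²/ΣV with hypergeometric variance, referred to χ²(1); curves
are product-limit estimates. Both are computed with lifelines; the test
suite checks the statistic against an explicit O − E/V hand computation
to 1e-10 and the curves against the empirical survival function in the
censoring-free case. Events precede censoring at tied times (standard
convention).

## Copy-number dosage

Focal gains: segment overlaps the locus by ≥ 1 bp, log2 ratio ≥ 0.3
(inclusive — the rule is stated as "≥"), size ≤ 5 Mb (inclusive — "a
maximal size of 5 Mb"). Arm gain: length-weighted mean log2 over the arm
region, gained iff strictly > 0.3 (the arm rule is stated as ">");
samples with no segment on the arm are "unknown" and excluded
downstream. The two inequalities are deliberately different because each
printed rule is followed literally.

The dosage ANOVA fits `expr ~ stage * gain` with type-II sums of squares
(robust to mild imbalance; in a balanced design identical to the
classical decomposition, which is the test oracle). Because the
biological claim is a gain effect *within high-stage disease*, the
headline quantity is the one-way F-test of gain in the high-stage
stratum; both the stratified and the two-way results are returned, since
the choice of SS type and the presence of an interaction term are open
questions in such analyses. Occupied cells need ≥ 2 samples; a
single-level factor errors, naming the factor.

## 4C interaction calling

The caller is deliberately simple and operates on binarized coverage
(covered ⇔ ≥ 1 read), which is robust to PCR jackpots in 4C libraries.
The statistic is a normal-approximate one-sample proportion test of the
small-window covered fraction against the co-centered large-window
background fraction (w = 100, W = 3000 fragments):

z = (p_w − p_W) / sqrt(p_W(1 − p_W)/n_w),

with n_w the actual, possibly edge-truncated, window size; z = 0 where
the background is degenerate (p_W ∈ {0, 1}). The centered-background
reading of "sliding windows" makes the test local, so broad coverage
gradients do not masquerade as interactions. An exact binomial tail is
the cross-check oracle in the tests. BH adjustment runs across all
tested windows of the track (no FDR procedure is canonical here; BH is
the field default), thresholds 1% cis / 0.5% trans, so trans calls on a
given z-vector are always a subset of cis calls. In cis mode, 200
fragments (2·w) around the viewpoint are masked: undercounting and
self-ligation artifacts dominate there. Overlapping significant windows
are merged into maximal runs for reporting. The caller is validated by
behavior, not against any external script: false-call rate ≤ 2% on 200
null tracks and ≥ 95% recovery of planted windows (p_hi = 0.5 over
p_bg = 0.05) across 100 tracks.

Smoothed tracks are a centered 21-fragment moving average of raw counts
(shrinking at the ends) scaled to reads per million of library size.
Domainogram row s, column i is the covered fraction of the centered
s-window at i; the w-row reproduces exactly the p_w used by the z-score.

## Drug synergy

Viability is percent of vehicle control; values above 100% are clamped
to 100% *after* normalization (negative viability indicates an upstream
bug and errors). EoB = observed inhibition − (i_a + i_b − i_a·i_b) with
margins taken from row/column 0 of the checkerboard; margins score
exactly 0 and EoB is always in [−1, 1]. For fixed-dose time courses, the
per-condition effect at a timepoint is 1 − confluency/control, floored
at 0 — confluency above the control is growth stimulation, which the
inhibition scale cannot represent, so it is treated as no inhibition.

## Signature scoring and correlation

Per sample, all G genes are ranked (average ranks for ties), ranks
rescaled to (r − 1)/(G − 1) ∈ [0, 1]; the score is mean(rescaled up) −
mean(rescaled down), or mean(rescaled up) − 0.5 for an up-only
signature. This rescaled-mean-rank form was chosen for monotone
invariance and exact zero-centering (the all-genes signature scores 0);
published rank-scoring schemes differ in their size normalization, so no
cross-package numeric agreement is claimed, and the property tests do
not depend on the exact scaling. Missing signature genes are dropped
with a warning; an empty intersection errors.

`correlate` operationalizes "Pearson if the homoscedasticity assumption
is met, Spearman otherwise" as a Breusch–Pagan test on the y ~ x
residuals at α = 0.05 — no specific test is canonical for this rule, and
the choice only switches between two correlation measures that agree in
sign.

## Synthetic data

The generators are pure functions of spec + seed (one
`numpy.random.default_rng` stream each, no global state) and each
returns a truth record sufficient to score recovery.

* **Landscape** (defaults): 26 cell lines, one driver cluster present in
  24 lines at within-sample rank ≤ 3, 20 decoy clusters with uniform
  ranks and recurrences from 3 to 26, spaced 1.5 Mb apart on 17q (far
  beyond the 500 bp merge gap, so the planted cluster count is exact);
  signal scores are constructed so that descending-signal ranking
  reproduces the planted ranks. A TF gene sits 30 kb from each cluster
  (with a non-TF decoy gene nearby) and every line carries a TSS peak at
  every gene, so the active-TSS filter is exercised but not the
  bottleneck.
* **Cohort** (defaults): 200 tumors; driver expression = baseline 8 +
  1.0·gain + N(0, 1) with half the tumors arm-gained (arm segment log2
  0.5 vs 0.0, sd 0.05); survival exponential with hazard
  (1/1500 d⁻¹)·HR^z, HR = 2.5 per SD of driver expression, independent
  exponential censoring at ~30%. Exponential times are the simplest
  model consistent with a pipeline that makes no distributional
  assumption.
* **4C**: Bernoulli coverage p_bg = 0.05 over 5,000 fragments of
  200–2,000 bp, planted windows at p_hi; covered fragments carry
  1 + Poisson(2) reads.
* **Checkerboard**: three-fold dilution series (9 doses plus vehicle,
  top doses 33.3 µM and 0.333 µM, mirroring a BET/CDK7 inhibitor pair),
  Hill single agents, combinations under exact Bliss independence plus a
  planted EoB offset; noise is Gaussian on the viability scale, clipped
  at 0 and clamped at 100.

What the generators do *not* emulate: read-level noise, SE-calling
uncertainty, copy-number breakpoint structure, correlated gene-gene
expression, cohort substructure, or plate effects. Passing tests
therefore demonstrate that the *algorithms* behave as specified under
their stated statistical assumptions — not that the biological findings
of any particular study would replicate on raw data.

## Numerical choices and degenerate inputs

Cluster and report orderings use stable sorts with explicit tie-break
keys, so outputs are byte-identical across runs. The z-score guard sets
z = 0 at degenerate background; log-rank requires ≥ 1 event and two
non-empty groups; median split requires ≥ 4 samples and a non-constant
vector; ANOVA requires two levels per factor and ≥ 2 samples per
occupied cell. All validation failures raise typed errors
(`ValidationError`, `ParseError`, `SchemaError`) rather than returning
sentinels.

## Study sizes

The simulation studies use 1,000 random instances (clustering oracle),
200 null tracks and 100 planted tracks of 5,000 fragments (4C), 50
landscape+cohort pairs of 26 lines / 200 tumors (driver recovery),
2,000 replicates each for the log-rank and ANOVA null calibrations, and
100 checkerboards (Bliss). These sizes give the recovery and calibration
estimates standard errors of a few percent, which is sufficient to
separate the designed behavior from failure modes.

## Known limitations

The 4C z-score is a documented reconstruction of a statistic whose
original implementation is not public in detail; it is validated by its
FDR control and sensitivity, not by script-level agreement. The
proportion test ignores the covariance between p_w and p_W (the small
window is part of the background window), which makes it slightly
conservative. The prioritization consumes SE calls; it does not call SEs
from signal. The curated 17q23.2 gene table carries approximate hg19
coordinates adequate for inside/outside-the-amplicon decisions only.
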