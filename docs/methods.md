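# Methods

## Data model

The unit of observation is the amplicon: a PCR-amplified interval
(BED-defined, 0-based half-open) with a gene symbol, GC fraction and
length. Reads are single-end; each primary mapped read is assigned to the
amplicon with maximal alignment overlap (ties: smaller start, then
smaller id), reads overlapping nothing are dropped from counting, and
duplicates are kept — at typical amplicon depth ~95% of reads are PCR
duplicates and removing them would erase the dosage signal. Amplicons
that reciprocally overlap by more than 75% of both lengths are merged
before counting (transitively, to a fixed point), because reads in the
shared region cannot be attributed; merged amplicons carry comma-joined
gene labels and are attributed to the first label for gene bookkeeping.

## Normalization

Biases are treated as multiplicative, so all fits operate on log counts.

**Library size.** NRC_Lib = RRC / (N/R). N defaults to the column sum;
when counting from alignments, N is the number of primary mapped reads,
so unassignable reads depress the mean NRC below 1 (visible in QC).

**GC and length.** Two sequential LOESS (degree 2) detrending steps, GC
first. The smoother is a hand-written local quadratic with tricube
weights: no installed Python package provides degree-2 local regression,
and degree 2 matters because the GC trend is unimodal. The fit uses a
span of 0.3 by default (configurable `loess_span`) — wide enough to be
smooth over hundreds to thousands of amplicons, narrow enough to track
the GC curve — evaluated on ≤200 support points with linear
interpolation; queries beyond the fitted support are clamped to the
boundary value rather than extrapolated, since amplicons with extreme GC
or length are exactly where polynomial extrapolation misbehaves. The
correction is exp(log v − f + mean f), which preserves the geometric mean
of the support. Amplicons with zero raw count are masked per sample
(assay failure, not deep deletion); amplicons whose control-cohort mean
NRC_Lib falls below 0.01 are excluded panel-wide. Detrending requires at
least 50 usable amplicons, otherwise it is skipped with a warning.

**Gender.** M_i = mean(NRC_Len on chrX) / mean(NRC_Lib) per control
(denominator ≈ 1 by construction; computed over unmasked amplicons). A 1-
vs 2-component Gaussian mixture on {M_i} is selected by BIC; with two
components the lower-mean cluster is male, with one component all
controls are male iff the common M < 0.9. The mixture uses
reg_covar = 1e-3: with only a handful of controls, an unregularized
2-component fit can collapse onto near-duplicate M values and win BIC
spuriously. Male chrX counts are doubled exactly once — the corrected
counts are wrapped in a flagged container and re-correction raises.

## Baseline and noise model

PCA is computed on the amplicons × controls matrix of log NRC_Len
(covariance PCA; controls are same-technology replicates, so per-control
variance scaling would distort the shared profile). By default
k = min(3, n−1) components are kept. PC1's sign is fixed to correlate
positively with the cross-control mean profile, remaining PCs by their
largest-magnitude loading, so baselines are reproducible under control
relabeling. Each sample is regressed (OLS, intercept + k PC scores) on
the baseline; residuals form the log-ratio profile. The intercept absorbs
global scaling, so profiles are defined only up to an offset — absolute
anchoring is deferred to the zero level.

σ_i = f(PC1) is fitted by LOESS (degree 2) to *squared* residuals pooled
over controls, each control first rescaled to overall residual variance
1; the square root of the floored fit (floor 1e-3) is σ_i. Squared
residuals rather than absolute: unbiased for normal noise. Because
squared residuals are chi-square-heavy-tailed, this fit uses a wider span
(0.5) and trims its evaluation grid to the inner 96% of the PC1 range,
clamping beyond — boundary local-quadratic fits on such noisy responses
otherwise whipsaw. σ_i is relative; the absolute per-sample scale is
σ_sample below.

A panel hash is embedded in serialized baselines; tumors are refused
against a baseline from a different panel.

## Segmentation and calibration

Weighted CBS, per chromosome: the statistic is
Z = (m₁ − m₂) / √(1/W₁ + 1/W₂) over circular arcs, where m, W are the
weighted mean and total weight (w_i = 1/σ_i²) of the arc and its
complement. The maximizing arc is accepted if it survives a permutation
test ((x, w) pairs permuted jointly; 1,000 permutations, α = 0.01, early
stopping once the P-value can no longer reach α), then the piece is split
and recursion continues. Minimum segment width is 2, enforced in the arc
candidate set; chromosomes with < 4 usable amplicons stay whole. The
statistic depends only on mean differences, so segmentation is
shift-equivariant.

**Zero level.** Each segment contributes 50 seeded draws from
Normal(wmean, sem) — Parzen-style resampling that widens unreliable
segments — and a 1-D equal-variance Gaussian mixture (1..9 components,
BIC) is fitted to the pooled draws. The neutral component is the one with
the highest peak density weight/(σ√2π), ties resolved toward the mean
closest to 0; segments whose wmean is assigned to it are copy-neutral.
Component numbering from the mixture fit is arbitrary across seeds; the
neutral *partition* and the zero level are the stable quantities. All log
ratios are centered on the zero level;
σ_sample = sd(centered log ratio / σ_i) over neutral amplicons, and
σ_i^sample = σ_sample · σ_i. Non-neutral segments get status from the
sign of their centered weighted mean.

**Gene-aware readjustment.** For every gene split across segments, each
adjoining segment mean μ_s is tested against all the gene's log ratios
(one-sample t-test); if the best P > 0.01 the whole gene moves to that
segment. A consequence worth knowing: for a *balanced* intragenic break
the t statistic is bounded by √n, so genes with fewer than ~12 amplicons
can never retain a balanced true intragenic break at α = 0.01 — genes
with more amplicons are adjudicated more reliably, and panels with ≥ 8
amplicons per gene are the intended regime.

## Statistical validation

On X_i = centered log ratio / σ_i^sample (standard normal for neutral
amplicons if the calibration holds), each non-neutral segment must pass:

- fixed variance test, P = 2(1 − Φ(|X̄|√n)) — equivalently |X̄| is
  half-normal with the variance treated as known;
- one-sample t-test (variance estimated from the segment; undefined for
  n < 2 or zero spread, which conservatively fails the filter);
- both at P < 0.01; and
- purity band: the segment's weighted geometric mean of centered linear
  ratios (weights 1/σ_i², non-positive values excluded) must lie outside
  (0.875, 1.125). The band is applied after zero-level centering, where
  it is symmetric around 1. Via ExpectedNRC = (1−c) + c(1 ± l/P) this
  encodes the minimum detectable cell fraction c = 0.125·P for one-copy
  events: 25% (diploid), 37.5% (triploid), 50% (tetraploid).

Filtered candidates are demoted to neutral with a reason flag rather than
dropped, so gene tables always cover the panel. Copy numbers are
round(ploidy × ratio) under a diploid, uncontaminated-sample assumption
and are reported alongside the continuous ratio, never instead of it.
Per-amplicon outlier P-values under Normal(wm_seg, σ_i^sample) are
BH-adjusted across the sample (outlier at q < 0.05) but single-amplicon
events are never promoted to CNA calls.

## Synthetic data

The generator writes count-level cohorts (no read synthesis) with the
noise structure the pipeline is built for: per-amplicon lognormal PCR
efficiency (log-sd 0.5 — the dominant spread, shared across samples and
hence learnable by the PCA baseline), unimodal GC bias exp(−k(gc−0.5)²)
with k = 4, decreasing length bias exp(−k(len−70)/70) with k = 1 over
70–140 bp amplicons, ±20% per-sample jitter on both bias strengths,
independent per-amplicon lognormal sample noise (log-sd 0.1), Poisson
counts at mean depth 1,000, halved chrX dosage in males, and planted CNAs
scaling rates by ExpectedNRC. Default cohorts are 40 genes × 8 amplicons
and 15 controls; the panel spans 10 chromosomes so segmentation operates
per chromosome.

What the generator does *not* emulate: mappability and replication-timing
effects, correlated (wave) noise along the genome, overdispersion beyond
the lognormal × Poisson mixture, subclonal heterogeneity beyond a single
cell fraction per event, FFPE degradation artifacts, and B-allele
frequencies (which the method deliberately does not use). Passing tests
therefore demonstrate correctness of the algorithms under the stated
noise model, not performance on any particular clinical panel.

## Problem sizes and numerical choices

Test and reproduction runs use cohorts of 15 controls with panels of
320–2,000 amplicons and depth 1,000, sizes representative of real
targeted panels while keeping simulations quick. The permutation count
(1,000) and CBS α (0.01) follow the filter threshold; resampling draws
per segment (50) balance density resolution against mixture-fit cost.
All randomness flows from explicit integer seeds (numpy Generator);
reruns with the same config and seed are bit-identical. Degenerate
inputs: empty libraries, single-control baselines, rank-deficient
regression designs, segments without neutral amplicons, and constant
covariates all raise or warn explicitly rather than propagating NaNs.

## Known limitations

Calls are relative to the zero level — global ploidy shifts on small
panels are invisible. Purity and ploidy are not estimated from the data
(the purity band is a detection limit, not an estimator). One-amplicon
events are reported only as outliers. Genes whose amplicons all sit at
extreme GC or length are corrected by boundary-clamped fits and may be
under-corrected.
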