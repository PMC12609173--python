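# Methods

## Model and assumptions

### Pseudo-time ordering

Cross-sectional subjects are ordered by ascending WMH volume (ties
broken by subject id) and the ordered, covariate-residualized
grey-matter values are treated as a time series. The core assumption is
that lesion burden is a monotone proxy for disease stage, so
"earlier in the ordering" stands in for "earlier in progression". This
is an approximation — subjects are not their own past — and all causal
language downstream inherits it.

### Signed-path-coefficient Granger causality

For standardized series x (seed) and y (target) the lag-1 model

    y_t = α + ρ·y_{t−1} + β·x_{t−1} + ε_t

is fit by least squares; β is the GC value. Standardizing both series
first makes β scale-free, which is what makes a fixed |GC| > 0.20
retention threshold meaningful. The model order is fixed at 1: the
pseudo-time axis has no physical lag scale, so higher orders would fit
ordering noise. (`signed_gc_pair` accepts higher orders and then
returns the summed lagged-x coefficients, but nothing in the default
pipeline uses them.) Voxel-wise maps are computed in both directions
(seed→voxel, voxel→seed) with a vectorized closed-form solve of the
3-parameter normal equations; voxels with constant or collinear series
are left undefined (NaN).

The GC map is z-scored over defined in-mask voxels (sample sd, ddof 1).
Voxels pass when |z| > 1.96 **and** |GC| > 0.20; both criteria are
two-sided so compensatory (negative) influences are detectable.

### Cluster-level inference

Supra-threshold voxels are clustered at 26-connectivity and filtered by
a minimum extent. Cluster p-values are nonparametric: the maximum
supra-threshold cluster mass (sum of |statistic|) is recomputed under
permutations of the exchangeable unit — group labels for the VBM
contrast, the pseudo-time ordering for CaSCN — and each observed
cluster's mass is referred to that null; Benjamini–Hochberg FDR is then
applied across clusters. Random-field parametric cluster inference is
deliberately out of scope.

The per-voxel GLM t uses the Frisch–Waugh–Lovell identity (residualize
data and indicator against the nuisance design, then simple-regression
t with df = n − p − 1), which is algebraically exact and lets every
permutation reuse the residualized data.

### Severity staging

Stage thresholds are the breakpoints of a continuous 4-segment
piecewise-linear approximation (exhaustive breakpoint search on a
quantile grid, least squares on a dense evaluation grid) to a
loess-smoothed curve of global GMV on WMH volume. The smoother is a
tricube-weighted *local quadratic*, written in-house because available
library smoothers are local-linear. How the original staging procedure
derived thresholds from local polynomial regression is not specified
anywhere; this operationalization is explicit, deterministic and
oracle-testable (planted changepoints are recovered). Stage intervals
are right-closed: stage I = [0, t1], II = (t1, t2], III = (t2, t3],
IV = (t3, ∞).

### ROI graph and modularity

Edges are retained when |GC| > 0.20; signs are kept on the edge list
for reporting. Degrees and modularity use |GC| weights because the
directed-modularity null model requires non-negative weights. The
partition maximizes the directed weighted (Leicht–Newman) modularity

    Q = (1/m) Σ_ij [A_ij − s_i^out s_j^in / m] δ(c_i, c_j).

Graphs with ≤ 10 nodes are solved exactly by enumerating set
partitions (Bell(10) ≈ 1.2e5); larger graphs use greedy agglomeration
followed by single-node move refinement, deterministic given the seed.
Hub roles come from the binary out−in degree: positive = causal
source, negative = causal target, zero = balanced.

### Functional decoding

A generic enrichment operation: per behavioural domain with in-module
activation count k, module total n and database base rate p, the
one-sided binomial tail P(X ≥ k | n, p) is computed and BH-corrected.
The activation database itself is user-supplied; the package ships no
database content.

### Mediation

With standardized X (WMH), M (global GMV), Y (score), the two
regressions M ~ X + C and Y ~ X + M + C give a, (c′, b); indirect =
a·b, total = c′ + a·b — an identity that holds at machine precision
whenever both equations share the covariate set C (age, sex, education,
TIV by default). Least squares equals maximum likelihood for this
saturated recursive system. Confidence intervals are bias-corrected
(not accelerated) percentile bootstrap over case resamples; TMT-A
enters as 1/TMT-A so higher = better for both outcomes. When direct
and indirect effects have opposite signs their percent shares of the
total are reported unnormalized with a warning.

## Synthetic-cohort generator

The generator emulates the study conditions the pipeline is designed
for; its defaults are the package's fixed study conditions, not tuning
knobs.

* **WMH volumes**: lognormal with location ln 5.24 and scale
  (ln 11.68 − ln 2.64)/(2·z₀.₇₅) ≈ 1.102, i.e. quantile-matched to the
  published median and quartiles. Draws are stratified
  (Latin-hypercube) inversions: one uniform per probability stratum in
  random order. Each draw is marginally lognormal, but sample quantiles
  deviate at O(1/n) instead of O(1/√n), so the calibration (median
  within ±0.5 mL) holds for every seed rather than on average.
* **Global GMV**: constructed with an *exact* in-sample correlation of
  −0.954 with WMH volume (Gram–Schmidt mixture), on the published
  mean/sd scale (548.92 ± 25.81 mL). The correlation is the planted
  mediation path a.
* **Fazekas grades**: volume cuts at 5 and 11.5 mL, reproducing the
  published grade proportions (≈ 88:52:45).
* **Images**: 24×24×24 grid, 6 mm voxels, homogeneous template density
  0.6. The source region (radius-2 sphere) loses
  0.06·ln(1 + WMH) density units; each target applies its parent's
  atrophy `lag` pseudo-time ranks earlier times a path weight
  (negative weights add density — compensation). Independent Gaussian
  voxel noise (sd 0.05) and isotropic smoothing (FWHM 2 voxels) are
  applied. Controls receive template + noise only; an optional age
  slope exists but defaults to 0 because the emulated cohort showed
  only weak age effects.
* **Planted network**: source → A1 → A2 chain plus a compensatory
  target (module 0), and a B1 → B2 → B3 chain reached from the source
  only through a weak (0.3) link (module 1) — a hub driving a loosely
  coupled second subnetwork. The ground-truth schema allows any target
  to name a parent region; propagation composes weights
  multiplicatively and lags additively, so the construction identity
  (target series = weight × parent series shifted by lag) holds
  exactly at every level.
* **Cognition**: standardized score = c′·z(WMH) + b·z(GMV) + ε with
  defaults chosen to reproduce the published 39%/61% direct/indirect
  split given a = −0.954; the score is mapped in-sample onto the
  published DST scale (50.63 ± 18.28), and 1/TMT-A analogously via the
  delta-method sd. Residual sd is derived so the standardized score has
  unit variance; it can be overridden (e.g. set to 0 for construction
  identities).

### What the generator does not emulate

Realistic cortical anatomy and folding, registration error, scanner
artifacts, lesion segmentation noise, spatially varying templates, and
age/vascular comorbidity structure. Passing planted-truth tests shows
the estimators recover the *model* they assume under realistic noise —
not that real lesion-driven atrophy follows that model.

## Numerical choices

* Pooled-variance (Student) two-sample t and Pearson chi-square
  without continuity correction — both validated against the published
  cohort-table statistics (3.903, 0.477 exact at 3 dp; the GMV t
  reproduces to 8.201 vs the printed 8.200, the residual being
  rounding of the printed 2-dp inputs).
* Cluster-forming threshold for the GLM contrast: two-sided voxel
  p = 0.001 (the original forming threshold is unstated; this is the
  field's common default and is config-exposed). Connectivity is
  26-neighbour.
* `min_cluster_voxels` defaults to 200 (full-resolution convention);
  the desk-scale preset uses 10 because planted radius-2 regions span
  ~33 voxels on the 24³ grid, where a 200-voxel extent criterion would
  discard every true effect.
* Permutation p-values use the add-one estimator (1 + #exceedances) /
  (n_perm + 1); defaults: 200 permutations, minimum 100.
* z-scoring uses the sample sd (ddof 1) throughout; a two-voxel map
  (a, b) yields z = (∓1, ±1)/√2.
* Ties in the pseudo-time ordering break lexicographically by subject
  id; cluster labeling is invariant to subject order.
* Bias-corrected bootstrap proportions are clipped to
  [1/(B+1), B/(B+1)] before the normal quantile, so a resample
  distribution entirely on one side of the estimate stays finite.
* Seeds: every stochastic routine takes an explicit integer seed;
  `simulate_study` derives per-stage sub-seeds (< 2³¹) from one master
  seed via `SeedSequence`.

## Problem sizes used in the shipped analyses

The default study is 185 patients / 40 controls on a 24³ grid — the
published cohort size at desk scale. The validation suite runs 100
null simulations (with 200 permutations each) for false-positive
control, 50 replicate studies for planted-truth recovery, and 200
simulated datasets (1000 bootstrap resamples each) for mediation CI
calibration; the full pipeline demonstration uses 100 permutations and
1000 resamples. The mediation CLI default remains 5000 resamples.

## Known limitations

* Pseudo-time GC on smooth monotone severity profiles is strongly
  collinear across regions: the ROI graph recovers planted hubs and
  module structure reliably, but individual spurious edges between
  co-driven regions do occur (they are what the modularity step
  absorbs). Edge-level interpretation should lean on the seed-based
  maps, not single ROI-pair coefficients.
* GC magnitudes depend on the standardized-β convention used here;
  published CaSCN tables produced by other toolboxes report values on
  other scales (magnitudes > 1), so only signs and rankings — not raw
  magnitudes — are comparable across implementations.
* Permutation cluster inference assumes exchangeability of the
  permuted unit under the null; for CaSCN that is the ordering, so the
  null preserved is "no temporal structure", not "no spatial
  structure".
* The bias-corrected bootstrap can be mildly anticonservative for
  products of coefficients at small n; the shipped calibration checks
  cover n ≥ 200.
* Staging thresholds are data-dependent; the published values
  (3.21, 7.78, 14.96 mL) are not reproduction targets.
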