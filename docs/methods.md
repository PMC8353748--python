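# Methods

`evsig` implements a pipeline for classifying subjects from plasma
extracellular-vesicle (EV) data: nanoparticle-tracking-analysis (NTA) size
distributions compressed to radial-basis-function (RBF) features, optionally
combined with EV protein-cargo measurements, fed to Random-Forest classifiers
trained under leakage-safe oversampling and evaluated with precision–recall
curves.  This note records the models, the defaults and the choices made
where the design was genuinely open.

## Size-distribution summaries (`evsig.nta`)

An NTA export is a binned curve: particle concentration (particles/mL) per
diameter bin on 0–400 nm.  Summaries:

- **Normalization** rescales a curve to unit trapezoidal area so that curves
  are comparable as densities; the raw area (the total particle
  concentration) is retained as separate metadata.  Normalization to unit
  area rather than unit maximum was a free choice: unit area makes the
  sub/supra-cutoff split a probability and keeps concentration available as
  an independent feature.
- **Mean** is the concentration-weighted mean diameter; **mode** is the bin
  center of the largest value, ties resolved to the smallest diameter (a
  determinism choice).
- **D10/D50/D90** are quantiles of the binned distribution.  Bin masses are
  trapezoid weights times bin values; quantiles use the midpoint
  weighted-percentile convention restricted to bins with positive mass.
  This convention was chosen over inverting the trapezoidal cumulative
  because it treats a single-bin spike as a point mass (all D-values collapse
  onto the bin) while converging to the continuous quantiles on fine grids
  (verified against a Monte-Carlo oracle with 10^6 draws).
- **Area split**: the curve area below/above a cutoff (130 nm by default,
  configurable; `derive_cutoff` recomputes it as the cohort median D50),
  with the cutoff ordinate linearly interpolated so the two parts always sum
  to the full integral.  Areas are computed by direct trapezoidal
  integration of the data rather than planimetry of plotted figures — exact
  and plot-independent.

Degenerate inputs: all-zero curves are rejected for normalization and
summarization; a cutoff outside the curve support is an error.

## RBF compression (`evsig.rbf`)

A normalized curve is approximated by
`f(x) ≈ b + Σ_j c_j exp(−(x−t_j)²/(2 w_j²))` with `m = 30` Gaussian kernels
by default; the coefficient vector `c` is the sample's feature vector.
Open choices and how they were fixed:

- **Kernel**: Gaussian, the standard RBF choice.
- **Centers**: two modes.  Greedy forward (orthogonal-least-squares style)
  selection from the curve's own grid points adapts the basis to a single
  curve; a uniform grid over the support makes the basis identical for every
  sample.  The grid mode is the default for cohort feature extraction
  because coefficients are only comparable across samples when the centers
  are shared; per-sample adaptive centers would scramble feature positions.
- **Widths**: per-center width = `c ×` distance to the nearest other center
  (`c = 1` by default) — scale-adaptive and deterministic.
- **Solve**: ridge-regularized least squares with penalty 1e-8 on the
  kernel coefficients (bias unpenalized), for numerical stability with
  near-collinear kernels; plain least squares is recovered as the penalty
  goes to 0, and the coefficients agree with the penalized normal equations
  to 1e-8.

With 30 shared-grid centers the median relative L2 reconstruction error on
default synthetic cohorts is ≈ 4 %, under the 5 % quality threshold the
package tests enforce.  Everything is deterministic given the inputs.

## MWMOTE oversampling (`evsig.mwmote`)

Majority-weighted minority oversampling generates synthetic minority samples
for imbalanced training sets.  Parameters default to the algorithm's
published reference settings (`k1 = 5`, `k2 = 3`, `k3 = ⌈|minority|/2⌉`,
closeness threshold 5, closeness cap 2, clustering multiplier 3).  Distances
are Euclidean on z-standardized features (RBF coefficients and biomarker
units are incommensurable); k-NN ties break to the lowest row index for
determinism.  Filtered minority points are grouped by average-linkage
clustering with threshold = 3 × the mean nearest-neighbor distance; each
synthetic point is `x + α(y − x)` with `x` drawn by the selection weights,
`y` uniform in `x`'s cluster and `α ~ U(0,1)`, so every synthetic sample is
a convex combination of two original minority samples.  Parent indices are
recorded on every synthetic row; the pipeline's leakage guard is built on
this provenance.

## Classification frameworks (`evsig.pipeline`)

Binary comparisons only (ALS vs HC / MD / SBMA; fast vs slow progressors).
Both frameworks: stratified 25 % holdout (the independent test cohort; the
fraction is configurable), per-feature mean imputation fit on training rows
only, stratified 5-fold cross-validated selection of Random-Forest
hyperparameters by mean CV PR-AUC (default grid: 200 trees, depth ∈
{unlimited, 5}, √p features per split — the classifier family is fixed but
the paper-style analysis names no grid, so this is a configuration default),
refit on the full training set, evaluation on the untouched test set.

The advanced framework additionally balances the training data with MWMOTE —
re-run *inside every CV fold* on that fold's training part only.  The
leakage contract is enforced, not advised: synthetic rows in any
validation/test partition, or synthetic parents inside an evaluation
partition, raise `LeakageError`.  The package's tests include a
demonstration of why: oversampling a signal-free cohort before splitting
inflates the measured PR-AUC by ≈ 0.5 over the correct protocol.

PR curves are computed at every distinct score threshold with ties grouped;
the AUC is trapezoidal over recall, anchored at recall 0 with the precision
of the top score group (an average-precision variant is deliberately not the
default; the integration rule is recorded with the result).  The null
baseline of PR-AUC is the positive-class prevalence; note the trapezoidal
estimator has a positive finite-sample bias of order `1/n_pos`, which is why
the null-sanity check runs at a test-set size (100) where the bias is well
inside its Monte-Carlo band.

## Synthetic cohorts (`evsig.cohort`)

The generator emulates the statistical structure of plasma-EV cohorts in
motor-neuron-disease studies; it does not model instrument physics (camera
level, track counting) or TRPS/zeta measurements.

One sample's curve is a lognormal mixture truncated and renormalized to
[0, 400] nm (NTA curves are right-skewed; two modes reproduce bimodal
healthy-control curves), scaled by a lognormal total concentration, sampled
at uniform bin centers (400 bins by default).  Sample-to-sample biological
variability: mode medians jittered lognormally (log-sd 0.08), mode weights
redrawn from a Dirichlet (concentration 60 × weights), concentration CV
0.35.  Bin-to-bin measurement noise is multiplicative lognormal with log-sd
0.04, the level appropriate for an export averaged over ~5 video captures
(single-video traces are far noisier, but the analysis only ever sees the
average); values are clamped nonnegative.

Default class profiles are calibrated to reported *orderings*, not absolute
values (which are free parameters): MD the largest mean diameter and SBMA
the smallest; ALS shifted toward small diameters with a larger sub-130-nm
fraction than HC; HSP90 ≈ 52 % lower in ALS than HC; within ALS, slow
progressors ≈ 1.3 × the particle concentration and ≈ 1.5 × the sub-130-nm
count of fast progressors, and PPIA ≈ 32 % lower in fast progressors.
Biomarker CV is 0.30.  Clinical tables draw a progression rate (lognormal,
stratum-specific median), a disease duration (lognormal, median 14 months)
and back out the ALSFRS-R score, so the pooled ALS rate distribution
straddles the 0.96 points/month cutoff.

What passing tests therefore show: the pipeline recovers class structure of
the stated kind and strength from curves with realistic noise and
imbalance.  What they do not show: performance on real NTA data, whose
inter-subject variability, batch effects, operator differences and
instrument artifacts the generator does not emulate.  With these defaults
the ALS-vs-control comparisons reach test PR-AUC ≈ 0.95–1.0 at the reference
class sizes (106/36/28/32); the fast-vs-slow comparison, whose generative
separation is anchored only to the qualitative effect directions above,
reaches ≈ 0.7 — the progression signal is deliberately subtle, and area
normalization removes the concentration difference from the curve features,
leaving shape and PPIA.

## Clinical and LFQ metrics (`evsig.metrics`)

- ΔALSFRS-R = (48 − score)/months; strata are defined by strict
  inequalities, so a rate exactly at 0.96 is flagged `indeterminate` rather
  than silently assigned.
- Censored measurements are replaced by `L/√2` (L the detection limit);
  idempotent.
- Purity index = particles per µg protein divided by a configurable
  reporting scale (default 1e8); published purity plots use
  instrument-dependent units, so the scale is a parameter rather than a
  constant.
- LFQ fold changes are ratios of group mean intensities, reported to two
  decimals; a protein undetected in the denominator group yields an explicit
  "ND" object, never infinity.
- The apolipoprotein-reduction index is `100 × (1 − ΣB/ΣA)` over an
  accession set with undetected entries counted as zero; both the exact
  value and its integer part are reported because sums over
  two-significant-figure table cells carry rounding.

## Problem sizes and determinism

All randomness flows through integer seeds (NumPy `SeedSequence`); identical
inputs and seeds reproduce cohorts bitwise and framework runs exactly.  The
shipped test suite and the acceptance script use: 100 curves for RBF
quality, ≤ 30-point planar instances for the MWMOTE brute-force oracles, a
400-sample null cohort with 50 shuffle replicates for the null-sanity check,
and 3–10 simulated cohorts at the reference class sizes for classification —
sizes chosen so each check is statistically meaningful while the whole suite
runs on a single CPU in minutes.

## Known limitations

- Binary comparisons only; no multi-class, survival or continuous-outcome
  models.
- The generator's class profiles are calibrated to qualitative orderings;
  absolute PR-AUCs on synthetic cohorts are properties of those choices, not
  estimates of clinical performance.
- MWMOTE is the only oversampler; plain SMOTE/ADASYN are out of scope.
- Curve ingestion expects already-binned distributions; raw NTA video/track
  processing is out of scope.
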