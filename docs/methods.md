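# Methods

`seedsort` implements a complete workflow for evaluating crop-seed
quality from near-infrared (NIR) hyperspectral images: calibrating and
segmenting seed trays, deriving sparse PLS-DA discriminant models from
per-seed reflectance spectra, and — its methodological core — a family
of sorting-oriented evaluation metrics built around the *standard
condition* and *relative precision*.

## The sorting problem

A seed batch with initial eligibility rate `iP` (the fraction of seeds
that germinate normally and, where relevant, carry the desired hybrid
haplotype) is to be improved by recovering only seeds whose discriminant
score `ŷ` is at or above a lower score threshold (LST). Every LST
defines an operating point with precision `P` (eligibility rate after
sorting), recall `R` (fraction of eligible seeds recovered) and accuracy
`A`. The whole family of operating points is the sorting curve, derived
from the empirical distribution of scores.

## Standard condition

When the fraction of *all* seeds recovered equals `iP`, precision and
recall coincide (`sP = sR`), whatever the model. We call this operating
point the standard condition; its threshold is the standard LST
(`sLST`), defined as the k-th highest score with `k = round(iP·N)`.
Because a physical sorter cannot split seeds with identical scores, ties
at `sLST` are all recovered and the realized recovery may exceed `k`
(the reported `sP` uses the realized cut). `sP` is the primary
model-selection criterion: how far the eligibility rate rises above `iP`
under a fixed, comparable recovery budget.

## Relative precision and AUC-rPR

Precision is bounded below by `iP`, so PR curves (and AUC-PR) from
batches with different `iP` are not comparable. Relative precision

    rP = (P − iP) / (1 − iP)   if P > iP, else 0

rescales precision to [0, 1]: 0 means no enrichment, 1 means the
recovered fraction is pure. The rP–recall curve (rPR) and its area
(AUC-rPR) evaluate a model across all threshold settings with much
weaker `iP` dependence than AUC-PR, so they are the criterion of choice
for comparing models across batches.

Area computation is trapezoidal over recall in [0, 1]. Empirical curves
do not reach `R = 0`; the curve is closed by carrying the value at the
smallest achieved recall to 0 (and, symmetrically, the last value to 1
if needed). This constant-extrapolation closure is the least-assumption
choice; a step-function (average-precision) integration differs by less
than the sampling noise at the batch sizes used here.

### Degenerate and edge cases

- Batches with a single class, `iP ∈ {0, 1}`, or an empty recovery set
  raise degenerate-data errors rather than returning conventional
  values.
- `Amax` (maximum accuracy over thresholds) includes the recover-nothing
  classifier, so `Amax ≥ max(iP, 1 − iP)` always.
- All metrics are rank statistics of the scores: any strictly monotone
  transform of `ŷ` leaves `sP`, `Amax`, AUC-PR and AUC-rPR unchanged.

## Thought experiment and its analytic oracle

The metric surface is validated on hypothetical discriminant models of
graded skill — near-perfect (NP), medium (MP) and poor (PP) — that score
eligible/ineligible seeds from normal distributions with sd 0.25 and
means ±1, ±0.2 and ±0.05 respectively, applied to batches of 65,535
seeds at `iP` = 80% (52,428/13,107) and 60% (39,321/26,214). The
`N(μ, 0.25)` notation is read as standard deviation 0.25: with variance
0.25 the resulting `sP` values are inconsistent with the rest of the
metric surface by more than two percentage points, as the analytic
oracle shows.

The oracle computes the population standard condition of any normal
mixture by bracketed root finding on
`iP·S_ok(t) + (1−iP)·S_ng(t) = iP` (with `S` the class survival
functions), then `sP = S_ok(sLST)`. Simulated and analytic values agree
within the asymptotic quantile standard error
`sqrt(iP(1−iP)/N) / f(sLST)`.

One caveat worth stating explicitly: for a near-perfect model the
standard threshold falls in the nearly empty gap between the two score
clusters. The empirical `sLST` there is an extreme order statistic
whose run-to-run spread (sd ≈ 0.045 at N = 65,535 for the NP model) is
orders of magnitude larger than for density-supported quantiles, and
the mixture density `f(sLST)` in the denominator of the quantile SE is
correspondingly tiny. Any single published realization of NP-model
`sLST` is therefore reproducible only to within that spread, not to
quantile precision; `sP` and the area metrics are unaffected.

## Multi-trait sorting

When eligibility requires several traits (e.g. germinability *and*
hybrid haplotype), three routes are supported:

- **successive**: two per-trait models with independent thresholds; the
  P/R/rP of the intersection form surfaces over the threshold grid
  (default 201×201 over each model's achieved score range), with
  PR/rPR volumes integrated over the per-model marginal-recall unit
  square by 2-D trapezoid. Grid cells whose intersection recovers no
  seed inherit precision from the nearest less-strict non-empty cell,
  the surface analogue of the curve closure above.
- **direct**: one model trained on the joint eligibility label.
- **unification**: per-trait scores are standardized as
  `ẑ = (ŷ − sLST(ŷp)) / s(ŷp)` and combined as `û = min_i ẑ_i` — the
  conservative choice, since rejection is preferred over acceptance when
  any requirement is in doubt. `û` is then treated like any other score.

The calibration subset `ŷp` used to estimate the scale (`s`, computed
with ddof = 1) and location (`sLST`) of a model's score distribution
defaults to the model's outer-cross-validation scores; any labeled
scored batch can be supplied instead. Standardization makes `ẑ = 0`
the estimated standard condition, so `ẑ` values are comparable across
models and testing occasions.

## Spectral preprocessing

Raw per-seed reflectance `R` (mean over seed-occupied pixels) generates
twelve candidate explanatory variables by crossing three base transforms
(identity, reciprocal `1/R`, pseudo-absorbance `−log10 R`) with optional
Savitzky–Golay smoothing (window 5, 3rd-order polynomial, mirror-padded
edges) and optional standard normal variate (SNV) row standardization
(sample sd, ddof = 1). The index layout is blocks of four per base —
plain, +SG, +SNV, +SG+SNV — giving X1–X4 (reflectance), X5–X8
(reciprocal), X9–X12 (pseudo-absorbance).

Every variant is computed on the valid spectral range (980–2,200 nm;
201 wavebands on the reference 6 nm-pitch instrument grid, other grids
accepted with a warning). Restricting *before* the transforms keeps the
chain compositional (X2 = SG(X1), X4 = SNV(SG(X1))) and all twelve
matrices on one waveband axis; only the SNV normalization strictly
requires the restriction. When both filters are flagged, SG runs before
SNV by default (denoise, then baseline-correct); the order is recorded
in the variant provenance and can be flipped. Reflectance ≤ 0 is a
domain error; values below 1e−6 are clipped up (logged) before
reciprocal/logarithm.

## Discriminant modeling

PLS-DA is PLS1 regression of the ±1 eligibility dummy on
column-centered (not scaled) spectra; the continuous prediction is the
discriminant score. The latent-variable count minimizes K-fold
cross-validated MSE (default 10-fold, capped at 20 for single fits; the
candidate-derivation loop uses 5-fold capped at 10 with an
early-stopping scan, since the CV-MSE curve is near-convex in
components). Waveband selection follows an adaptive LASSO: the
standardized partial regression coefficients
`β_j = coef_j · sd(x_j)/sd(y)` of the full-waveband model set
per-variable penalty weights `1/|β_j|` (zero-SPRC wavebands are
hard-excluded), realized by rescaling columns by `|β_j|` and running a
standard lasso path. Each distinct support along the path is refit with
PLS-DA. Variable importance in projection is
`VIP_j = sqrt(p · Σ_a SS_a (w_ja/‖w_a‖)² / Σ_a SS_a)` with `SS_a` the
y-variance captured per component; mean squared VIP is 1 by
construction.

**Validation is nested.** Candidate metrics come from mutual outer
cross-validation over the paired duplicate captures (each tray is imaged
twice, rotated 180°): the *entire* derivation chain — full-waveband fit,
SPRC, lasso path, refits — runs inside the training capture, and the
held-out capture is scored; fold results are pooled per sparsity rank
(position along the size-ordered path). Selecting supports on all rows
and then "validating" across captures leaves substantial selection
optimism (measured at ≈0.2 AUC-rPR on pure-noise data, versus ≈0.01
nested), because chance band–label correlations are shared between
captures of the same seeds. The deployable model of each candidate is
refit on all rows using the same-rank support of the all-rows chain.
With a single capture the folds fall back to seeded seed-level 2-fold
CV, with a warning.

Candidates are ranked by `sP` (descending), tie-broken by AUC-rPR then
support size ascending. The optional iterative mode re-evaluates all
candidates over repeatedly resampled seed-level fold assignments and
aggregates median ranks — one concrete realization of selecting models
that rank highly across repeated derivations.

Runtime-bounding choices (all package defaults, adjustable): the lasso
grid in the derivation loop uses 60 alphas down to `1e−2·λ_max` (the
dense tail beyond half the wavebands never yields a candidate and
dominates runtime on weak-signal data; the standalone
`adaptive_lasso_path` default remains 100 alphas to `1e−4·λ_max`), at
most 25 supports per variant are evaluated (spread over the size
range), and supports above half the waveband count are not refit.

## Hypercube handling

Cubes are ENVI-style header + binary pairs; BSQ/BIL/BIP interleaves are
accepted and returned in `(line, sample, band)` memory order.
Reflectance calibration is per-pixel-per-band linear interpolation
between a darkfield (0%) and a 99%-reflectance standard, clipped to
[0, 1.2] (specular glints; clipping logged). Seed segmentation — not
part of the modeling contract, since tray layouts are often known — is
Otsu thresholding of the mean-reflectance image, 4-connected components
with a minimum area (default 20 px at ≈90 ppi), ordered row-major by
centroid; a well-grid alternative is provided. Per-seed spectra are
unweighted means over region pixels. Score maps fill each region with a
colormap color of its min–max-normalized score over a grayscale
background.

## Synthetic data

The generator emulates the structure the method must cope with, not any
particular crop's chemistry:

- smooth base reflectance (~0.45) with a broad 1,940 nm water feature;
- three informative Gaussian absorption dips (sd 18 nm) centered at
  1,200, 1,730 and 1,920 nm — the C–H and amide overtone regions where
  storage-lipid and protein differences appear — deeper by
  `effect_size` (default 0.03 reflectance) in ineligible seeds;
- per-seed, per-feature depth variability (sd 0.01): seeds differ in
  biochemical composition feature-to-feature, so no single absorption
  band is a perfect surrogate of eligibility and an optimal sparse
  model draws on all informative regions;
- per-seed baseline offset (sd 0.02) and tilt (sd 0.01), band-wise
  noise (sd 0.01), and two captures per seed differing by independent
  measurement noise plus a capture-level offset (sd 0.005);
- stratified labels: exactly `round(iP·n)` eligible seeds.

A support is credited with recovering an informative feature when it
selects any channel within the feature's half-maximum window:
neighbouring channels inside one absorption band are nearly collinear
and interchangeable for a sparse model.

What the generator does *not* emulate: crop-specific waveforms,
scattering physics, seed-orientation effects, instrument drift between
sessions, or spatially structured within-seed heterogeneity. Passing
the planted-recovery tests therefore shows the derivation chain is
sound, not that any particular crop is discriminable.

## Problem sizes and determinism

The thought experiment runs at the full 65,535-seed batch sizes
(seconds). Pipeline recovery and null checks use 400 seeds × 201 bands
× 2 captures with 20 replicates each, sizes at which the nested
derivation completes in a few minutes while the planted signal
(effect/noise = 3) remains clearly detectable. All randomness flows
through seeded NumPy generators; replicate seeds are spawned from a
single root `SeedSequence`, so every result is reproducible from one
integer.

## Known limitations

- Mutual outer cross-validation across duplicate captures validates on
  unseen *measurements*, not unseen *seeds*: seed-level confounds
  shared by both captures (here, baseline and depth variability) are
  not penalized. External validation on a different batch remains the
  only test of generalization across seeds.
- The standard condition requires `0 < round(iP·N) < N`; very small or
  extremely imbalanced batches are rejected.
- AUC integration choices (trapezoid vs step) matter only below the
  sampling noise of the batch sizes treated here, but are configurable
  via direct use of `auc` on curve points.
- The iterative-ranking protocol is one admissible reading of
  "frequently high-ranked across repeated derivation"; its fold
  resampling is seed-level, so its absolute metric values are more
  optimistic than the capture-nested ones and are used only for
  relative ordering.
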