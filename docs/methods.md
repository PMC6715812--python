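# Methods

`glcmrad` implements a texture-radiomics pipeline for preclinical brain-tumor
MRI: gray-level co-occurrence matrix (GLCM) features extracted from segmented
tumor volumes, tumor-type classification under cross-validation, exponential
growth-rate modelling with a shallow neural network, and a sensitivity
analysis of feature values against the number of gray levels. This note
records the models, the defaults and the numerical choices, and what the
synthetic phantoms do and do not establish about real data.

## Feature extraction

**Quantization.** Intensities are binned linearly into N levels over the
*whole volume's* min–max range (bin width `(max − min)/N`; the maximum maps
to level N; a constant volume maps to level 1). Volume-wide binning — rather
than per-slice — gives every slice the same gray-level scale, which is what
makes averaging per-slice GLCMs coherent. A per-slice caller can pass its own
pre-quantized array.

**GLCM.** For a slice and its binary tumor mask, ordered pixel pairs
`(p, p + offset)` are counted only when *both* endpoints are in-mask, at
pixel distance δ = 1 along 0°, 45°, 90° and 135°; symmetry is applied by
adding the transpose, so each direction's total equals twice the ordered
pair count. Each directional matrix is normalized to sum 1 and the four are
averaged. Directions with no valid pair are excluded from the average; a
slice is degenerate only when all four are empty (e.g. a single-pixel mask).
For the whole-tumor region the normalized per-slice matrices are averaged
(matrices are averaged before features are computed, never features
averaged). Neighbor distances δ > 1 are out of scope: tumor cross-sections
at this resolution are too small for longer offsets to be meaningful.

**Regions.** A slice is *visible* when its mask area is positive. The
*central* slice has the largest cross-section (first occurrence on ties).
Walking outward from the central slice on one side, the *edge* is the
second-to-last visible slice, and the *middle* is halfway between central
and edge, rounding half away from the central slice. The default side policy
is deterministic — the side with more visible slices beyond the central one,
ties toward higher indices — with an optional seeded-random policy
(`side="random"`) emulating a rater picking either side. Tumors spanning too
few slices get middle and/or edge flagged absent and those rows are recorded
as failures, not silently dropped. The *whole* region uses all visible
slices.

**The 33 features.** 10 first-order statistics of the raw (unquantized)
in-ROI intensities and 23 second-order statistics of the normalized GLCM,
following Haralick, Soh & Tsatsoulis, and Clausi. Each name in
`features.FEATURE_REGISTRY` carries its IBSI reference code. Conventions
that matter for cross-implementation comparison:

- entropy-type features use base-2 logarithms with `0·log 0 ≔ 0`;
- skewness and kurtosis are population (biased) moments, kurtosis
  non-excess (Gaussian → 3); a constant sample leaves both NaN rather than
  silently 0;
- first-order intensity entropy uses a fixed 256-bin histogram over the
  sample range;
- sum variance is computed about the sum average (the modern convention),
  not about sum entropy;
- the second information measure of correlation converts its bit-valued
  entropies to nats inside the exponential, `√(1 − exp(−2 ln2 (HXY2 − HXY)))`;
- correlation is NaN for a zero-variance GLCM; all other features are still
  returned;
- a GLCM built with fewer occupied levels than N is *not* re-indexed — the
  matrix stays N×N, so index-scaling features (autocorrelation, cluster
  shade/prominence, sum statistics) legitimately grow with N.

The exact composition of a published 33-feature panel varies between tools;
this registry pins 10 + 23 and includes every feature the analysis reports
on (autocorrelation, cluster prominence/shade, sum average/variance, sum of
squares, entropy, maximum probability, contrast, energy, correlation,
homogeneity, skewness, kurtosis, median/mean intensity).

## Synthetic phantoms

The phantom generator provides the study conditions for every downstream
stage. Three tumor classes emulate a mouse glioma (GL261-like), a human
glioma (U87-like) and a human medulloblastoma (Daoy-like):

| class | corr. length (px) | intensity mean ± SD | border softness (px) | α (mm³) | β (day⁻¹) |
|-------|------------------|---------------------|----------------------|---------|-----------|
| GL261 | 1.5 | 600 ± 80 | 0.5 | 0.7 ± 0.9 | 0.15 ± 0.04 |
| U87   | 2.5 | 500 ± 120 | 1.0 | 1.2 ± 0.8 | 0.21 ± 0.03 |
| Daoy  | 4.0 | 550 ± 150 | 3.0 | 0.9 ± 0.5 | 0.08 ± 0.04 |

Growth-parameter scales are the cohort estimates reported for these three
models; texture correlation length and border softness encode the
qualitative contrast between well-defined glioma borders and diffuse
medulloblastoma borders, and are pairwise distinct so the classes are
separable by texture alone.

Each scan is an ellipsoid (seeded axis ratios in [0.75, 1.35], seeded
sub-voxel center jitter) voxelized to exactly `round(V/voxel volume)`
voxels — the voxels of smallest ellipsoidal norm — so mask-derived volumes
match the growth law to within half a voxel. In-mask texture is white noise
smoothed in-plane by a Gaussian kernel of the class's correlation length,
then standardized *on the in-mask voxels* so the requested intensity mean
and SD hold exactly (a finite correlated region otherwise under-disperses
relative to the field's marginal SD by several percent). The tumor blends
into a constant background (100 a.u.) through a Gaussian-blurred mask of
width `border_softness`; white measurement noise (default SD 5 a.u.) is
added everywhere. The texture field is rendered only on the padded mask
bounding box; outside it the blend weight vanishes identically.

Per-animal (α, β) are drawn once — α moment-matched lognormal, β normal —
and clipped to ±2.5 SD (β floored at 0.01/day, α at mean/6) so every
scheduled tumor fits the imaging grid. Longitudinal volumes follow
`V(t) = α·e^(βt)`; the standalone series generator adds unit-mean
multiplicative lognormal noise of a given coefficient of variation
(multiplicative, so volumes stay positive at any noise level). Cohorts are
lazy: the manifest (scan_id, animal_id, class, day, volume_mm3, per-scan
seed) is planned up front and voxel data is regenerated bit-identically on
demand, or materialized to NIfTI / single-slice DICOM plus a manifest CSV.

Defaults: 15 animals per class, weekly imaging at days 7–42 post-implant
with a tumor-burden cutoff — an animal leaves the schedule once its volume
exceeds 300 mm³ (the first two sessions are always kept so every animal
supports a growth fit). Fast-growing classes therefore contribute fewer
scans per animal and slow-growing classes more, as in longitudinal animal
studies; the default cohort comes to roughly 220 scans. The grid is 40
slices of 256×256 at 0.117×0.117 mm and 0.5 mm thickness — the emulated
acquisition geometry, with enough slices for the largest tumor the cutoff
and the clipped parameter draws admit.

**What the phantoms do not emulate:** MR physics (no k-space, bias field,
partial-volume or contrast kinetics), anatomical context (uniform
background), inter-scanner variation, and segmentation error (masks are
exact). Passing the pipeline tests on phantoms therefore demonstrates that
the *computational chain* behaves as designed — separable texture in,
correct features, classifiers and fits out — not that real tumors of these
three types are separable at these accuracies.

## Classification

Three families, matching the study design:

- **Decision tree** — Gini impurity; maximum leaf count and minimum
  observations per leaf chosen by deterministic grid search minimizing
  inner stratified-CV error (a reproducible stand-in for black-box
  hyperparameter optimization).
- **Random forest** — 500 bootstrap Gini trees, √p features per split; the
  ensemble class is a hard majority vote over trees, with per-class vote
  fractions exposed as ROC scores; vote ties break toward the first class
  in sorted label order.
- **SVM** — Gaussian kernel, one-vs-one multiclass; box constraint, kernel
  scale and standardization on/off grid-searched; aggregated one-vs-rest
  decision values serve as ROC scores (the model emits no probabilities).

Evaluation: stratified 10-fold cross-validation partitioned by scan (the
study's unit; repeat scans of one animal may straddle folds — an
acknowledged limitation of that design), with an animal-level mode
(`groups=`) for leakage-free folds. When k exceeds the smallest class count
(up to leave-one-out) plain shuffled folds are used. Out-of-fold predictions
are pooled into one confusion matrix; per-class accuracy, specificity,
sensitivity and F-score follow the one-vs-rest formulas
`(TP+TN)/total`, `TN/(FP+TN)`, `TP/(TP+FN)`, `2TP/(2TP+FP+FN)`, with zero
denominators reported NaN. AUC is the one-vs-rest trapezoid ROC, equal to
the rank-sum estimator under ties. 95% CIs are percentile bootstrap (2000
seeded resamples of the pooled predictions); the CI method is a documented
choice — the original report does not state one.

Forest feature importance credits each branch node's weighted impurity
decrease to its split feature, summed over all trees and divided by the
forest's total branch-node count; unused features score exactly 0.

## Growth modelling

Per tumor, `V(t) = α·e^(βt)` is fit by trust-region nonlinear least squares
(`scipy.optimize.least_squares`, `trf`, α bounded positive), initialized
from the log-linear regression of log V on t; the result carries RSS and
convergence status. The fit is exact to ≤1e-6 relative on noiseless series
and recovers β with <2% bias at 10% multiplicative noise over four weekly
time points (simulation in the test suite).

The predictor is a fixed-architecture feedforward network: 33 inputs (the
whole-tumor N=512 feature vector from each animal's *first* imaging
session), one hidden layer of 33 sigmoid units, linear 2-unit output
(α̂, β̂). Features are standardized and targets min–max normalized with
constants fitted on the training partition only; both are serialized with
the weights (JSON), so the error metric is well-defined anywhere. Training
minimizes full-batch MSE with L-BFGS run in stages (default 60 stages × 40
iterations), keeping the weights of the best validation MSE and stopping
after 8 stages without improvement — a deterministic, second-order-friendly
substitute for Levenberg–Marquardt backpropagation, immaterial at this
network size. The data split is class-stratified 60/35/5
(train/validation/test; per class `floor` for train and validation,
remainder to test).

Prediction error is the mean squared error of min–max-normalized (α, β)
jointly, × 100 ("percent MSE"). The acceptance evaluation augments the
internal 5% test partition with a separate two-animal-per-class phantom
cohort, mirroring a held-out test cohort of 2 cases per type — three
internal test animals alone would make the metric meaningless.

## Sensitivity analysis

The sweep extracts features at the ten GLCM sizes
N ∈ {8, 16, 24, 32, 48, 64, 98, 128, 256, 512} (the published sequence,
including 98) for any region set, in long format with failures recorded.
Per feature and size, a one-way fixed-effects ANOVA compares the three
classes; significance uses the Bonferroni threshold α/m with α = 0.05 and
m = 99 (three types × 33 features), i.e. 0.000505051, and the equivalent
adjusted p-values `min(p·m, 1)` are emitted alongside. When every group has
zero internal variance with unequal means the p-value is reported as the
smallest positive float with a degeneracy note rather than a hard zero.

Size dependence is summarized per feature as the relative range of the
per-size cohort means, `(max_N m_N − min_N m_N)/max(|m̄|, ε)`, plus a
Spearman rank correlation of m_N against N as a monotone-trend statistic;
features are ranked by the relative range. The statistical test behind the
original size-dependence p-values is unspecified, so the ranking — not a
p-value — is the checked property: the four index-scaling features
(autocorrelation, cluster prominence, sum of squares, sum variance) must
rank above the median.

## Problem sizes and degenerate inputs

The shipped test and acceptance runs use the default cohort (15
animals/class × 3 sessions = 135 scans), 200-case brute-force oracle
equivalence on images ≤16×16 with N ≤ 16 at 1e-9 tolerance, and 200
simulated tumors for parameter recovery — sizes chosen so a full run
completes on one CPU in minutes while keeping every statistical check
well-powered.

Degenerate inputs are handled explicitly throughout: empty masks, absent
regions, single-pixel slices (degenerate GLCM), constant volumes (one
quantization level; NaN skewness/kurtosis), zero-variance GLCMs (NaN
correlation), zero-variance targets and too-small classes all raise or flag
rather than silently returning numbers.

## Known limitations

- The phantom classes are far cleaner than real cohorts; reported phantom
  accuracies are upper bounds in kind, not estimates of the original
  dataset-dependent numbers.
- First-order features are computed on raw intensities (whether the
  original panel used raw or quantized values is unstated).
- The feature registry's 33-name composition is a documented
  reconstruction; other tools' panels may differ feature-for-feature.
- Scan-level folds allow repeat scans of an animal across folds by design
  fidelity; use `groups=animal` for leakage-free evaluation.
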