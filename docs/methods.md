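# Methods

This note documents the models, the synthetic-data generator, the numerical
conventions, and the design choices made where the problem left the design
genuinely open.

## Discriminant models

**Class coding.** A label vector over K species becomes an n × K one-hot
indicator matrix Y, columns ordered by sorted class code. Classification of
a predicted row is by argmax.

**PLS-DA.** Fitted by sequential component extraction with per-component
deflation of both X and Y (NIPALS semantics). X is column-scaled (default
mean-centering for spectra, autoscaling for metabolite tables — standard
chemometric practice), Y is column-centered. For each component the weight
vector w is the dominant left singular vector of the residual
cross-covariance X′Y. This is exactly the fixed point of the classical
NIPALS inner iteration, computed directly: the power iteration it replaces
converges at a rate set by the gap between the top eigenvalues of X′YY′X,
and for late components of high-capacity models (20+ LVs) that gap sits in
the noise floor, so no fixed iteration budget is reliable. Scores t = Xw,
loadings p = X′t/t′t, response loadings c = Y′t/t′t; both X and Y are
deflated by the rank-one component before the next extraction. Coefficients
B = W(P′W)⁻¹C′ reproduce the training fit from the scaled X. Signs are
fixed (largest-|w| element positive) for bit-reproducibility. Degenerate
residuals (zero response variance, X uncorrelated with Y) raise an error
rather than returning a partial model.

**OPLS-DA.** Orthogonal components are extracted iteratively before the
predictive fit: take (w, t, p) of a one-component PLS on the current
residual, form w_o ∝ p − (w′p)w (the part of the loading orthogonal to the
predictive weight), score and deflate X by (t_o, p_o). After A_o rounds the
filtered X is fit by ordinary PLS-DA. For the multi-class case one shared
set of orthogonal components is extracted against the full indicator matrix
(simpler than per-class contrasts, and sufficient for score-plot and VIP
use). With zero orthogonal components the model is prediction-identical to
PLS-DA, which the tests assert.

**VIP.** `VIP_j = sqrt( p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a )`, where
SSY_a = (t_a′t_a)(c_a′c_a) is the response sum of squares captured by
component a. Σ_j VIP_j² = p identically. Two screening conventions coexist
deliberately: metabolite screening uses the inclusive VIP ≥ threshold,
while the VIP fusion strategy uses the strict VIP > threshold; both are
exposed via a flag.

**Cross-validation.** Stratified venetian-blind folds within each class
(deterministic), 7 folds by default — the common default of commercial
PLS software. Scaling and Y-centering are re-estimated inside every fold.
Q² = 1 − PRESS/SS with SS the held-out deviation from the fold-training
mean; RMSECV = sqrt(PRESS/(nK)). A fold whose training partition loses an
entire class is an error. RMSEE and RMSEP use the same nK denominator
(no degrees-of-freedom correction), matching the cross-validated analogue.

**Permutation testing.** Labels are permuted n_perm times (n ≥ 20); for
each permutation the model is refit and (|r|, R²Y, Q²) recorded, with |r|
the absolute Pearson correlation of the vectorized permuted and original
indicator matrices. The R² and Q² intercepts come from least-squares lines
through the permuted points plus the unpermuted model at correlation 1 —
the convention of the standard permutation-validation plot. A Q² intercept
below the original Q² (and near or below zero) indicates no overfitting.

## Fusion strategies

All three strategies share one sample split so comparisons are paired. The
split is Kennard–Stone, applied per class (quota ceil(0.7 × 15) = 11) on
the autoscaled low-level concatenation of all blocks; with 13 × 15 samples
this yields 143 calibration / 52 validation. Plain unstratified 70 % of 195
would give 136–137, so only the stratified reading reproduces the 143/52
design. Every selection or projection parameter — block centers, block
variances, VIP selections, per-block models — is estimated on calibration
rows only; tests assert that perturbing validation rows changes nothing.

* **Low-level**: blocks are centered on calibration means and divided by
  the square root of their total calibration variance ("block-variance"
  scaling) so the 1001-channel NIR block cannot dominate the 226-channel
  MIR block by size alone; then concatenated (1227 columns).
* **Mid-level (VIP > 1)**: a 10-LV PLS-DA per block on calibration rows
  gives VIPs; channels with VIP strictly above the threshold are kept and
  concatenated (block-variance scaled). An empty selection is an error
  naming the block.
* **Mid-level (latent variables)**: per block, a PLS-DA (5 scores) and a
  PCA (5 scores) are fit on calibration rows; calibration and validation
  rows are projected and the scores concatenated (20 columns for two
  blocks). The 5+5 mix is configurable; no per-block counts are published.

Final-model capacities default to the published values per strategy
(LV = 23, 22, 12). The permutation test inside `run_strategy` defaults to
20 permutations (the routine's minimum) to keep the harness cheap; pass
`n_permutations=200` for a publication-style validation plot, or 0 to skip.

## Synthetic-data generator

The generator emulates the study design: 13 species × 15 samples, 3
instrument replicates per sample and modality, averaged before modelling.

* **Contents.** Per class, each metabolite's relative content is drawn from
  Normal(mean, SD) truncated at zero — contents cannot be negative and only
  mean ± SD are published. The 13 default class specs carry exactly the six
  published main metabolites per species over a shared 31-metabolite
  universe (absent metabolites: mean 0, SD 0). At SD = 0 the mean is
  reproduced exactly. Truncation biases the mean upward by at most ~0.002 %
  for the most dispersed compounds; tests allow for this explicitly.
* **Spectra.** Each spectrum is a sum of Gaussian bands at the literature
  peak positions (NIR: 8330, 6803, 5696, 5179, 4693 cm⁻¹; MIR: 3289, 2921,
  2854, 1623, 1425, 1369, 1315, 1240, 1010 cm⁻¹) on the acquisition grids
  (12,000–4000 cm⁻¹ at 8 cm⁻¹; 4000–400 cm⁻¹ at 16 cm⁻¹, stored
  descending). Band FWHM defaults: 120 cm⁻¹ (NIR overtone/combination
  bands) and 40 cm⁻¹ (MIR fundamentals), config-overridable.
* **Band amplitudes.** amplitude(sample i, band k) =
  matrix_k(class) + baseline_k + Σ_m L_km · content_im. The species matrix
  term (uniform on [0, 0.6] absorbance units per class and band, seeded
  from the class code) represents the non-volatile bulk of the powder —
  starch, cellulose, protein — which dominates real NIR/MIR spectra of
  ground fruits, is stable within a species, and differs between species.
  The affine volatile term (nonnegative loading matrix L, fixed seed;
  scale 0.05 per % content) propagates compositional differences into band
  intensities. Both structural matrices are frozen under a module-level
  seed independent of the sampling seed, so the "instrument response" is
  identical across runs. Without the matrix term, species pairs sharing
  similar volatile profiles are intrinsically inseparable from 14 band
  amplitudes — contrary to the premise that powder spectra distinguish all
  thirteen species.
* **Noise.** Replicates of a sample share its band amplitudes and differ
  only by a smooth random baseline (three low-order cosine terms, SD 0.01
  a.u.) and white noise (SD 0.005 a.u.) — instrument-replicate semantics.
  Defaults are realistic for absorbance spectra with peak heights of
  0.1–1 a.u. and leave the between-class to within-class distance ratio
  comfortably above one, which the test suite asserts directly.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: chromatographic co-elution and identification
ambiguity, correlated metabolite covariance within a species (draws are
independent), water-band and scattering artifacts, ATR penetration-depth
effects, batch and instrument drift beyond the smooth baseline, and any
nonlinearity between composition and absorbance. Results on the synthetic
study demonstrate that the pipeline is correct and that the design is
recoverable under its stated noise; they are not evidence about any
particular real spice dataset.

## Other conventions and degenerate inputs

* Kennard–Stone: initial pair = globally most distant pair; every tie
  breaks to the lowest index; a per-class quota of 1 falls back to the
  sample nearest the class centroid (the maximin rule needs two picks).
* Zero-variance variables under autoscaling (or z-scoring) get scale 1
  (respectively z = 0) with a logged warning, not an exception.
* HCA: Ward linkage on Euclidean distances of per-metabolite z-scores
  (population SD), the common metabolomics heatmap convention.
* "Upregulated in class c" — no published definition exists — is taken as:
  the class-mean z-score of the metabolite is maximal over classes and
  positive. This assigns each metabolite to at most one class, giving
  disjoint per-class counts.
* Compound classes: per-metabolite annotation from the packaged summary;
  one compound is printed there with inconsistent classes across species
  and resolves to its majority class. Unknown class strings on file read
  map to "other" with a warning. "Terpenoids" aggregates monoterpenes and
  sesquiterpenes.
* Explained-variation reporting for score plots is 100 × (r²x₁ + r²x₂),
  returned unrounded.

## Problem sizes

The test suite and the acceptance script run the full simulated design
(195 samples, 1227 fused channels, three fusion strategies with 23/22/12
LVs and 7-fold cross-validation) in a few seconds on one CPU; permutation
examples use 20–50 permutations, and the generator-recovery checks use
10,000 draws. These sizes were chosen as the smallest that exercise every
code path at the study's full design dimensions.
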