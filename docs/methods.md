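# Methods

`perirad` implements a clinical–radiomic analysis pipeline for liver-lesion
CT: a tumor volume of interest (Tumor-VOI) and a 5 mm peritumoral rim
(Margin-VOI) are characterised by 45 radiomic indices each, and nested
logistic models (clinical, clinical+Tumor, clinical+Tumor+Margin) are
compared by stratified cross-validation and paired permutation tests, with
the enrolment-center effect quantified by a random-intercept mixed model.
Because patient data of this kind are not publicly distributable, the
package ships a synthetic phantom and cohort generator with a known
generative model; all statistical claims the test suite makes are claims
about recovery of that generative truth.

## Coordinate conventions and the peritumoral margin

Volumes are 3D arrays in Hounsfield units, indexed `(i, j, k)` with
`spacing_mm` in the same axis order. All geometry is physical: a mask is
dilated by collecting every voxel whose center lies within the radius (in
mm) of some mask-voxel center, so anisotropic spacing (e.g. 5 mm slices)
correctly blocks out-of-plane growth. The margin is
`dilate(tumor, 5 mm) \ tumor`. The margin is clipped only by the image grid;
if the dilation would leave the grid the operation raises instead of
silently truncating, since a truncated rim would bias every margin feature.
No organ (liver) mask is applied: a real peritumoral rim can include
extra-hepatic voxels, and excluding them would require a segmentation the
pipeline does not assume. This is a known simplification.

## The 45 radiomic indices

Per VOI the retained vector holds:

* **7 grey-level descriptors** — HUmin, HUmean, HUstd, HUmax and the
  quartiles HUQ1/HUQ2/HUQ3 (inclusive linear-interpolation quantile rule).
* **4 first-order** — skewness and kurtosis (Pearson, i.e. non-excess,
  standardized central moments), histogram energy `sum(p^2)` and entropy
  `-sum(p log2 p)` over discretized-bin probabilities.
* **3 shape** — volume (mL), sphericity `pi^(1/3) (6V)^(2/3) / A`, and
  compacity `A^(3/2) / V`, with `A` a mesh surface area.
* **6 GLCM, 11 GLRLM, 3 NGLDM, 11 GLZLM** texture indices (below).

The GLCM routine computes seven values (homogeneity, energy, contrast,
correlation, entropy in log2 and log10, dissimilarity) but the retained
vector keeps a single entropy: the log10 entropy is an exact scalar multiple
of the log2 entropy (`ln 2 / ln 10`), so the pair is perfectly correlated
and any redundancy screen — including this pipeline's own |r| > 0.85 rule —
would immediately remove one. Keeping both would also break the fixed
45-key contract the modeling stage relies on.

### Discretization

Texture matrices operate on integer grey levels. Default: fixed bin number
(64) over the VOI min–max, which makes texture indices invariant to global
HU shifts and rescalings; a fixed-bin-size mode over an absolute HU window
is available where cross-patient comparability of absolute HU is preferred.
A constant VOI maps to a single level.

### Texture matrices

* **GLCM** — symmetric co-occurrence counts at distance 1 along the 13
  unique 3D directions, restricted to in-mask voxel pairs. Feature values
  are computed per direction and averaged (a merged-matrix mode exists);
  direction averaging matches the common clinical-radiomics convention.
  Correlation is undefined (NaN, with a warning) when a direction's matrix
  has zero grey-level variance.
* **GLRLM** — maximal constant-level in-mask runs per direction; the eleven
  standard indices (SRE, LRE, LGRE, HGRE, SRLGE, SRHGE, LRLGE, LRHGE, GLNU,
  RLNU, RP) averaged over the 13 directions. Run percentage RP is runs per
  masked voxel.
* **NGLDM** — for each masked voxel with at least one 26-connected in-mask
  neighbour, the absolute difference between its level and the mean
  neighbour level is accumulated per level; Coarseness, Contrast and
  Busyness follow the Amadasun-style definitions. A single-level VOI has
  Contrast 0 and undefined Coarseness/Busyness (NaN sentinel, warned).
* **GLZLM** (size-zone) — 26-connected constant-level zones binned by
  (level, size); the same eleven-index family as the GLRLM with zone size in
  place of run length.

Undefined features are always emitted as NaN under their key, never
dropped, so the 45-column contract is stable.

### Surface area

Mesh surface area is obtained by marching cubes at the 0.5 iso-level of a
lightly smoothed occupancy field (Gaussian, 0.8 voxel). Meshing the raw
binary mask leaves a staircase artifact whose ~8 % area overestimate does
not vanish as resolution grows; with the anti-aliased field a digital
sphere's sphericity converges to 1 (radius 20 voxels: ≈0.997). The exact
voxel-face-count estimator is kept as an option; it is exact for
axis-aligned blocks — a cube's sphericity is `(pi/6)^(1/3)` to machine
precision — and upper-bounds the mesh area, which the tests exploit.

## Synthetic data

### Phantom

`background_hu + heterogeneity * T + noise`, with the lesion ellipsoid set
to `tumor_hu` first. `T` is Gaussian white noise smoothed by a Gaussian
kernel of physical width `texture_corr_len_mm` and rescaled to unit SD, so
`heterogeneity` is the texture amplitude in HU. Defaults (48³ grid, 1 mm
spacing, parenchyma 50 HU, lesion 80 HU, noise SD 8 HU, texture amplitude
10 HU, correlation length 2 mm, semi-axes 12/10/9 mm) give a
portal-phase-like lesion crop whose tumor and margin feature vectors differ
clearly. In the noise-free, zero-heterogeneity limit the phantom is exactly
two-valued, which anchors the extraction tests. Construction fails loudly if
the lesion plus a 5 mm rim does not fit inside the grid. The phantom does
not model scanner physics, reconstruction kernels, partial-volume effects or
anatomy; what passing tests show is that the *extraction and modeling
machinery* is correct, not that the phantom resembles any patient.

### Cohort

Clinical covariates are drawn from documented marginals chosen to resemble a
resected intrahepatic cholangiocarcinoma population (median age ~67, ~49 %
male, HBV 7.8 %, HCV 11.1 %, cirrhosis 10.7 %, log-normal diameter with
median 50 mm, tumor pattern 62/25/13 %, heavy-tailed log-normal CA 19-9 with
median ~29 U/mL, preoperative chemotherapy 10.7 %, major hepatectomy
52.5 %). The binary outcome follows a logistic model: intercept + named
clinical effects (per SD for continuous covariates, per category otherwise)
+ named radiomic-feature effects + a per-center Gaussian random intercept
with SD `center_sd`. Features can be attached from phantom extraction or
drawn from an equicorrelated multivariate normal. Missingness is applied
completely at random to designated covariates only — the 15 % imputation
rule is what the pipeline tests, and MCAR is the mechanism under which that
rule's behaviour has a clean expectation. An optional prevalence target
calibrates the intercept by root-finding on the realized linear predictors.

## Modeling-table assembly

Rows missing an outcome or any radiomic feature are excluded; covariates
missing in ≥ 15 % of the retained rows are excluded from the model matrix
and reported; covariates below the cut are imputed by chained equations
(iterated OLS of each incomplete column on all others, replacement =
prediction + Gaussian residual draw; observed cells never change; one
completed dataset per seed, several behind a flag). Feature pruning uses
absolute Pearson correlation with threshold 0.85, Tumor-VOI and Margin-VOI
blocks pruned independently; the greedy scan repeatedly takes the
most-correlated offending pair and drops the member with the larger mean
absolute correlation to the others, with column order as the deterministic
tie-break. Pearson on raw values was chosen because the features are
continuous and the rule is a redundancy screen, not an inference; the kept
set's max |r| ≤ threshold is asserted on every run. Continuous predictors
are z-scored before fitting, so odds ratios are per SD.

## Model families

Unpenalized fits are maximum-likelihood logistic regressions with Wald
intervals; lasso/ridge use internally cross-validated penalties with a fixed
seed. Backward elimination removes, at each step, the term whose deletion
most improves AIC, stopping when no deletion improves it; forward and
stepwise analogues are provided. AIC was preferred over a strict p < 0.05
rule because final clinical–radiomic models of this kind routinely retain
terms with p ≈ 0.09–0.11, which a 0.05 rule would never produce. Clinical
candidates enter selection from an a-priori list plus univariate screening
at p < 0.1 (chi-square/Fisher for categorical; t-test vs Mann–Whitney for
continuous, with the graphical normality check mechanized as |skew| < 1 and
|excess kurtosis| < 2 per group). Perfect separation is detected and the fit
falls back to a weakly ridge-penalized estimate, flagged on the result.

## Center effect

The center effect is a random-intercept logistic model estimated by maximum
likelihood with **adaptive** Gauss–Hermite quadrature (15 nodes): each
center's likelihood integrand is re-centered at its Laplace mode and
rescaled by the local curvature before quadrature. Adaptivity matters: with
~200 patients per center the integrand is an order of magnitude narrower
than the random-effect scale, and fixed-node quadrature visibly biases the
variance downward. The implementation agrees with `lme4::glmer` (nAGQ = 15)
to < 0.01 on shared data, which the test suite checks through `Rscript`.

The Variance Partition Coefficient uses the latent-threshold method,
`VPC = sigma_u^2 / (sigma_u^2 + pi^2/3)` — the standard choice for logistic
random-intercept models. At 30 centers the sampling variability of the
realized between-center variance alone gives the recovered VPC an SD of
about 0.07, so recovery checks average the estimate over five independent
cohorts at the stated scale (30 centers × 200 patients) rather than scoring
a single draw.

## Validation design

* **Stratified k-fold CV, k = 50.** The splitter deals each class
  round-robin into k folds after a seeded shuffle, so class counts smaller
  than k are legal; with ~244 patients folds hold ~5 patients, which is why
  per-fold metric SDs are large (±0.2–0.4) and why folds containing a single
  class have their panel flagged undefined and excluded from the mean, with
  the count reported. By default pruning and subset selection are re-run
  inside every training split so the held-out fold never informs selection;
  a pre-selected-model mode (plain per-fold refit of a fixed column set) is
  available and is what the replicate-heavy pattern analyses use for speed.
  Threshold metrics use a 0.5 probability cut.
* **Paired permutation test.** Two CV runs on identical fold assignments are
  compared per metric by sign-flipping the per-fold differences;
  `p = (1 + #{permuted mean >= observed}) / (1 + n_perm)`, one-sided for the
  challenger exceeding the reference. Identical inputs give p = 1; a uniform
  shift gives the minimal attainable `1/(1+n_perm)`. Fold-label permutation
  was rejected because it tests a different null than "the two models
  perform equally on the same folds".
* **Type-I calibration.** The test's size is measured on 200 synthetic null
  replicates of exchangeable paired per-fold metric panels (a shared
  per-fold difficulty effect plus independent model noise), which isolates
  the permutation machinery itself; running 400 full CV pipelines would
  measure the same thing at ~100× the cost.
* **Nested-block pattern.** On cohorts where tumor and margin features carry
  independent signal, mean cross-validated AUC must be non-decreasing across
  clinical → +Tumor → +Tumor+Margin, and each increment significant by a
  sign-flip permutation pooled over 20 replicates × 50 folds.

## Numerical and degenerate-input policy

NaN is the single sentinel for undefined features, always accompanied by a
warning. Constant columns correlate as 0 in pruning (warned). Quantile rule:
linear interpolation. GLCM/GLRLM direction averages skip directions with no
in-mask pairs. The mixed-model optimizer runs Nelder–Mead then BFGS from a
plain-logistic start with SD 0.5; σ is parametrized unsigned and floored at
1e-6 during likelihood evaluation.

## Problem sizes

Defaults used by the test suite and the acceptance script: 200 random VOIs
≤ 6³ for oracle equivalence; 48³ phantoms; cohorts of 244 (pattern
analyses), 1 000 (selection power, 100 replicates), 5 000 (odds-ratio
recovery) and 6 000 (VPC recovery, 5 replicates per level); 200 null
replicates for permutation calibration. These sizes give every check a
comfortable signal-to-noise margin while keeping a full run in the order of
minutes on one CPU.

## Known limitations

* No scanner/reconstruction physics, no liver-boundary exclusion of the
  margin, MCAR-only missingness.
* LifeX (the application used in the motivating clinical workflow) does not
  publish its exact discretization bounds or direction-aggregation mode;
  this package fixes documented defaults (64-bin min–max, direction
  averaging) and exposes the alternatives, but byte-parity with any
  particular application is out of scope.
* Odds ratios from penalized fits are reported without intervals (the
  penalty invalidates Wald standard errors).
* The cohort generator's covariate marginals are recognisably realistic but
  synthetic; nothing here validates against patient data.
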