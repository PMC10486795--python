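# perirad

**Tumor + peritumoral-margin CT radiomics with clinical–radiomic logistic
modeling.**

Pathology markers of liver-cancer aggressiveness — histologic grading (G3
vs G1-2) and microvascular invasion (MVI) — are only known after resection.
`perirad` implements the analysis pipeline used to predict them
non-invasively from preoperative portal-phase CT: it characterises the
tumor (Tumor-VOI) and a 5 mm peritumoral rim (Margin-VOI) by 45 radiomic
indices each, assembles them with clinical covariates into nested logistic
models, and asks — with stratified k = 50 cross-validation and paired
one-sided permutation tests — whether each radiomic block adds predictive
value over the clinical model, while quantifying the multicenter enrolment
effect with a random-intercept mixed model.

It is aimed at methodologists and imaging scientists who need a tested,
reproducible implementation of this workflow. Since patient imaging of this
kind is not redistributable, the package includes a synthetic phantom and
multicenter-cohort generator with a known generative model, so the entire
pipeline is exercisable and testable offline.

## What it computes

* **Margin geometry** — anisotropy-aware physical dilation:
  `margin = dilate(tumor, 5 mm) \ tumor`, distances measured between voxel
  centers in mm.
* **45 radiomic indices per VOI** — 7 grey-level descriptors (HUmin, HUmean,
  HUstd, HUmax, quartiles), 4 first-order (skewness, kurtosis, histogram
  energy/entropy), 3 shape (volume, sphericity
  `pi^(1/3)(6V)^(2/3)/A`, compacity `A^(3/2)/V`), 6 GLCM, 11 GLRLM,
  3 NGLDM, 11 GLZLM — all texture matrices in full 3D over the 13 unique
  directions, restricted to in-mask voxels, and validated against
  brute-force enumeration oracles.
* **Selection** — |Pearson r| > 0.85 redundancy pruning per VOI block, the
  <15 % missingness rule, chained-equation imputation.
* **Models** — ML logistic regression (ORs + Wald CIs), lasso/ridge,
  AIC-driven backward/forward/stepwise selection; random-intercept logistic
  mixed model by adaptive Gauss–Hermite ML with
  `VPC = sigma_u^2/(sigma_u^2 + pi^2/3)`.
* **Validation** — stratified k-fold CV (selection re-run per training
  fold), a six-metric panel (ROC AUC, PR AUC, sensitivity, specificity,
  accuracy, precision), and paired sign-flip permutation comparison of
  model blocks.

## Worked example

```python
import numpy as np
from perirad.phantom import PhantomConfig, CohortConfig, make_phantom, make_cohort
from perirad.voi import make_margin
from perirad.features import extract_all
from perirad.evaluate import stratified_cv, permutation_compare
from perirad.models import fit_mem

# a synthetic portal-phase lesion and its 5 mm margin
volume, tumor = make_phantom(PhantomConfig(seed=7))
pair = make_margin(tumor, volume, width_mm=5.0)
vec = extract_all(volume, pair)                      # 90 namespaced indices
print(round(vec["Portal_Tumor_Shape_Sphericity"], 3),
      round(vec["Portal_Margin_GLZLM_ZLNU"], 1))

# a multicenter cohort whose outcome depends on clinical + radiomic effects
tumor_f = ["Portal_Tumor_HUmin", "Portal_Tumor_GLRLM_SRHGE"]
margin_f = ["Portal_Margin_NGLDM_Busyness", "Portal_Margin_GLZLM_ZLNU"]
table = make_cohort(CohortConfig(
    n_patients=244, n_centers=6, center_sd=0.4,
    beta_clinical={"major_hepatectomy": 0.8, "age": -0.2},
    beta_features={tumor_f[0]: 0.6, tumor_f[1]: -0.6,
                   margin_f[0]: -0.7, margin_f[1]: 0.7},
    feature_names=tuple(tumor_f + margin_f), intercept=-0.6, seed=11))

clin = ["age", "major_hepatectomy", "ca19_9"]
cv_clin = stratified_cv(table, "G3", clin, [], k=50, seed=7, select_per_fold=False)
cv_tum = stratified_cv(table, "G3", clin, tumor_f, k=50, seed=7, select_per_fold=False)
cv_mar = stratified_cv(table, "G3", clin, tumor_f + margin_f, k=50, seed=7,
                       select_per_fold=False)
for name, cv in [("clinical", cv_clin), ("+tumor", cv_tum), ("+margin", cv_mar)]:
    print(f"{name:9s} AUC {cv.mean['roc_auc']:.3f} ± {cv.sd['roc_auc']:.3f}")

res = permutation_compare(cv_tum, cv_mar, n_perm=2000, seed=0)
print("margin increment: p =", round(res.p_values["roc_auc"], 3))
print("center VPC:", round(fit_mem(table, "G3", ["major_hepatectomy"]).vpc, 3))
```

prints

```
0.997 2645.7
clinical  AUC 0.627 ± 0.227
+tumor    AUC 0.732 ± 0.279
+margin   AUC 0.822 ± 0.197
margin increment: p = 0.01
center VPC: 0.042
```

i.e. the phantom lesion is nearly spherical, on this cohort each radiomic
block raises the cross-validated AUC, the margin increment over the
tumor-only model is significant at the 0.05 level, and ~4 % of the latent
outcome variance is attributable to the enrolment center. (Per-fold SDs are large because k = 50 on 244 patients
leaves ~5 patients per fold.)

A CLI mirrors the library:
`perirad phantom make`, `perirad voi make-margin`, `perirad features
extract`, `perirad select prune`, `perirad evaluate cv|compare` — run any of
them with `--help`.

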