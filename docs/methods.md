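# Methods

This note documents the models, the synthetic world, the numerical choices,
and the limits of what a green test establishes. Everything quantitative
below is computed by the package's tests or scripts; nothing is asserted
from memory.

## 1. The age model

The estimator regresses chronological age on voxel-wise gray-matter (GM)
probability values with an elastic net in the glmnet parameterization

    (1/2n) Σ_i (age_i − b0 − x_i'w)²  +  λ ( α‖w‖₁ + (1−α)/2 ‖w‖₂² ),

with α fixed at 0.5 and the intercept b0 never penalized. The solver behind
`BrainAgeModel` is scikit-learn's coordinate descent (`ElasticNet` /
`enet_path`; sklearn's `alpha` is λ and `l1_ratio` is α, so the objectives
coincide exactly); a ridge-only fit (α = 0) uses the closed form. The
protocol around the solver is authored here:

- **Standardization.** Each voxel is centered and scaled to unit SD before
  penalization (penalty fairness across voxels); coefficients are
  back-transformed to the original GM scale, and the intercept absorbs the
  means. Voxels constant across subjects are removed from the fit and
  reported with zero weight.
- **λ grid.** `auto` builds a descending log-spaced grid of `n_lambda`
  (default 100) values from λ_max = max|X̃'ỹ|/(n·α) — the smallest penalty
  at which all coefficients vanish — down to `lambda_min_ratio`·λ_max.
  The default depth is 1e-2 (glmnet's own default for p > n); profiling
  showed the deeper 1e-3 tail multiplies runtime ~10× while the 1-SE rule
  never selects there. Both settings are plain config fields.
- **Cross-validation.** k-fold (default 10) with a fresh seeded random
  partition per repeat (default 5 repeats) — the repeats average over
  partitioning noise. Within each training fold, features are
  re-standardized from fold statistics so validation errors leak nothing.
  Per λ, the CV curve records the fold-mean validation MSE and its standard
  error over folds.
- **Selection.** The one-standard-error rule: the largest λ whose mean CV
  error is within one SE (taken at the minimizing λ) of the minimum;
  `selection_rule="min"` is available. The per-repeat selections are
  averaged arithmetically (log-scale averaging by config) and the final
  model is refit once on all data at that λ.
- **Convergence.** The CV paths run at a loose duality-gap tolerance
  (`cv_tol=1e-3`; they only rank λ values on a curve whose own SE is far
  larger), while the final refit uses `tol=1e-8`. The refit satisfies the
  elastic-net stationarity (KKT) conditions to better than 1e-5 on the
  standardized scale; the test suite checks this directly and also matches
  the solver's objective against an independently coded coordinate descent
  to 1e-6 relative on small instances.

Accuracy is summarized as MAE, RMSE, and the Pearson correlation between
predicted and chronological age. When either vector is constant the
correlation is reported as undefined (`r_defined=False`), never silently 1.

## 2. Bias correction and the BAG

Penalized age models over-predict young and under-predict old subjects
(regression dilution / regression to the mean), so the raw gap
`pred − age` carries a spurious negative age trend. The correction fits OLS

    (pred_raw − age) = a·age + b + ε

on the **training** cohort (in-sample predictions) and subtracts the fitted
trend wherever the model is applied:

    BAG = (pred_raw − age) − (a·age + b),    pred_corrected = age + BAG.

By OLS orthogonality the corrected BAG is exactly uncorrelated with age in
the cohort the correction was fitted on (the suite verifies |slope| and
|intercept| < 1e-8 after re-regression). Whether to fit the trend on the
training or the target cohort is genuinely ambiguous in the field; it is a
config switch (`bias_fit_cohort`, default "train" — the variant that never
touches target outcomes and therefore cannot leak them).

## 3. Tertiles and the association suite

- **Tertiles.** Boundaries are the round(n/3)-th smallest and the
  round(n/3)-th largest BAG value, so all three groups stay within one
  subject of n/3 absent ties. Boundary ties go outward (v ≤ q1 → lowest,
  v ≥ q2 → highest), mirroring the "t1 ≤ q1 < t2 < q2 ≤ t3" printing
  convention. Heavy ties that would empty a group are an error, not a
  silent collapse.
- **Cox models.** lifelines `CoxPHFitter` with Efron tie handling, tertile
  dummies with the **highest** (oldest-looking) tertile as reference, plus
  the configured covariates (categoricals dummy-encoded drop-first),
  complete-case with the exclusion count kept on the result. The
  competing-risk sensitivity analysis is **cause-specific**: deaths from the
  competing cause are censored at their event time, and the event/competing
  tallies are reported. (The subdistribution-hazard alternative was not
  chosen because the emulated analysis reports "competing events" counts
  alongside an otherwise identical model.) With zero competing events the
  cause-specific model reduces to the plain fit exactly.
- **LS means.** From OLS of BAG on group + covariates, each group's
  least-squares mean evaluates the fit at that group's indicator with all
  covariate columns at their sample means (categorical covariates at their
  observed proportions). With no covariates this reduces to raw group means;
  pairwise contrasts use the model covariance and the residual t
  distribution. The adjustment set for the cognitive-status contrast is a
  config list (default empty, i.e. unadjusted) because the emulated
  analysis does not state its own.
- **Phenotype regressions.** One OLS per phenotype with BAG as outcome,
  the phenotype (binary or continuous) first, covariates (default age, sex,
  center-race) after; Wald 95% CI and p per phenotype.

## 4. Proteome-wide association scan

Per analyte: OLS of BAG on the standardized analyte plus covariates. All
analytes are fitted in one pass via the Frisch–Waugh–Lovell decomposition
(residualize BAG and analytes on the covariate block, then simple
regressions with n − q − 1 residual degrees of freedom), which is
algebraically identical to the per-analyte full model — the suite checks
equality with statsmodels to 1e-10, including a missing-data column that
takes the per-column complete-case fallback. Analyte preprocessing is
`raw` (default: z-score only, matching the generator's Gaussian analytes),
`log2`, or `rank` (inverse-normal), always followed by per-analyte
standardization, so β is in BAG-years per analyte SD.

Multiplicity: Bonferroni at α/m with m the analytes actually tested (after
QC and constant-column skips, both logged), and Benjamini–Hochberg step-up
at α, implemented in-package and cross-checked against statsmodels'
reference implementation in the tests. Bonferroni rejections are provably a
subset of BH rejections at equal α. Subgroup scans (e.g. cognitively normal
only) are plain subject filtering upstream; m is re-counted per scan.

## 5. The synthetic world

The generator states one coherent world and the defaults are that world;
they are not tuned per test.

- **Template.** An ellipsoidal soft blob (semi-axes 0.45 of each grid
  dimension, values to ~0.85) plus a smoothed Gaussian texture, clipped to
  [0, 1]; the "brain" (template > 0.1) covers 30–70% of voxels.
- **Atrophy signal.** `n_signal_clusters` non-overlapping spheres (radius
  max(2, min_dim/10) voxels) placed inside the brain via a distance
  transform, each a negative parabolic bump of peak magnitude
  `effect_scale` = 0.004 GM units per year of effective age.
- **Volumes.** `clip(template + weight_map·(age + bag − age_ref) + ε, 0, 1)`
  with ε i.i.d. Gaussian (SD `noise_sd` = 0.05 before smoothing) smoothed to
  3 voxels FWHM for realistic spatial autocorrelation. Ages are uniform on
  the configured ranges (training 55–90, target 67–90; uniform is the
  simplest shape that exposes regression-to-the-mean for the correction
  test). The subject-level true gap `bag` ~ N(0, 2.9²) years, centered; the
  2.9-year SD was chosen once so that tertile cuts of a N(0.5, 2.9)-like gap
  distribution land near the printed −0.75/+1.75 reference values.
- **Phenotypes.** Covariates (sex, 5-level center-race, smoking, education,
  hypertension, diabetes, BMI, intracranial volume) are drawn independently
  of the gap at roughly the emulated cohort's marginals. Cognitive status
  comes from a logistic latent with slope 0.35 per BAG-year, thresholded at
  the latent's empirical 63% / 95% quantiles (the ≈63/32/5 CN/MCI/dementia
  mix). Gait time, low grip strength, and the four disease indicators load
  positively on the gap.
- **Mortality.** Exponential survival with log-hazard equal to the
  tertile-of-true-gap log hazard ratios (defaults 0.4 and 0.6 vs the highest
  tertile) over a baseline of 0.035/year, which reproduces the emulated
  study's ~19% death fraction over ~8 years of follow-up. Baseline dates are
  uniform over mid-2011–mid-2013; administrative censoring is site-specific
  (2017-12-31 for Jackson, 2019-12-31 elsewhere), and deaths are labelled
  CNS with probability `p_cns_death` = 0.15, independent of tertile.
- **Proteins.** analyte_j = γ_j·bag + small age/sex loadings + N(0, 1),
  with γ_j = ±`protein_effect_sd` for `n_true_proteins` designated analytes
  (defaults 33 of 5,284) and zero otherwise; a `qc_fail_fraction`
  (default 407/5284) of analytes is flagged as failing QC, reproducing the
  5,284 → 4,877 panel reduction.

**What the generator does not emulate:** scanner/site effects and
harmonization, registration or segmentation error, non-uniform age
distributions, aptamer cross-reactivity or batch structure, informative
censoring, and covariate-outcome confounding (covariates are independent of
the hazard by construction). A green recovery test therefore establishes
that the estimators are correct *under the stated generating model*, not
that they are robust to real-data artifacts.

## 6. Determinism and seeds

Every stage seed is derived from the global seed as
`sha256("{seed}:{stage}") mod 2^31`, so stages are individually
reproducible and two runs with the same config and seed produce
byte-identical CSVs (verified at the suite level). Result CSVs are written
with `%.17g` floats so the round-trip is exact.

## 7. Known limitations

- The cause-specific competing-risk model estimates cause-specific hazards;
  it does not provide cumulative-incidence (Fine–Gray) estimates.
- LS-mean covariate weighting uses overall sample means/proportions; other
  weighting schemes (e.g. equal-cell) are not implemented.
- The elastic-net CV curves inherit scikit-learn's duality-gap stopping
  rule; with `cv_tol` loosened, the selected λ can shift by one grid point
  between tolerance settings (never between runs at fixed settings).
- Desk-scale grids (≤ 32³) keep the voxel count in the low tens of
  thousands; nothing in the code limits larger grids, but runtimes grow
  linearly in voxels × folds × repeats × grid length.
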