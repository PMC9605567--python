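# Methods

## Normative model

Each ROI's volume is modeled on the log10 scale as a linear function of
subject covariates over a cognitively normal (NC) reference cohort:

    log10 V_ij = β0_j + β_j · x_i + ε_ij,   ε_ij ~ N(0, σ²_j)

The log transform makes multiplicative volume differences additive and
stabilizes variance across ROIs spanning ~1.5 decades of volume. The
covariate row can contain, in any order: age in years, scanner field
strength (binary, 0 = 3 T reference, 1 = 1.5 T), sex (0 = female,
1 = male), and log10 eTIV. Four conventional subsets are exposed as
variants (a) age; (b) age + field; (c) + log10 eTIV; (d) + sex. Variant
(d) is the default: it is the fullest harmonization and the one evaluated
throughout the test suite. One pooled model is fitted over the whole NC
reference (both field strengths together); the field-strength covariate
carries the between-scanner offset, which is what makes pooling coherent.
Field strength is deliberately the only scanner descriptor: finer
covariates (vendor, coil, protocol) multiply without bound in clinical
data, and a binary field covariate keeps the reference model applicable to
scans from unseen scanner models.

Fitting is per-ROI ordinary least squares with a shared design matrix,
solved jointly for all ROIs by `numpy.linalg.lstsq` (statsmodels fits one
response at a time; with a common design, multi-response least squares is
a single solve — statsmodels.OLS serves as the independent cross-check in
the tests instead). The residual variance is the unbiased estimate
σ̂²_j = SSE_j/(N − p − 1). Constant or collinear covariates (e.g. field
strength in a single-scanner cohort) abort the fit with a message naming
the covariate to drop — silently deleting a covariate would corrupt
comparability between models that claim the same specification.

## The harmonized Z-score

A subject with covariate row x and volume V in ROI j scores

    Z = (log10 V − β0_j − β_j·x) / sqrt( (1 + 1/N + q) σ̂²_j ),
    q = (x − x̄)ᵀ Σ⁻¹ (x − x̄) / (N − 1)

where x̄ and Σ are the mean and sample covariance (divisor N − 1) of the
reference covariate rows. Interpreting Σ as the sample covariance makes
1/N + q identically the hat-matrix leverage x₀ᵀ(XᵀX)⁻¹x₀ of the
intercept-augmented design — an identity the test suite asserts to 1e-10
on random designs — so Z is the standard studentized prediction residual:
its sampling distribution for a held-out normal subject is Student t with
N − p − 1 degrees of freedom, indistinguishable from N(0,1) at the
reference sizes in scope (N ≳ 10³). The same denominator is used for
in-reference and new subjects; consequently the in-sample Z variance sits
slightly below 1 (the in-sample residual has variance σ²(1 − h) while the
denominator uses σ²(1 + h)), which the calibration tests bound at
[0.85, 1.05] rather than [0.9, 1.1]. Singular Σ is an error, never
regularized: it means the covariate specification itself is degenerate.

Z < −2 (strict) classifies an ROI as significantly atrophied; the
boundary value −2 itself is classified normal, an arbitrary but
documented tie-break.

## Outlier QC

Reference cohorts contain segmentation failures. After the initial fit,
each ROI's reference Z vector is screened with the two-sided
Smirnov–Grubbs test at α = 0.05: G = max|Z − mean|/sd against the
critical value ((n−1)/√n)·sqrt(t²/(n−2+t²)), t the upper α/(2n) t-quantile
on n − 2 df. The most extreme point is removed while G exceeds the
critical value (ties broken at the lowest index; iteration stops with a
recorded warning below 3 remaining values). Exclusions are per-ROI, never
whole-subject — a subject with a failed hippocampal segmentation still
supports every other ROI's model. Affected ROIs are then refitted on
their retained subjects with x̄, Σ and N recomputed per ROI, and Z-scores
are recomputed once (exclude → refit → rescore). A single cycle is the
default; `max_cycles` allows iterating to convergence, and the
no-new-outlier case is a fixed point. ROIs whose residual variance is at
rounding level (σ̂² ≤ 1e-20) are skipped: their "residuals" are float
noise, not measurements. Two-sided screening is used because both atrophy
(under-segmentation) and enlargement (leakage) artifacts occur.

## Evaluation metrics

* **Harmonization (KS).** Per ROI, a two-sample Kolmogorov–Smirnov test
  between the Z distributions of the two levels of a binary covariate
  (field strength or sex) in NC subjects. Asymptotic p-values (exact
  enumeration below combined n = 25); rejections counted per-ROI at
  α = 0.05 with no multiple-testing correction, so ~5% rejections is the
  expected noise floor for perfect harmonization.
* **Discrimination (ROC/AUC).** Orientation is fixed as "lower Z =
  disease": AUC = P(Z_disease < Z_control) + ½P(ties), computed as the
  normalized Mann–Whitney U. Balanced accuracy (sensitivity +
  specificity)/2 is maximized over thresholds at midpoints of pooled
  sorted unique scores plus one threshold below and above everything (so
  the degenerate 0.5 rules are reachable); the lowest optimal threshold
  is reported. This in-sample optimum is optimistic relative to held-out
  use, and is labeled as such.
* **Age trend.** Simple OLS of log10 volume on age with the pointwise
  95% mean-response CI band (statsmodels prediction intervals).
* **KDEF.** Gaussian kernel density with Silverman's bandwidth
  (`scipy.stats.gaussian_kde`); the default grid spans the data ± 5
  bandwidths so the density integrates to 1 within 1%.

## Synthetic cohorts

The generator draws subjects group-by-group and produces volumes from
exactly the generative form the model fits, plus group-level disease
shifts. Demographic defaults emulate a mixed-site aging study built
around a large 3 T NC reference and a 1.5 T evaluation set:

| group | n | age mean (SD) | males | field |
|---|---|---|---|---|
| NC 3 T | 1089 | 58.5 (14.3) | 375 | 3 T |
| NC 1.5 T | 146 | 67.6 (5.66) | 68 | 1.5 T |
| sMCI | 102 | 72.8 (6.10) | 57 | 1.5 T |
| pMCI | 112 | 73.0 (5.54) | 47 | 1.5 T |
| AD | 147 | 73.5 (6.60) | 63 | 1.5 T |

Ages are truncated-normal with a floor of 40 years (the linear age model
is not meant to extrapolate to young brains); sex is Bernoulli; eTIV is
sex-conditional normal (female 1.45×10⁶ ± 1.1×10⁵ mm³, male 1.60×10⁶ ±
1.2×10⁵ mm³, floored at 8×10⁵). Per-ROI coefficients have no published
values and are invented, chosen once as plausible: age slope −0.001
log10/yr (≈ −0.23%/yr), field offset −0.02 log10 (≈ −4.5% on 1.5 T), sex
offset +0.01, eTIV log-log slope 0.7, residual SD 0.05 log10 units.
Twenty named ROIs anchor at typical volumes (hippocampus ≈ 3.5 cm³,
amygdala ≈ 1.6 cm³, …); disease shifts are expressed as Z-scale effects
via shift = δ·σ (helper `z_effect_to_log10_shift`) and graded to mirror
the usual medial-temporal ordering: AD hippocampus δ = 2.5 (binormal AUC
limit Φ(2.5/√2) ≈ 0.96), weaker in amygdala/temporal ROIs, weak pMCI and
minimal sMCI effects. A truth record retains every parameter for recovery
tests.

What the simulator does *not* emulate — and hence what passing tests do
not establish about real data: non-Gaussian residuals and heavy-tailed
segmentation error, nonlinear age effects, scanner effects beyond a pure
mean offset (variance or covariance differences between field strengths),
spatial correlation between ROIs, and longitudinal structure. Tests
establish that the estimator is correct and calibrated under its own
assumptions, not that those assumptions hold for any given dataset.

## Numerical and validation choices

* Volumes must be strictly positive and finite; NaN marks a missing cell,
  rejected in reference fitting and masked (`missing`) in scoring.
* Leverage q is clamped at 0 against rounding; near-singular Σ
  (condition number > 1e12) raises with the collinear covariates named.
* σ̂² = 0 with a non-zero residual is an error (degenerate model); with a
  zero residual, Z = 0.
* Model JSON stores floats at repr precision, so save/load round-trips
  bitwise and rescoring is exactly reproducible.
* Validation problem sizes (chosen to give each Monte-Carlo estimate a
  standard error well inside the asserted band): hat identity on 100
  random designs; calibration pooled over 20 cohorts of N = 1000/500
  held-out; harmonization efficacy on one 120-ROI cohort of 1235 NC;
  AUC closed form as the mean of 50 replicates at 150 vs 150 (a single
  replicate has SE ≈ 0.03 at δ = 1, too noisy to test a ±0.03 band);
  Grubbs rates over 500 trials at n = 146; coefficient recovery over 200
  replicates at N = 1000, asserting each coefficient within 3 SE in
  ≥ 95% of replicates (the theoretical rate is ≈ 99.7% per coefficient).

## Limitations

* The leverage reading of the Z denominator is an interpretive choice
  (documented and tested via the hat-matrix identity); other covariance
  conventions would rescale q by O(1/N) factors.
* Balanced accuracies use an in-sample optimal threshold and overstate
  held-out accuracy.
* Per-ROI univariate Z only; multivariate combination across ROIs is out
  of scope.
* The field-strength covariate captures a mean offset per ROI; it cannot
  correct scanner effects that alter residual variance.
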