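# harmoz — harmonized Z-scores for regional brain volumes

Regional brain volumes measured by MRI morphometry are confounded by age,
sex, head size, and scanner field strength (1.5 T vs 3 T systematically
shift volumetric estimates). This makes raw volumes — and naive Z-scores
against a normal database — unreliable for detecting atrophy in
neurodegenerative disease, especially when the patient was scanned on
different hardware than the reference cohort. `harmoz` implements a
normative-modeling approach for researchers and imaging analysts who have
per-subject ROI volume tables (e.g. from an atlas-based segmentation
pipeline) and want atrophy Z-scores that are comparable across sites and
demographics.

## The model

For ROI *j* and subject *i*, a general linear model is fitted by ordinary
least squares on a cognitively normal (NC) reference cohort:

    log10 V_ij = β0_j + β_j · x_i + ε_ij

where the covariate row x_i contains age (years), field strength
(0 = 3 T, 1 = 1.5 T), sex (0 = female, 1 = male) and log10 eTIV (estimated
total intracranial volume, mm³) — or any ordered subset (the conventional
variants: (a) age; (b) + field; (c) + eTIV; (d) + sex, the default). A
subject is scored with the prediction-studentized residual

    Z_ij = ε_ij / sqrt( (1 + 1/N + q_i) · σ̂²_j ),
    q_i  = (x_i − x̄)ᵀ Σ⁻¹ (x_i − x̄) / (N − 1)

with σ̂²_j = SSE/(N − p − 1) the unbiased residual variance, x̄ and Σ the
mean and sample covariance of the N reference covariate rows. The quantity
1/N + q_i is exactly the hat-matrix leverage of x_i in the
intercept-augmented design, so Z_ij is the classical studentized residual
for predicting a new observation: approximately standard normal for a
held-out normal subject whatever their covariates. Z < −2 flags
significant atrophy.

The reference fit is protected by a per-ROI iterative Smirnov–Grubbs
outlier screen (two-sided, α = 0.05) on the reference Z-scores: flagged
subjects are excluded for that ROI only, the ROI is refitted, and Z-scores
are recomputed. Harmonization quality is evaluated with per-ROI two-sample
Kolmogorov–Smirnov tests between covariate subgroups (1.5 T vs 3 T, male
vs female); discriminative power with ROC AUC (equivalently the normalized
Mann–Whitney U, oriented so lower Z = disease) and balanced accuracy at
the in-sample optimal threshold. A synthetic-cohort generator reproduces
the statistical structure the model assumes (mixed-field-strength NC
reference, age-related atrophy, field/sex/eTIV effects, graded
medial-temporal disease shifts) so that the full pipeline is testable
end-to-end without any data download.

## Worked example

```sh
python examples/01_simulate_fit_score.py
```

```
reference fit: N=1235 NC subjects, 20 ROIs
Grubbs QC excluded 2 ROI-level outliers
NC reference Z: mean=+0.000, var=0.992  (target ~0, ~1)
subject AD_0001: right hippocampus Z=-2.97 -> atrophied
```

The NC Z-scores are calibrated (mean ≈ 0, variance ≈ 1, the slight
variance deficit being the usual in-sample effect of the prediction-error
denominator), and the simulated AD subject's hippocampal Z of −2.97 falls
below the −2 atrophy threshold. The other examples demonstrate the KS
harmonization check (`02`), ROI ranking by AUC for AD vs NC and pMCI vs
sMCI (`03` — simulated hippocampal AUC ≈ 0.96 for AD vs NC and ≈ 0.6–0.7
for pMCI vs sMCI), and age-trend/density summaries (`04`).

The same pipeline is available from the shell:

```sh
harmoz simulate --seed 42 --out-volumes v.csv --out-metadata m.csv
harmoz fit      --volumes v.csv --metadata m.csv --out model.json
harmoz score    --model model.json --volumes v.csv --metadata m.csv --out z.csv
harmoz evaluate --zscores z.csv --metadata m.csv \
                --compare AD:NC --split-by field_strength --out report.json
```

Real data enters as a wide CSV of ROI volumes (first column `subject_id`)
plus a metadata CSV (`subject_id,age,sex,field_strength,etiv[,group]`;
textual codes like `F`/`M` and `3T`/`1.5T` are accepted).

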