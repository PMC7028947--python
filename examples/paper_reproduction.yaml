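# Analysis profile pinning the published thresholds and point mapping:
# germline filter at 0.1% population frequency, NLR >= 5 / SNV >= 10 /
# ECOG >= 1 dichotomizations with the cohort's median SNV split pinned at
# 8, univariable screen at p <= 0.05 with stay criterion <= 0.10, the
# three-factor points {+1, -2.5, -2, +3} classifying benefit at score
# >= -1, and the progression-free-survival risk cutoffs -0.29 / 1.54.
schema: ucipred-profile/1
af_threshold: 0.001
rules:
  nlr_cut: 5.0
  snv_cut: 10
  snv_median_cut: 8
  cnv_cut: 0
  ecog_cut: 1
model:
  family: logistic
  alasso_gamma: 1.0
  tuning: bic
  stay_alpha: 0.10
  univariable_alpha: 0.05
points:
  intercept: 1.0
  visceral_mets: -2.5
  nlr_ge5: -2.0
  snv_ge10: 3.0
score_threshold: -1.0
prognostic_cutoffs: [-0.29, 1.54]
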