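# ERASL-post: postoperative risk score for early HCC recurrence; adds the
# microvascular-invasion (MVI) indicator to the preoperative covariates.
#
# Coefficients and fixed cut-points transcribed from the derivation
# publication (Chan et al. 2018) as reproduced in the validation
# literature; verify against the original before any clinical use.
# The baseline_survival table is a SYNTHETIC stand-in (see erasl_pre.yaml).
name: erasl_post
source: >-
  Transcribed from Chan et al. 2018 (derivation publication); baseline
  survival table synthetic (see erasl_pre.yaml header comment).
terms:
  - {covariate: male, transform: identity, coefficient: 0.732}
  - {covariate: albi_grade_23, transform: identity, coefficient: 0.294}
  - {covariate: afp, transform: ln, coefficient: 0.089}
  - {covariate: tumor_size, transform: identity, coefficient: 0.093}
  - {covariate: multiple_tumors, transform: identity, coefficient: 0.799}
  - {covariate: mvi, transform: identity, coefficient: 0.855}
albi:
  bilirubin_coef: 0.66
  albumin_coef: -0.085
  cut_grade_1_2: -2.60
  cut_grade_2_3: -1.39
grouping:
  fixed: [2.332, 3.445]
  percentiles: [50.0, 85.0]
baseline_survival:
  - [0, 1.000000]
  - [3, 0.991332]
  - [6, 0.983886]
  - [9, 0.976872]
  - [12, 0.970140]
  - [15, 0.963620]
  - [18, 0.957274]
  - [21, 0.951073]
  - [24, 0.945000]
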