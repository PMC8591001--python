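# ERASL-pre: preoperative risk score for early HCC recurrence after resection.
#
# Coefficients and fixed cut-points transcribed from the derivation
# publication (Chan et al. 2018) as reproduced in the validation
# literature; verify against the original before any clinical use.
#
# The baseline_survival table is a SYNTHETIC stand-in for the derivation
# model's baseline curve (which is not republished here): a Weibull curve
# S0(t) = exp(-0.00324*t^0.9) anchored at S0(24 months) = 0.945, chosen so
# that typical score values (LP around 2) imply roughly 35-42% two-year
# recurrence, matching the published cohort margins. Replace it with the
# true derivation table to reproduce absolute predictions.
name: erasl_pre
source: >-
  Transcribed from Chan et al. 2018 (derivation publication); baseline
  survival table synthetic (see header comment).
terms:
  - {covariate: male, transform: identity, coefficient: 0.818}
  - {covariate: albi_grade_23, transform: identity, coefficient: 0.447}
  - {covariate: afp, transform: ln, coefficient: 0.100}
  - {covariate: tumor_size, transform: identity, coefficient: 0.112}
  - {covariate: multiple_tumors, transform: identity, coefficient: 0.792}
albi:
  bilirubin_coef: 0.66
  albumin_coef: -0.085
  cut_grade_1_2: -2.60
  cut_grade_2_3: -1.39
grouping:
  fixed: [2.558, 3.521]
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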