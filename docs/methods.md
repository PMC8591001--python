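# Methods

This note documents the statistical procedures `survalid` implements, the
defaults it ships, the numerical choices that are not forced by the
definitions, and what the synthetic cohorts do and do not establish.

## Setting

A derivation study publishes a prognostic score for right-censored
event times: a linear predictor LP = Σⱼ βⱼ·fⱼ(xⱼ) with fixed weights,
cut-points splitting the LP scale into low / intermediate / high risk
groups, and a baseline survival curve S₀(t) such that
S(t | LP) = S₀(t)^exp(LP). The shipped configurations instantiate the
ERASL-pre and ERASL-post scores for early HCC recurrence within 24 months
of liver resection; outcome times are months since surgery, with patients
censored at their last radiologic examination and follow-up
administratively truncated at 24 months. Validation asks three questions
of a new cohort: are the relative risks right (misspecification), does the
score rank patients correctly (discrimination), and do the absolute
predicted probabilities match observation (calibration)?

## Cohort handling

Patients with any missing value among the score's covariates are excluded
(complete-case analysis; the exclusion summary counts missingness per
field). No imputation is performed, matching standard practice for these
scores. Truncation maps any outcome beyond the horizon to (horizon,
censored); it is idempotent and commutes with the complete-case filter.
Missing values are NaN sentinels, distinct from zero; AFP values at or
below the assay floor are clamped to 0.1 μg/L before the log transform.
Time is real-valued months (dates, if present upstream, convert at
30.4375 days/month).

## Risk scoring

The ALBI liver-function grade is 0.66·log₁₀(bilirubin μmol/L) −
0.085·albumin g/L with grade cut-points −2.60 and −1.39; both boundaries
resolve downward (score ≤ cut-point keeps the lower grade), and the same
≤ convention applies to the LP risk-group cut-points. In-sample grouping
uses the empirical 50th and 85th percentiles of the cohort's own LPs
(linear interpolation between order statistics, `numpy.percentile`
default), which by construction yields 50/35/15% groups on distinct
scores; fixed grouping uses the published cut-points. The shipped ERASL
coefficient values are transcription, not derivation — the YAML headers
state their provenance and that the baseline survival table is a synthetic
stand-in (a Weibull curve anchored at S₀(24 m) = 0.945 chosen so typical
LPs imply a 35–42% two-year recurrence fraction). Users validating against
the true derivation model must substitute the published table.

## Survival engine

All fitters are written from definition because the validation methodology
requires an offset — a term with coefficient fixed at 1 in the Cox partial
likelihood — which the common Python survival fitters do not expose. All
are deterministic: no random initialization, fixed starting points.

**Cox proportional hazards.** Efron tie correction (the default of the R
survival ecosystem, and exact when ties are absent). Damped Newton
iterations from β = 0 with step-halving whenever a step would decrease the
partial likelihood; convergence on both parameter change (1e-9) and
gradient norm. The covariance is the inverse observed information; Wald
95% intervals are estimate ± 1.96·SE, exponentiated for hazard ratios.
The Breslow baseline cumulative hazard is anchored at covariate value 0
and offset 0 — no mean-centering — so baselines stay on the published
score scale. Singular information (constant column, separation) raises an
error naming the suspect column. Unit tests pin the fitter to a
brute-force grid maximization of the written-out partial likelihood and to
lifelines.

**Kaplan–Meier.** Product-limit with Greenwood variance; subjects censored
at an event time remain in that time's risk set. Pointwise confidence
bands use the complementary log-log transform; the median CI is the first
crossing of 0.5 by each band, with "not reached" (NR) as an ordinary
value, not an error.

**Weibull AFT.** ln T = μ + γ·lp + σW with W standard minimum
extreme-value, right-censored likelihood, σ parameterized on the log
scale. BFGS with analytic gradient from a method-of-moments start
(μ₀ = mean log event time, σ₀ = √6/π × its SD), polished by Newton steps
on a central-difference Hessian; relative tolerance 1e-9, 200 iterations
max. The covariance of (μ, γ, log σ) is the inverse observed information.
The exponent e^z is clipped at e^60 to keep line-search excursions finite;
the clip is inactive at any reasonable optimum.

## Discrimination

* **Harrell's C**: over pairs whose ordering is identifiable under right
  censoring (the smaller time is an event and times differ), the fraction
  where the higher score has the shorter time; score ties count ½.
* **Gönen–Heller K**: mean over unordered pairs of 1/(1 + exp(−|Δlp|)),
  the PH-model-implied concordance probability. It uses scores only, so
  censoring never enters; by construction K ≥ ½ and K is invariant under
  negation of the scores (unlike C, which maps to 1 − C).
* **Royston–Sauerbrei D and R²_D**: scores are ranked, ranks mapped to
  expected normal order statistics (Blom: Φ⁻¹((r − 3/8)/(n + 1/4))),
  scaled by κ = √(8/π); D is the Cox coefficient of that covariate and
  R²_D = (D²/κ²)/(π²/6 + D²/κ²). Rank-based, hence invariant to
  increasing transforms of the score; D itself is scale-defined.
* **tdAUC**: inverse-probability-of-censoring-weighted cumulative/dynamic
  AUC(t) — cases are events at or before t weighted by 1/Ĝ(Tᵢ⁻) with Ĝ
  the Kaplan–Meier of the censoring distribution, controls are subjects
  beyond t — integrated over the window against the event-time
  distribution (−dŜ(t) weights). This is the Uno-style estimator; tests
  pin it to scikit-survival's implementation at machine precision. Which
  IPCW variant a given historical analysis used is rarely stated, so the
  estimator is isolated behind one function. For cohorts with more than 60
  distinct event times the evaluation grid is thinned to 60
  quantile-spaced times; the −dŜ weighting keeps the integral consistent.

Uncertainty for all four is a patient-level nonparametric bootstrap
(default B = 200, matching how such validations conventionally report
SEs), with normal-approximation intervals estimate ± 1.96·SE — chosen over
percentile intervals because the quantity conventionally reported is the
bootstrap SE. Replicates on which a statistic is undefined are skipped and
counted; more than 10% failures is an error.

## Calibration

The calibration slope is the Cox coefficient of the LP as sole covariate.
The Weibull calibration model transforms each time by the derivation
baseline, T* = H₀(T) = −ln S₀(T), and fits the AFT above to (ln T*, LP).
Under a perfectly transportable model H₀(T)·exp(LP) is unit exponential,
so (μ, γ, σ) = (0, −1, 1) — note γ = −1, not 0: the AFT sign convention
makes the perfect-calibration reference point (0, −1, 1), which is also
why fitted γ values are negative, with attenuation (|effects|
overstated by the score) appearing as γ ∈ (−1, 0). The summary reports
Wald tests against the perfect-calibration point for all three parameters
and retains the conventional γ ≠ 0 contrast for comparability with
published reports; which null a user should privilege is a substantive
choice the package does not adjudicate.

S₀ between knots is interpolated linearly in ln(−ln S₀) versus ln t —
exact for Weibull baselines; below the first positive knot the first
segment extends (H₀(0) = 0), beyond the last knot evaluation raises unless
a flat extension is requested. T* is floored at 1e-10 before logs. The
pipeline uses the configured (derivation) baseline throughout; refitting
the baseline per cohort is possible by editing the config, a deliberate
non-default.

Two plot types, each emitted with its underlying CSV so every number is
regenerable without image comparison: per-group Kaplan–Meier curves with
the mean of per-patient predicted curves S₀(t)^exp(LP) (and, when a
calibration fit is supplied, the mean recalibrated curves, dashed), and
predicted-vs-observed points at 12 and 24 months against the 45° line with
cloglog CI whiskers. Empty groups are dropped rather than fatal — real
validation cohorts can put only a handful of patients in the high-risk
group.

## Model updating

Extension tests fit one candidate covariate with the LP as unit offset;
the coefficient is the difference between derivation and validation log
hazard ratios. The joint misspecification test frees all score covariates
at once and compares against the offset-only null by likelihood ratio
(df = number of covariates). Forward selection starts from the LP-only
model and repeatedly admits the smallest-p candidate below the entry
threshold (default 0.05, configurable); the LP stays an offset by default
(`lp_mode="free"` re-estimates it), ties in p break by candidate name so
the trace is invariant to column order. Selection stops on information
criteria is deliberately not offered.

## Synthetic cohorts

The generator emulates published cohort margins: Bernoulli gender /
MVI / hepatitis indicators, normal albumin, log-normal bilirubin, AFP and
tumor size parameterized by median and IQR (closed form: μ = ln median,
σ = ln(q₃/q₁)/(2·z₀.₇₅) — reproducing the median and the IQR ratio
exactly), and tumor count 1 + Bernoulli(p)·(1 + Poisson(0.8)). The
`rotterdam_like` defaults are 70% male, albumin 42 ± 5.8 g/L, bilirubin
10 (7–15) μmol/L, AFP 9 (3–148) μg/L, size 5.9 (3.2–9.6) cm, 21%
multiple, 58% MVI, 25%/15% hepatitis B/C; `okayama_like` uses 79% male,
albumin 40 ± 4.6, bilirubin 12 (9–15), AFP 10 (4–78), size 3.5 (2.3–6.0),
29% multiple, 29% MVI, 27%/47% hepatitis B/C.

Event times are linked to the score itself: in `ph` mode
T = H₀⁻¹(E/exp(γ_sim·LP)) with E unit exponential, so at γ_sim = 1 the
cohort is perfectly calibrated to the scored model *by construction* —
the keystone cross-module check, since the Weibull calibration must then
recover (0, −1, 1); γ_sim < 1 produces the attenuation seen in real
validations. `weibull_aft` mode draws ln T* = μ + γ·LP + σW directly.
Censoring is independent Uniform(0, 120 months) — about 20% censored
before the 24-month horizon, matching the reported ~80% two-year
follow-up — plus administrative truncation at 24 months; with the shipped
baseline this yields a ~35% observed two-year event fraction. One integer
seed drives named per-field sub-streams, so adding a field never perturbs
existing draws and identical (config, seed) gives byte-identical CSVs.

What the synthetic cohorts do **not** emulate: between-covariate
correlation (an optional logistic MVI-on-size link exists but defaults
off), non-MCAR missingness, measurement error, informative censoring, and
any true difference between the shipped coefficients and a population's
actual hazards. Passing tests therefore demonstrate that the machinery is
correct — estimators match their oracles, recovery is unbiased under the
assumed laws — not that any particular score is valid for real patients.

## Problem sizes and determinism

Simulation-based tests use cohorts of 150–4000 patients and 6–200
replicates per claim, with 3-Monte-Carlo-SE tolerances; the acceptance
script uses 50 replicates of n = 2000 for calibration recovery, 500 null
replicates for the size of the joint LR test, and n = 10 000 for the
margin-fidelity checks. Every stochastic path — simulation, bootstrap,
acceptance — flows from a single integer seed; fitters themselves are
deterministic, so a fixed (cohort, config, seed) reproduces every report
byte for byte.

## Known limitations

Competing risks, time-varying coefficients, stratified baselines and
frailties are out of scope. The Cox engine targets small covariate counts
(p ≲ 20) on cohorts up to tens of thousands of rows. Bootstrap intervals
are normal-theory; for statistics with skewed resampling distributions at
small n (notably R²_D near 0) percentile intervals would differ. The
tdAUC variant is one of several in use; results on real data can differ
across variants by more than their SEs.
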