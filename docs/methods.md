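# Methods

`pointrisk` implements the construction and validation of a point-based
risk score for end-stage renal disease (ESRD) in type 2 diabetes: a Cox
proportional-hazards model is fitted to a cohort, converted to integer
points per risk-factor category in the Framingham style, and the total
score is mapped to absolute 3-, 5- and 8-year risk. The package ships the
published score tables as fixtures and a synthetic-cohort generator so the
whole pipeline is testable without access to the original claims data.

## The model

Survival is modelled as proportional hazards over eleven risk factors:
age (continuous, per year), gender, age of diabetes onset (<45 / ≥45),
serum creatinine (<2.0 / 2.0–4.0 / >4.0 mg/dL), visit-to-visit variability
of HbA1c and of systolic blood pressure (tertiles of the adjusted CV),
diabetes retinopathy, albuminuria, anti-diabetes medication class, combined
blood-pressure/anti-hypertensive-medication status (8 levels) and combined
total-cholesterol/lipid-medication status (6 levels). The partial
likelihood is maximised with Efron tie handling (delegated to lifelines;
heavy ties are expected in coarsely recorded follow-up). Baseline survival
S0(t) is the Breslow-type estimate evaluated at the covariate means, so the
absolute risk of a subject with covariates x is

    p(x, t) = 1 − S0(t) ^ exp( Σ βᵢ (xᵢ − x̄ᵢ) ).

Death and loss to follow-up are treated as censoring; competing risks are
out of scope.

### Variability metric

For each subject with n ≥ 2 first-year visits,
`raw_cv = 100·SD/mean` (sample SD, n−1 denominator) and
`adjusted_cv = raw_cv / sqrt(n/(n−1))`, removing the small-n inflation of
the CV. Subjects with fewer than two visits carry a missing CV, which is
the input to the imputation stage rather than an error. Tertile bands are
half-open on the left (`[0,c1), [c1,c2), [c2,∞)`); a value exactly on a
boundary goes to the upper band, a convention chosen because the published
bands print as contiguous "<c₁ / c₁–c₂ / >c₂". Two cutpoint presets are
kept for the HbA1c CV — 17.3/34.5 (incidence presentation) and 8.5/17.5
(score presentation) — because the two published tables use different
boundaries; they are encoded side by side rather than reconciled. The SD
denominator (n−1) is a package choice; the source does not specify it.

### Model building

Variable selection follows the screen-then-prune recipe: a univariable
likelihood-ratio screen at α = 0.25, a variance-inflation collinearity
check (threshold 10; the specific diagnostic is a package choice), then
backward elimination of whole factor blocks by likelihood-ratio test at
α = 0.05. Factors are kept or dropped as blocks because the published
model retains complete factors. The proportional-hazards assumption is
probed two ways: data for the log(−log S) plot are exported per stratum,
and the model is refitted with follow-up administratively censored at 3, 5
and 8 years. A coefficient is flagged when its spread across horizons
exceeds 0.5 in absolute value **and** 50% of its mean magnitude — both
conditions, so that Monte-Carlo noise on near-zero coefficients does not
flag spuriously. The published acceptance rule is qualitative; these
tolerances are the package's quantitative rendering and are configurable.

## Point derivation

The seven Framingham steps reduce to: fix the constant B (log-hazard worth
one point) as five years of age effect, B = 5·β_age; give each category j
of factor i the representative value W_ij (interval midpoint for bounded
continuous categories) and reference value W_iREF; then

    points_ij = round( βᵢ (W_ij − W_iREF) / B ),

rounding half away from zero. Indicator-coded categories have W ∈ {0,1},
so their points are round(β_category/B). Age is categorised in 5-year bins
from 30–34 to 80–84 with midpoints 32…82 and reference 40–44, which makes
the age points exactly (midpoint − 42)/5 = −2 … 8. The total score maps to
risk through

    p(P, t) = 1 − S0(t) ^ exp(B·P + c),   c = Σ βᵢ W_iREF − Σ βᵢ x̄ᵢ.

Only the product S0(t)^exp(c) is identified when a system is rebuilt from
published points alone; the packaged reconstruction therefore sets c = 0
and solves S0(t) from one anchor row of the published risk table (the
20–22 bin, lower edge) per horizon.

### Printed-precision caveat

The published coefficients carry two decimals, so no single B reproduces
every printed point. The regression anchor B = 2.57/29 (the creatinine
2.0–4.0 row: β = 2.57 → 29 points) reproduces 23 of the 25 scored category
rows exactly; the HbA1c-CV > 17.5 row (computed 5, printed 6) and the
insulin-plus-oral row (computed 1, printed 2) are off by one under any
printed-precision B and are whitelisted with tolerance ±1. The encoded
printed system spans totals −16 … 97.

## Validation metrics

* **Discrimination.** At horizon t the outcome is binary "event by t";
  subjects censored before t without an event are excluded (default) or
  IPCW-weighted (sensitivity option). The AUC is the Mann–Whitney
  statistic with a DeLong-type variance for the 95% CI.
* **Calibration.** Hosmer–Lemeshow over deciles of predicted risk,
  χ² = Σ (O−E)²/(E(1−E/n_g)); groups with zero expected events are merged.
  The χ² reference has groups−2 degrees of freedom when the risks were
  estimated on the data being tested (the classical setting, the default)
  and the full `groups` degrees of freedom when the risks are externally
  fixed — the g−2 reference is measurably anti-conservative in that case.
  Calibration-in-the-large and the calibration slope are measured on the
  complementary-log-log scale of the predicted risk at the 5-year horizon
  by default (the source names neither scale nor horizon; cloglog is the
  natural scale for a survival risk). The slope comes from a free binomial
  GLM fit, the intercept from the same GLM with the slope fixed at 1.
  Because the horizon outcome excludes censored-before-t subjects — which
  keeps every case but only the still-observed controls — the calibration
  GLM is weighted by inverse-probability-of-censoring weights; without the
  weights the intercept is biased upward by roughly the log of the inverse
  censoring survival at t.
* **Internal validation.** Bootstrap optimism correction: refit on each
  resample, evaluate the calibration pair on the resample and on the
  original data, subtract the mean difference from the apparent values;
  non-convergent replicates are skipped and counted. The mean absolute
  bootstrap-minus-original difference is reported as the error measure.
* **Descriptives.** Incidence rates are 1000·events/person-years;
  standardized differences use the pooled-SD formulas for means and
  proportions; the derivation/validation split is simple random at 2:1
  with the derivation set taking ⌈2n/3⌉ subjects (24,104 → 16,070/8,034).

## Missing data

Missing CV values are imputed by fully conditional specification: each
target is regressed on age, onset age and diabetes duration plus the other
target, with regression parameters drawn from their approximate posterior
and Gaussian noise added to predictions (plain regression imputation, not
predictive-mean matching, matching the stated imputation method). Five
imputations and five chain iterations are the defaults (the source states
neither count). Pooling uses Rubin's rules: pooled variance = mean
within-imputation variance + (1+1/m)× between-imputation variance.

## Synthetic-data generator

The generator emulates the published cohort's marginal structure:
24,104 subjects; age truncated-normal(61.03, 10.77²) on [30, 84]; each
factor drawn independently at the published category proportions; event
times exponential with hazard λ0·exp(Σβᵢ(xᵢ−x̄ᵢ)) using the published
coefficients; censoring the minimum of a 10-year administrative horizon
and exponential dropout at 0.033/year (mean follow-up ≈ 8.3 years);
λ0 = 0.003984 per person-year, calibrated by bisection on the closed-form
event probability so that ≈5.06% of subjects develop ESRD. Numeric
diabetes-duration and onset-age columns are attached as imputation
predictors. Visit series are built by exact construction: visit values are
standard-normal draws rescaled so the sample mean and SD — hence the
adjusted CV — equal a target drawn uniformly inside the subject's assigned
tertile band.

What the generator deliberately does **not** emulate: correlation between
risk factors (only marginals are published), non-constant baseline hazard,
informative censoring, claims-level artifacts (ICD coding, comorbidity
ascertainment). Passing tests therefore demonstrate the correctness of the
pipeline's arithmetic and its statistical calibration under the assumed
model, not robustness to real-data violations of those assumptions.

## Numerical choices and degenerate inputs

* Cox fits retry once with a damped Newton step (step size 0.25) before
  failing; failures surface a per-column VIF table.
* Baseline survival at a horizon is the step-function value at the largest
  event time ≤ t.
* Rounding of points is half-away-from-zero; table risks are rounded to
  two decimals only at the presentation layer.
* A single-visit subject yields a missing CV, not an exception; an
  all-missing imputation target, a non-positive visit mean, unordered
  tertile cutpoints, B ≤ 0 and person-years ≤ 0 are errors.
* Empty final models in backward elimination are allowed and flagged.
* `risk()` values are clipped to [0, 1]; monotonicity in the score is
  strict until the risk saturates to 1.0 in double precision (total
  scores ≳ 80 at the 8-year horizon).

## Problem sizes used in the shipped checks

Simulation-backed checks run at the sizes that make their Monte-Carlo
error small relative to the asserted tolerance: coefficient coverage uses
100 replicate cohorts of 20,000 subjects; Hosmer–Lemeshow type-I error
uses 200 outcome draws over one 10,000-subject risk profile; bootstrap
calibration uses 60 resamples of a 10,000-subject cohort (the pipeline
default remains 1000 for production use); the fitted-versus-generating
point comparison uses an event-rich cohort (hazard 0.05/year) and checks
categories whose coefficient SE is below B/3, since rarer categories
cannot support a one-point guarantee at any realistic cohort size.

## Known limitations

* Real-cohort performance numbers (AUCs ≈ 0.90/0.86/0.81, bootstrap
  intercept/slope) are not reproducible without the original claims data;
  the package instead verifies the published *derived* tables and the
  statistical properties of the method on synthetic data.
* Two published incidence strata carry a 1–2 person-year rounding slip in
  their margins; the fixtures store the rows as printed.
* One 8-year risk band (score bin 40–41) is typographically unreadable in
  the source and is excluded from reconstruction checks.
* The exact representative values W_iREF used by the original authors are
  not published; the midpoint convention is a package choice.
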