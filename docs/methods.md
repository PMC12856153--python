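# Methods

## Scope and data model

`le8surv` analyses the prognostic association between Life's Essential 8
(LE8) cardiovascular health and two endpoints in an atrial-fibrillation
cohort over a 10-year horizon: all-cause mortality and composite MACE
(first of ischaemic heart disease I20–I25, myocardial infarction
I21–I23, stroke I60/I61/I63/I64, heart failure I50.0/I50.1/I50.9).
ICD-10 range patterns and bare three-character codes include decimal
children; enumerated codes with decimals match exactly.  Times are
stored in days and analysed in years (365.25 d/y); follow-up is
truncated administratively at the horizon.  Analyses are complete-case:
rows missing any LE8 input are dropped with counts logged; no imputation
is provided.

## LE8 scoring

Each component is scored 0–100 from a versioned plain-text band table
(`src/le8surv/data/le8_rubric_v1.csv`) following the published AHA
rubric, and the composite is the unweighted mean of the eight
components.  Choices that required judgement:

* **Physical activity** arrives as IPAQ-style MET-min/week rather than
  minutes of moderate-to-vigorous activity; the AHA minute cut-points
  are multiplied by 4 MET (150 min → 600 MET-min, etc.).
* **Non-HDL cholesterol** is supplied in mmol/L and converted at
  38.67 mg/dL per mmol/L; **HbA1c** converts IFCC mmol/mol to NGSP % via
  0.09148·IFCC + 2.152, and a participant is scored on the diabetes
  bands if flagged diabetic (type-2 diabetes comorbidity or
  glucose-lowering medication) or if HbA1c ≥ 6.5%.
* **Treatment modifiers**: the rubric applies the AHA −20 deduction for
  antihypertensive and lipid-lowering treatment (floored at 0).
* **Diet** is an adapted nine-item score (processed meat, red meat,
  fish, alcohol, spread type, cereal, added salt, water, fruit and
  vegetables): the count of healthy habits met is converted to cohort
  quartiles mapped to {0, 100/3, 200/3, 100} points.  Diet-quartile
  boundary ties resolve *upward* so a perfect count of nine always
  scores 100, even in a saturated cohort.
* **Cohort quartiles of the composite** use rank-based allocation:
  group sizes n//4 with the remainder assigned to the lowest quartiles,
  boundary ties to the lower quartile (so 23,758 distinct values split
  5940/5940/5939/5939); an all-tied input degenerates to Q1 with a
  warning.  Q1 is the least healthy quartile and serves as the Cox
  reference.

## Incidence rates

Rates are reported per 1000 person-years with 95% Poisson intervals.
The default interval is the normal approximation on the log-rate scale,
`rate · exp(±1.96/√events)`, with half-up integer rounding; this is the
method that reproduces the published per-quartile intervals exactly.
Count-scale normal and exact Garwood intervals are selectable.  A
zero-event group yields a degenerate (0, 0) interval with a warning.

## Cox models

A single partial-likelihood engine (vectorised Breslow accumulation
with an exact Efron correction applied only at tied event times)
underlies all fits.  It supports case weights and counting-process rows
((entry, stop] risk sets) under Breslow ties, a quadratic coefficient
penalty, and Newton–Raphson maximisation with step-halving, so the
objective is nondecreasing across iterations.  Convergence requires a
gradient max-norm below 1e-8 or an objective plateau (relative change
< 1e-10, which under quadratic convergence implies a numerically
vanishing gradient — relevant when a large smoothing penalty injects
round-off into the gradient); divergence (|β| > 100, monotone
likelihood) raises an explicit error.  Efron is the default tie method;
Breslow is selectable and is used wherever weights or delayed entry are
present.  Constant columns and rank-deficient designs are rejected.

Adjustment sets mirror the study's models: Model 1 unadjusted, Model 2
age + sex + Townsend deprivation, Model 3 additionally six baseline
comorbidities (stroke, MI, chronic coronary syndrome, heart failure,
type-2 diabetes, depression).  Multimorbidity is ≥ 1 of these six.

### Penalised spline

The continuous LE8 effect is modelled as f(x) = B(x)θ with a cubic
B-spline basis (default 8 basis functions, interior knots at exposure
quantiles) and a second-order difference penalty λ·θ'D'Dθ.  Because the
partial likelihood cannot identify an additive constant, θ is
reparameterised onto the orthogonal complement of the constant
direction.  The second-difference penalty leaves linear trends
unpenalised, so λ → ∞ collapses the fit onto the linear Cox model — a
property the tests exploit.  The effective degrees of freedom are
tr[(A + λP)⁻¹A] over the spline block (A the unpenalised observed
information at the penalised estimate); λ is found by bisection on
log λ to hit the pre-specified target (default 4 df) within 0.01.
Variances use (A + λP)⁻¹.  `linear_coef` is the least-squares linear
trend of the fitted curve over the sample exposures with a delta-method
SE; it equals the linear Cox coefficient in the λ → ∞ limit.  HR curves
are exp(f(x) − f(ref)) with pointwise delta-method CIs; the reference is
the sample median by default, and out-of-range grid points are clipped
with a warning.

### Diagnostics, moderation, sensitivity analyses

Proportional hazards are checked with Schoenfeld residuals (Efron-
consistent risk-set means) correlated against event rank via the
Grambsch–Therneau score test; the statistic matches the standard
cox.zph-style implementation.  Moderation is tested by a likelihood-
ratio comparison of penalised fits with and without spline × moderator
interaction columns (sharing the main fit's λ); the chi-square uses
unpenalised log partial likelihoods at the penalised estimates on the
interaction block's effective df, rounded — an approximation, flagged as
such.  The 2-year landmark filter removes all records whose follow-up
ended at or before the landmark and keeps survivors on the original
time scale with delayed entry.  The Fine–Gray subdistribution model for
MACE keeps competing deaths in the risk set with inverse-probability-
of-censoring weights G(t−)/G(D−) (G the Kaplan–Meier censoring
distribution), implemented as counting-process rows and fitted with the
weighted Breslow likelihood; with zero competing events it reduces
exactly to the cause-specific fit.  Standard errors are model-based
(inverse information), which understates the IPCW sampling variability
somewhat — a known limitation.

## Impact fractions

With HR(x) the fitted composite-hazard curve, PAF = 1 − Σᵢ HR(x_ref) /
Σᵢ HR(xᵢ); the default reference rule takes the minimum-hazard exposure
on the curve, searched between the 1st and 99th exposure percentiles
because the spline's extreme tails rest on very few observations and
can dip spuriously (fixed-score-100 and top-quartile-mean references are
selectable, for sensitivity across rules).  PIF replaces only eligible
exposures: x′ᵢ = min(xᵢ + 20, 100) when xᵢ is below the scenario
threshold (overall default 50).  Component scenarios raise one component
by 20 points (capped at 100) for individuals below that component's
threshold (50 for smoking/diet/blood pressure, 60 for non-HDL/HbA1c, 70
for BMI/activity/sleep), recompute the composite — which therefore
moves by at most 20/8 = 2.5 points — and evaluate through the composite
curve; fitting eight separate component–outcome splines is a possible
alternative pathway that is deliberately not the default.  Both
measures are scale-free and order-invariant, and every output carries
the caveat that these are hypothetical, scenario-based quantities
assuming a causal, transportable association.  CIs are nonparametric
bootstrap percentile intervals over individuals (500 replicates by
default); "refit" mode re-estimates the spline per replicate, "fast"
mode resamples exposures against the fixed curve; degenerate replicates
are dropped and counted.

## Synthetic cohort

The generator emulates the baseline structure of a UK-Biobank-style AF
sample.  A single latent healthiness factor Z ~ N(0,1) per participant
drives all components, reproducing the published quartile gradient
without specifying a full covariance matrix.  Continuous variables are
anchored at the published per-quartile means (age 61.82 ± 6.1; BMI
32.7/29.7/27.6/25.2; SBP 150.8/147.5/144.5/135.4; MET-min
1831/2753/3055/3108; HbA1c 40.6/37.8/36.6/35.7; deprivation −0.7…−1.9),
with residual noise topping variance up to the published overall SDs.
Because cohort quartiles are formed on the *scored* composite — a noisy
readout of Z — the anchor spread is inflated by a fixed empirical
attenuation correction (0.78), and the saturating activity profile
carries small additive anchor corrections; both constants are part of
the generator's calibration and reproduce the quartile means within 5%
at n = 20,000.  Categorical variables (sex 33% female, smoking
10/45/45% current/former/never, medications 27/30/2%, comorbidities)
use logistic or ordered-probit loadings on Z matching the published
gradients.

Survival is proportional hazards on the composite: the linear predictor
is β·(LE8 − 66) with default β = −0.025/point for death and
−0.018/point for MACE (the centering constant is fixed, not
cohort-dependent, to keep early records invariant to cohort size).
Event times are inverse-transform exponential by default (Weibull shape
configurable) with baseline hazards 0.032/y (death) and 0.050/y (MACE)
at the centre score; censoring is an independent exponential (0.085/y)
plus administrative truncation at 10 years.  These defaults reproduce
the published follow-up volume (~5.9 person-years per participant) and
bracket the published quartile event rates.  Randomness flows through
per-variable counter-derived substreams of one master seed, so a given
(spec, seed) regenerates byte-identical cohorts and growing n leaves
earlier records unchanged.

What the generator does *not* emulate: recruitment and sampling bias,
missingness (all records are complete), geography, measurement error in
self-reported behaviours, non-proportional hazards, and any direct
age/sex/comorbidity effect on survival beyond their correlation with
the composite.  Passing tests therefore demonstrate that the analysis
chain recovers known structure under its own assumptions, not that the
published real-data estimates are reproduced; the published hazard
ratios and impact fractions from restricted data are covered only
qualitatively (graded monotone quartile direction, order-of-magnitude
impact fractions).  One deliberate divergence: with AHA banding and
realistic lipid levels plus ~30% statin use, an appreciable share of
participants is eligible for the non-HDL component scenario, so the
near-zero cholesterol impact printed in the source analysis (which
implies an almost empty eligible set under its unpublished banding) is
not reproduced; tests assert the mechanism (component ranking tracks
the eligible-weighted composite shift) and the robust direction (diet
and blood pressure among the top contributors).

## Problem sizes and numerical defaults

Tests exercise the chain at n = 4,000 (shared fixture), calibration and
spline checks at n = 20,000, and parameter recovery over 50 replicates
of n = 20,000 for both endpoints (±2 SE coverage ≥ 90%).  The pipeline
default runs n = 23,758 with 200 fast-mode bootstrap replicates and
caps the Fine–Gray expansion at a 5,000-participant subsample (the IPCW
row expansion grows as competing deaths × later event times); full-refit
bootstrap and larger Fine–Gray samples are configuration switches.
Significance is conventionally 0.05 with raw, uncorrected p-values
throughout, mirroring the single-outcome-family reporting style of the
study design.
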