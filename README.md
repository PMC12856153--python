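# le8surv

Cardiovascular-health scoring and prognosis modelling for people with
atrial fibrillation (AF).

People with AF carry high long-term risks of death and major adverse
cardiovascular events (MACE: ischaemic heart disease, myocardial
infarction, stroke, heart failure).  The American Heart Association's
**Life's Essential 8** (LE8) score summarises modifiable cardiovascular
health on a 0–100 scale as the mean of eight component scores — diet,
physical activity, nicotine exposure, sleep, BMI, non-HDL cholesterol,
blood glucose (HbA1c), and blood pressure.  `le8surv` implements the full
analysis chain for asking *"does better cardiovascular health predict
better AF prognosis, and what would improving it buy?"*:

* an adapted LE8 scorer (UK-Biobank-style inputs; nine-item diet score
  converted to cohort quartiles) driven by an auditable plain-text rubric;
* ICD-10-based endpoint derivation (all-cause mortality; composite MACE
  from I20–I25, I21–I23, I60/I61/I63/I64, I50.0/I50.1/I50.9), incidence
  rates per 1000 person-years with Poisson CIs, and Kaplan–Meier curves;
* Cox proportional-hazards models over LE8 quartiles (Q1 = least healthy
  reference), the continuous score, and a **penalised cubic-spline** fit
  whose smoothing parameter is searched so the curve's effective degrees
  of freedom equals a pre-specified target (default 4), for the nonlinear
  hazard-ratio curve HR(x) = exp(f(x) − f(x_ref));
* moderation tests (spline × moderator likelihood-ratio tests), Schoenfeld
  proportional-hazards diagnostics, a 2-year landmark sensitivity filter,
  and a Fine–Gray subdistribution-hazard model for MACE with death as a
  competing risk;
* **population attributable fractions** (PAF = 1 − Σ HR(x_ref)/Σ HR(x_i))
  and scenario-based **potential impact fractions**
  (PIF = 1 − Σ HR(x′_i)/Σ HR(x_i), with x′ a +20-point improvement for
  individuals below an eligibility threshold, overall and per component),
  with bootstrap confidence intervals;
* a synthetic AF cohort generator calibrated to the published baseline
  profile (n ≈ 23,758; mean age 61.8; graded quartile gradients in BMI,
  blood pressure, activity, smoking, HbA1c) with proportional-hazards
  survival driven by the composite score — so the whole chain is testable
  without restricted data.

## Worked example

```python
import le8surv as L

spec = L.CohortSpec(n_participants=8000, seed=42)
cohort, diagnoses = L.generate_cohort(spec)
scores = L.score_cohort(cohort)

surv = L.derive_survival(cohort, diagnoses, L.ALL_CAUSE_MORTALITY)
data = surv.merge(scores[["id", "composite", "quartile"]], on="id")
print(L.rate_table(data)[["group", "events", "person_years",
                          "rate_1000py_rounded", "ci_low_rounded",
                          "ci_high_rounded"]].to_string(index=False))

fit = L.fit_cox(data, L.ModelSpec(adjustment="model1", exposure_form="quartile"))
print(fit.summary()[["hr", "ci_low", "ci_high", "p"]].round(3))

sfit = L.fit_cox_pspline(data)
print(f"penalised spline: effective df = {sfit.effective_df:.2f}, "
      f"linear trend = {sfit.linear_coef:.4f} (SE {sfit.se_linear:.4f})")

pif = L.pif(sfit, data["composite"].to_numpy(), L.Scenario())
print(f"PIF (+20 points for LE8 < 50): {100*pif.estimate:.1f}%")
```

prints

```
group  events  person_years  rate_1000py_rounded  ci_low_rounded  ci_high_rounded
   Q1     565  10951.690623                   52              48               56
   Q2     448  11571.110198                   39              35               42
   Q3     307  11749.626283                   26              23               29
   Q4     250  12151.819302                   21              18               23
       hr  ci_low  ci_high    p
Q2  0.751   0.663    0.850  0.0
Q3  0.507   0.442    0.583  0.0
Q4  0.400   0.344    0.464  0.0
penalised spline: effective df = 4.00, linear trend = -0.0251 (SE 0.0018)
PIF (+20 points for LE8 < 50): 10.2%
```

Reading: mortality falls monotonically across cardiovascular-health
quartiles (52 → 21 deaths per 1000 person-years; Q4 hazard 0.40× Q1); the
spline's linear trend recovers the simulated log-hazard slope of −0.025
per LE8 point; and raising every below-50 score by 20 points would avert
about 10% of deaths under the fitted (assumed causal) association.

The same chain is available from the shell:

```bash
le8surv simulate --n 8000 --seed 42 --outdir cohort_out
le8surv rates cohort_out/cohort.csv cohort_out/diagnoses.csv --endpoint mace
le8surv report --outdir run_out --seed 42 --n 8000   # full pipeline
```

`le8surv report` writes every artefact (baseline table, rates, KM curves,
Models 1–3 quartile/linear/spline fits, Schoenfeld tests, moderation
LRTs, PAF/PIF tables, landmark and Fine–Gray sensitivity fits) plus a
`manifest.json` capturing the config hash, seed, and version.

## Cohort table schema

`generate_cohort` (and the `simulate` subcommand) emit two CSVs:

* `cohort.csv` — one row per participant: `id`, `age_years`, `female`,
  `townsend`, `smoking_status` (`never|former|current`), `quit_years`,
  `bmi_kg_m2`, `sbp_mmHg`, `dbp_mmHg`, `met_min_week`, `sleep_hours`,
  `non_hdl_mmol_l`, `hba1c_mmol_mol`, medication flags
  (`on_antihypertensive`, `on_lipid_lowering`, `on_glucose_lowering`),
  nine binary diet items (`diet_processed_meat` … `diet_fruit_veg`), six
  comorbidity flags (`comorb_stroke`, `comorb_mi`,
  `comorb_chronic_coronary`, `comorb_heart_failure`,
  `comorb_type2_diabetes`, `comorb_depression`), `death_day` (blank if
  alive), `censor_day` (always present; days from baseline).
* `diagnoses.csv` — long format: `id`, `icd10`, `day` (days from
  baseline; the AF inclusion code I48 appears at day 0).

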