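# cdss — offline-first clinical decision support for primary care

`cdss` is a Python library and command-line toolkit for managing
hypertension and diabetes in primary care settings with intermittent
connectivity. It turns a structured consultation record into tailored,
severity-tagged recommendations, keeps every unit's data in an
append-only local registry that synchronizes idempotently to a central
pool, and ships the statistical machinery used to evaluate such a system
(registry indicators, cohort summaries, Likert-instrument reliability).

It is aimed at implementers and evaluators of chronic-disease decision
support: the clinical content is declarative (a JSON rule bank over a
closed predicate vocabulary), every clinical cutoff is a named, documented
constant, and every computed variable comes from a published equation with
its coefficients shipped as an auditable table.

## What it computes

**Computed clinical variables** (`cdss.calculators`):

- BMI = weight / height² (kg/m²).
- eGFR by the CKD-EPI 2009 creatinine equation
  `eGFR = 141 · min(Scr/κ, 1)^α · max(Scr/κ, 1)^−1.209 · 0.993^age ·
  1.018 [female]` (optional race term, off by default), with KDIGO
  staging G1–G5 (G3a = 45–59 mL/min/1.73 m²).
- 10-year general cardiovascular risk by the Framingham sex-specific
  survival model, `risk = 1 − S₀(10)^exp(L − L̄)`, in the lipid-based and
  the office-based (BMI) variants.

**Decision rules** (`cdss.rules`): a rule bank is evaluated against the
patient state assembled from the record, the current consultation and
history. Conditions are and/or/not trees over named predicates
(`egfr`, `risk_pct`, `on_thiazide`, `fundoscopy_overdue`, …); conflicts
within a group resolve to the best evidence level (A > B > C > D, ties to
the lowest rule id); output is ordered red flags first. The shipped bank
implements the documented exemplars: statin suggestion above 20% 10-year
risk, thiazide contraindication at eGFR < 30, metformin above 2550 mg/day,
annual fundoscopy reminder in diabetes, one-month follow-up for blood
pressure ≥ 140/90, adherence reinforcement after a missed group session,
a stage-G3a renal red flag and the simvastatin–amlodipine interaction.

**Registry and synchronization** (`cdss.registry`): append-only versioned
NDJSON log per unit, last-writer-wins merge with full history retention,
flat CSV export, indicator-driven patient lists and cohort summaries with
half-up two-decimal percentages.

**Survey reliability** (`cdss.survey`): per-item median (IQR) by
professional group and Cronbach α = k/(k−1)·(1 − Σσ²ᵢ/σ²ₜ) globally and
per dimension (sample variances, listwise deletion, linear-interpolation
quartiles).

**Synthetic cohorts** (`cdss.synthetic`): deterministic generators for
registries with an exact diagnosis 2×2 table and sex count, and for
24-item Likert matrices with controllable inter-item correlation.

## Worked example

```python
from cdss import (CohortSpec, generate_cohort, cohort_summary,
                  default_rule_bank, build_patient_state, evaluate_rules)
from cdss.registry import latest_patient_state
from cdss.synthetic import exemplar_scenarios

# A registry with the end-line structure: 4211 patients, 3993 hypertensive,
# 1028 diabetic, 810 with both, 2819 female, 7960 consultations.
registry = generate_cohort(seed=1)
print(cohort_summary(registry))
```

prints (abbreviated):

```
{'patients': 4211, 'consultations': 7960,
 'hypertension_n': 3993, 'hypertension_pct': 94.82,
 'diabetes_n': 1028, 'diabetes_pct': 24.41,
 'both_n': 810, 'both_pct': 19.24,
 'female_n': 2819, 'female_pct': 66.94,
 'age_median': 55.0, 'age_q1': 47.0, 'age_q3': 62.0}
```

i.e. 94.82% of registered patients carry a hypertension diagnosis, 24.41%
diabetes, 19.24% both, and 66.94% are female, with a median age of 55
(IQR 47–62) at the latest consultation.

Evaluating the shipped rule bank on a crafted high-risk patient:

```python
scenario = exemplar_scenarios()[0]   # male smoker, 60 y, risk 29.5%, no statin
state = build_patient_state(scenario.patient, scenario.consultation)
for rec in evaluate_rules(default_rule_bank(), state):
    print(rec.severity, "|", rec.rendered_message)
```

```
suggestion | Cardiovascular risk greater than 20% in 10 years. The prescription of statin is suggested.
```

The same pipeline is available from the shell:

```sh
cdss synth cohort --seed 1 --out registry.ndjson
cdss summary --registry registry.ndjson
cdss evaluate --registry registry.ndjson --patient p00000
cdss survey alpha --responses survey.csv --by dimension
```

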