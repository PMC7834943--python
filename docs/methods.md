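# Methods

This note documents the models, conventions and design choices behind
`cdss`, and what the synthetic data used by the tests does and does not
establish.

## Record model

Patients, consultations, group sessions and professional profiles are
pydantic models with closed coded vocabularies (symptoms, comorbidities,
drug classes, roles). Few fields are hard-required; instead
`validate_consultation` returns non-blocking completeness warnings (foot
examination missing in diabetes, blood pressure in a single position,
missing creatinine, …), while true domain violations — negative
pressures, a consultation predating registration, prescriptions recorded
by a non-physician — raise. Units are fixed (mg/dL, mmHg, kg, m, cm);
dates are ISO-8601 and timestamps UTC so synchronization ordering is
unambiguous. Drafting a follow-up consultation carries forward active
medications and the medical history but never per-visit measurements.

## Computed variables

**CKD-EPI 2009.** `eGFR = 141 · min(Scr/κ,1)^α · max(Scr/κ,1)^−1.209 ·
0.993^age · 1.018 [female]`, with κ = 0.7 (women) / 0.9 (men) and
α = −0.329 / −0.411. The 1.159 race multiplier is shipped but off by
default; the flag exists so the choice is explicit and auditable. The
function is continuous at Scr = κ (both ratio terms collapse to 1) and
strictly decreasing in creatinine, which makes the KDIGO staging a
partition of the creatinine axis for fixed age and sex. Stage boundaries
assign the exact band minimum to the higher-function stage (60 → G2,
45 → G3a).

**Framingham general-CVD.** Sex-specific survival model
`risk = 1 − S₀(10)^exp(L − L̄)` over the composite outcome (coronary
disease, stroke, peripheral artery disease, heart failure), in two
variants: lipid-based (log total and HDL cholesterol) and office-based
(log BMI replacing the lipids, for use before laboratory results exist).
All coefficients, the mean linear predictors and baseline survivals live
in `src/cdss/data/coefficients.csv`, one row per term, checksum-verified
at import. The implementation was validated against the coefficient
publication's own worked example (61-year-old female smoker, TC 180,
HDL 47, SBP 124 untreated → 10.48%). Ages outside the published validity
range [30, 74] raise rather than clamp. Risk categories: high strictly
above 20%, low strictly below 10%.

**Display rounding.** Risk and BMI to one decimal, eGFR to integer, in
rendered messages and display helpers only; all internal computation and
rule evaluation uses full precision.

## Rule engine

Conditions are and/or/not trees over a closed predicate vocabulary (22
named state values plus one `on_<class>` flag per drug class); there is
no arbitrary code in a rule bank, which keeps the clinical content
auditable and lets the engine be verified against a brute-force
evaluator. Clinical cutoffs are a named-constants table referenced from
conditions as `"$name"`:

| constant | default | meaning |
|---|---|---|
| `statin_risk_threshold_pct` | 20 | 10-year risk above which a statin is suggested |
| `thiazide_egfr_cutoff` | 30 mL/min/1.73 m² | below: thiazide contraindicated |
| `metformin_max_daily_mg` | 2550 mg | maximum recommended daily dose |
| `fundoscopy_interval_days` | 365 | retinopathy screening interval in diabetes |
| `bp_goal_systolic` / `bp_goal_diastolic` | 140 / 90 mmHg | per-patient configurable goal |
| `group_window_days` | 180 | look-back for group-session adherence |
| `simvastatin_max_with_amlodipine_mg` | 20 mg | interaction dose cap |

Each default is deployment configuration with a guideline-citation slot,
not clinical ground truth.

Evaluation semantics: a condition touching a missing value (no
creatinine → no eGFR) makes the rule *not evaluable*; it is skipped and
reported, never raised, and the set of skipped rules is exactly the set
whose conditions reference missing state. Blood-pressure classification
uses the highest reading across recorded positions (conservative
alerting). History-dependent predicates (days since fundoscopy, group
attendance) are computed against the consultation date, not the wall
clock. Within a conflict group the single rule with the best evidence
level survives (ordinal A > B > C > D; ties broken by lowest rule id for
determinism). Output ordering is severity (red_flag > alert > suggestion
> info) then rule id.

The shipped bank carries the documented exemplar messages plus an
authoring format that scales to banks of hundreds of rules; the
stage-specific renal red flag is shipped for G3a (the documented
example) and further stages are authored the same way. Rendered
placeholders (`{egfr}`, `{risk_pct}`, `{ckd_stage_short}`, …) are
validated at bank load, so rendering cannot fail at evaluation time.

## Registry and synchronization

Each unit's registry is an append-only log of versioned document
envelopes; edits append superseding versions and never destroy history.
The NDJSON sync batch is the unit of transport (network or portable
storage). Merging at the central pool is a set union on envelope
identities, so it is idempotent and commutative by construction; the
"current" view resolves conflicts last-writer-wins by the ordering key
(version timestamp, unit id, version number), which is total and
identical regardless of merge order. Timestamps embed a per-unit logical
clock so versions from one unit are totally ordered even within one
wall-clock second.

Cohort percentages use half-up rounding at two decimals
(`round(100·a/n, 2)`), the convention of printed clinical tables, via
decimal arithmetic rather than binary floats. Ages are taken at each
patient's latest consultation. CSV export emits one flat row per
consultation joined with patient scalars in a documented stable column
order; scalar fields round-trip losslessly.

## Survey reliability

Cronbach α = k/(k−1) · (1 − Σᵢσ²ᵢ/σ²ₜ) with sample (n−1) variances in
both numerator and denominator and listwise deletion of incomplete
respondents — the simplest defensible convention, matching common
statistical packages; pairwise deletion is deliberately not offered.
α is invariant to adding a constant to every response and to item
relabeling, and equals the covariance-matrix identity
k/(k−1)·(1 − tr C / ΣC) to numerical precision; the test suite checks
both paths. Quartiles use linear interpolation (numpy's default), fixed
and documented because published median (IQR) tables cannot disambiguate
the convention. The default instrument maps 24 items to four dimensions
(feasibility, usability, utility, satisfaction), six items each, in
questionnaire order; custom mappings can be supplied.

## Synthetic data

`generate_cohort` emulates the end-line registry's marginal structure:
4211 patients with 3993 hypertensive, 1028 diabetic, 810 with both
(equivalently 3183 hypertension-only, 218 diabetes-only and zero with
neither — the printed margins leave no room for undiagnosed patients),
2819 female, median age 55 (IQR 47–62) and 7960 consultations. Exact
mode allocates the diagnosis 2×2 table and the sex count without
replacement, so those counts are hit exactly; ages come from a
piecewise-linear inverse CDF anchored at the target quartiles over a
30–80-year range, so the age median/IQR are matched in distribution, not
per draw. Consultation counts distribute the exact total with at least
one visit per patient. Clinical covariates (blood pressure,
anthropometrics, creatinine, lipids, glycemia, medication mixes with
occasional above-maximum metformin doses, fundoscopy recency, group
attendance) are drawn from plausible primary-care ranges, independently
given the diagnosis strata.

What this shows — and does not. Passing tests on these cohorts
establishes the arithmetic of the registry reports, the behaviour of the
rule engine and the conventions of the statistics; it does not establish
clinical validity on real populations, where covariates are correlated,
measurement is noisy and longitudinal, and prevalences drift.
Correspondingly, the deployment's observed instrument reliability
(α = .93) and its per-item medians arise from unpublished raw responses
and are not reproduction targets; the survey generator instead produces
matrices whose α is controllable through a one-factor model
(inter-item correlation 1 → α = 1 exactly; 0 → α ≈ 0), which is what the
reliability code can be held to.

## Numerical and design choices

- Percent rounding: decimal half-up at 2 places (cohort) and at 0 places
  for the printed professional mix; banker's rounding is deliberately
  avoided.
- Coefficient table integrity: SHA-256 checked at import; a modified
  table fails loudly rather than computing silently with wrong
  constants.
- Conflict-resolution tie-break by rule id, severity ordering, and the
  logical-clock timestamps all exist to make every output deterministic
  for identical inputs.
- The brute-force rule evaluator used in verification re-implements
  condition semantics and conflict resolution naively and independently;
  it is a test oracle, never a code path.
- Problem sizes in the shipped verification script: the full 4211-patient
  registry, 1000 random engine/oracle instances, 10 randomized sync
  permutations on a 40-patient unit, and 96-respondent survey panels —
  sizes chosen to match the reported study structure while keeping a full
  run to a few seconds.

## Known limitations

- The shipped rule bank is the documented exemplar subset, not a full
  clinical knowledge base; the format is the contribution.
- No drug-interaction database beyond the exemplified simvastatin–
  amlodipine check; no alternative risk scores.
- The sync model assumes cooperating units and does no authentication,
  encryption or concurrent-write arbitration beyond last-writer-wins.
- eGFR staging uses a single creatinine value, not the confirmed-
  chronicity definition of clinical guidelines.
- Stochastic cohort mode draws diagnoses per patient independently; it
  matches prevalences in expectation only.
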