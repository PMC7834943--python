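"""Synthetic cohorts and survey responses for exercising every module.

No patient-level data from the deployment is published, so tests and
demonstrations run on synthetic registries whose marginal structure
matches the end-line registry report: 4211 patients, 3993 with
hypertension, 1028 with diabetes, 810 with both (hence 218 with diabetes
only and none with neither), 2819 female, median age 55 (IQR 47–62), and
7960 consultations.  ``exact_count`` mode hits those counts exactly by
allocation without replacement via the 2×2 hypertension × diabetes
table; ``stochastic`` mode draws each margin independently per patient.

Clinical covariates (blood pressure, anthropometrics, creatinine,
lipids, glycemia, medications, fundoscopy recency, group attendance) are
drawn from documented plausible primary-care ranges, independently given
the diagnosis strata — enough structure for decision rules to fire, with
no claim of longitudinal epidemiological realism.

Survey generation uses a one-factor model with a configurable inter-item
correlation so internal consistency (Cronbach alpha) can be pushed
toward 1 or 0 on demand.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .records import (
    BloodPressure, CarePlan, Comorbidity, Consultation, Diagnosis, DrugClass,
    FootExamResult, GroupSession, GroupType, LabPanel, Medication,
    PatientRecord, PhysicalExam, ProfessionalRole, Sex, Symptom,
)
from .registry import Registry
from .survey import DEFAULT_DIMENSION_MAP, GROUPS, LikertResponseSet


@dataclass(frozen=True)
class CohortSpec:
    """Target structure of a synthetic registry.

    In ``exact_count`` mode the diagnosis/sex fields are absolute counts
    and are hit exactly; in ``stochastic`` mode they are probabilities
    (``both`` then given as P(diabetes | hypertension) consistency is not
    enforced — each patient draws hypertension, then diabetes with the
    conditional probability implied by the three marginals).
    """

    n_patients: int = 4211
    mode: str = "exact_count"  # or "stochastic"
    hypertension: float = 3993
    diabetes: float = 1028
    both: float = 810
    female: float = 2819
    age_median: float = 55.0
    age_q1: float = 47.0
    age_q3: float = 62.0
    age_min: float = 30.0
    age_max: float = 80.0
    total_consultations: Optional[int] = 7960  # exact mode; >= n_patients
    consultations_per_patient_mean: float = 1.89  # stochastic mode
    end_date: dt.date = dt.date(2019, 6, 30)
    unit_id: str = "unit-0"

    def validate(self) -> None:
        if self.mode not in ("exact_count", "stochastic"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "exact_count":
            h, d, b, f = (int(self.hypertension), int(self.diabetes),
                          int(self.both), int(self.female))
            if b > min(h, d):
                raise ValueError("'both' exceeds a diagnosis margin")
            if h + d - b > self.n_patients:
                raise ValueError("diagnosis counts exceed cohort size")
            if max(h, d, f) > self.n_patients:
                raise ValueError("count exceeds cohort size")
            if (self.total_consultations is not None
                    and 0 < self.total_consultations < self.n_patients):
                raise ValueError("need at least one consultation per patient")
        else:
            for p in (self.hypertension, self.diabetes, self.both, self.female):
                if not 0 <= p <= 1:
                    raise ValueError("stochastic mode expects probabilities")


#: The end-line registry structure as printed in the deployment report.
END_LINE_SPEC = CohortSpec()


def _sample_ages(rng: np.random.Generator, n: int, spec: CohortSpec
                 ) -> np.ndarray:
    """Piecewise-linear inverse-CDF sampling anchored at the target quartiles."""
    u = rng.uniform(0, 1, size=n)
    anchors_p = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
    anchors_x = np.array([spec.age_min, spec.age_q1, spec.age_median,
                          spec.age_q3, spec.age_max])
    return np.interp(u, anchors_p, anchors_x)


def _allocate_flags(rng: np.random.Generator, spec: CohortSpec
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(hypertension, diabetes, female) boolean arrays per patient."""
    n = spec.n_patients
    if spec.mode == "exact_count":
        h, d, b = int(spec.hypertension), int(spec.diabetes), int(spec.both)
        cells = np.concatenate([
            np.repeat(3, b),          # both
            np.repeat(2, h - b),      # hypertension only
            np.repeat(1, d - b),      # diabetes only
            np.repeat(0, n - (h + d - b)),
        ])
        rng.shuffle(cells)
        htn = (cells & 2).astype(bool)
        dm = (cells & 1).astype(bool)
        female = np.zeros(n, dtype=bool)
        female[rng.choice(n, size=int(spec.female), replace=False)] = True
    else:
        htn = rng.uniform(size=n) < spec.hypertension
        # conditional P(dm | htn) implied by the three marginals
        p_h = max(spec.hypertension, 1e-12)
        p_dm_given_h = min(spec.both / p_h, 1.0)
        p_dm_given_not_h = 0.0
        if spec.hypertension < 1:
            p_dm_given_not_h = min(
                max((spec.diabetes - spec.both) / (1 - spec.hypertension), 0.0),
                1.0)
        u = rng.uniform(size=n)
        dm = np.where(htn, u < p_dm_given_h, u < p_dm_given_not_h)
        female = rng.uniform(size=n) < spec.female
    return htn, dm, female


def _patient_medications(rng: np.random.Generator, htn: bool, dm: bool
                         ) -> list[Medication]:
    meds: list[Medication] = []
    if htn:
        pool = [
            ("enalapril", DrugClass.ace_inhibitor, 20.0),
            ("losartan", DrugClass.arb, 50.0),
            ("hydrochlorothiazide", DrugClass.thiazide, 25.0),
            ("amlodipine", DrugClass.ccb, 5.0),
            ("atenolol", DrugClass.beta_blocker, 50.0),
        ]
        k = int(rng.integers(1, 4))
        for idx in rng.choice(len(pool), size=k, replace=False):
            name, cls, dose = pool[idx]
            meds.append(Medication(drug_name=name, drug_class=cls,
                                   daily_dose_mg=dose))
    if dm:
        dose = float(rng.choice([850, 1700, 2000, 2550, 3000],
                                p=[0.25, 0.35, 0.2, 0.15, 0.05]))
        meds.append(Medication(drug_name="metformin",
                               drug_class=DrugClass.metformin,
                               daily_dose_mg=dose))
    if rng.uniform() < 0.25:
        dose = float(rng.choice([20, 40], p=[0.7, 0.3]))
        meds.append(Medication(drug_name="simvastatin",
                               drug_class=DrugClass.statin,
                               daily_dose_mg=dose))
    return meds


def _consultation(rng: np.random.Generator, patient_idx: int, visit: int,
                  patient_id: str, date: dt.date, htn: bool, dm: bool,
                  smoker: bool, meds: list[Medication]) -> Consultation:
    sbp = float(np.clip(rng.normal(145 if htn else 125, 18), 90, 230))
    dbp = float(np.clip(rng.normal(88 if htn else 78, 11), 50, 135))
    weight = float(np.clip(rng.normal(74, 14), 42, 150))
    height = float(np.clip(rng.normal(1.62, 0.09), 1.40, 1.98))
    labs = LabPanel(
        date=date,
        serum_creatinine=(
            float(np.clip(rng.lognormal(np.log(0.9), 0.32), 0.4, 6.0))
            if rng.uniform() < 0.8 else None),
        total_cholesterol=float(np.clip(rng.normal(202, 36), 100, 380)),
        hdl_cholesterol=float(np.clip(rng.normal(48, 12), 20, 100)),
        fasting_glucose=float(np.clip(
            rng.normal(150 if dm else 95, 30 if dm else 12), 60, 400)),
        hba1c=float(np.clip(rng.normal(8.0 if dm else 5.5, 1.3 if dm else 0.4),
                            4.0, 15.0)),
        fundoscopy_date=(
            date - dt.timedelta(days=int(rng.integers(30, 700)))
            if dm and rng.uniform() < 0.6 else None),
    )
    history = [Comorbidity.smoking] if smoker else []
    if rng.uniform() < 0.2:
        history.append(Comorbidity.dyslipidemia)
    return Consultation(
        consultation_id=f"c{patient_idx:05d}-{visit}",
        patient_id=patient_id,
        date=date,
        professional_role=(ProfessionalRole.physician
                           if rng.uniform() < 0.6 else ProfessionalRole.nurse),
        symptoms=[Symptom.asymptomatic] if rng.uniform() < 0.6 else
                 [Symptom.headache],
        medical_history=history,
        physical_exam=PhysicalExam(
            bp_sitting=BloodPressure(systolic=sbp, diastolic=dbp),
            weight_kg=weight, height_m=height,
            waist_cm=float(np.clip(rng.normal(94, 12), 60, 160)),
            foot_exam=(FootExamResult.normal if dm and rng.uniform() < 0.7
                       else None),
        ),
        medications=meds,
        labs=labs,
        care_plan=CarePlan(),
    )


def generate_cohort(spec: CohortSpec = END_LINE_SPEC, *, seed: int = 0
                    ) -> Registry:
    """Build a synthetic registry matching the cohort specification.

    Deterministic for a fixed seed; in ``exact_count`` mode the diagnosis
    2×2 table, the sex count and (when set) the total consultation count
    are hit exactly.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    registry = Registry(spec.unit_id)
    n = spec.n_patients
    if n == 0:
        return registry
    htn, dm, female = _allocate_flags(rng, spec)
    ages = _sample_ages(rng, n, spec)

    if spec.mode == "exact_count" and spec.total_consultations:
        extra = rng.multinomial(spec.total_consultations - n, np.full(n, 1.0 / n))
        visits = 1 + extra
    else:
        visits = 1 + rng.poisson(
            max(spec.consultations_per_patient_mean - 1.0, 0.0), size=n)

    for i in range(n):
        pid = f"p{i:05d}"
        last_date = spec.end_date - dt.timedelta(days=int(rng.integers(0, 180)))
        age_years = int(ages[i])
        birth = last_date - dt.timedelta(days=int(round(age_years * 365.25))
                                         + int(rng.integers(0, 300)))
        registered = dt.datetime.combine(
            last_date - dt.timedelta(days=int(rng.integers(60, 540))),
            dt.time(12, 0), tzinfo=dt.timezone.utc)
        diagnoses = set()
        if htn[i]:
            diagnoses.add(Diagnosis.hypertension)
        if dm[i]:
            diagnoses.add(Diagnosis.diabetes)
        patient = PatientRecord(
            patient_id=pid,
            name=f"patient-{i:05d}",
            sex=Sex.female if female[i] else Sex.male,
            birth_date=birth,
            diagnoses=diagnoses,
            registered_at=registered,
            registering_unit=spec.unit_id,
        )
        registry.append(patient)

        smoker = bool(rng.uniform() < 0.15)
        meds = _patient_medications(rng, bool(htn[i]), bool(dm[i]))
        k = int(visits[i])
        span = (last_date - registered.date()).days
        offsets = sorted(rng.choice(max(span, k), size=k - 1, replace=False)
                         .tolist()) if k > 1 else []
        dates = [registered.date() + dt.timedelta(days=int(o))
                 for o in offsets] + [last_date]
        for v, date in enumerate(dates):
            registry.append(_consultation(
                rng, i, v, pid, date, bool(htn[i]), bool(dm[i]), smoker, meds))
        if rng.uniform() < 0.3:
            registry.append(GroupSession(
                session_id=f"g{i:05d}",
                patient_id=pid,
                group_type=(GroupType.diabetes if dm[i]
                            else GroupType.hypertension),
                date=last_date - dt.timedelta(days=int(rng.integers(7, 120))),
                attended=bool(rng.uniform() < 0.75),
            ))
    return registry


def generate_survey(
    n_per_group: Optional[Mapping[str, int]] = None,
    *,
    inter_item_correlation: float = 0.5,
    item_means: Optional[np.ndarray] = None,
    seed: int = 0,
) -> LikertResponseSet:
    """Synthetic 24-item Likert matrix from a one-factor model.

    ``inter_item_correlation`` (rho in [0, 1]) is the share of latent
    variance common to all items: 1 gives identical item columns (alpha
    exactly 1), 0 gives independent items (alpha near 0 for large n).
    Default group sizes are the study's professional mix (25 physicians,
    44 nurses, 27 multidisciplinary-team members).
    """
    if n_per_group is None:
        n_per_group = {"physician": 25, "nurse": 44, "nasf": 27}
    if not 0 <= inter_item_correlation <= 1:
        raise ValueError("inter_item_correlation must be in [0, 1]")
    for g, n in n_per_group.items():
        if n < 2:
            raise ValueError(f"need n >= 2 per group (got {n} for {g!r})")
    rng = np.random.default_rng(seed)
    items = list(DEFAULT_DIMENSION_MAP)
    k = len(items)
    mu = (np.asarray(item_means, dtype=float) if item_means is not None
          else np.full(k, 4.2))
    groups: list[str] = []
    rows: list[np.ndarray] = []
    rho = inter_item_correlation
    for group, n in n_per_group.items():
        factor = rng.normal(0, 1, size=n)
        noise = rng.normal(0, 1, size=(n, k))
        latent = mu + 0.8 * (np.sqrt(rho) * factor[:, None]
                             + np.sqrt(1 - rho) * noise)
        scores = np.clip(np.rint(latent), 1, 5)
        rows.append(scores)
        groups.extend([group] * n)
    matrix = np.vstack(rows)
    return LikertResponseSet(
        pd.DataFrame(matrix, columns=items), groups)


# ---------------------------------------------------------------------------
# Hand-crafted exemplar scenarios for the shipped decision rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scenario:
    """A crafted patient/consultation pair and the single rule it triggers.

    ``control`` is a minimally modified twin on which the rule (and every
    other rule in the shipped bank) stays silent.
    """

    name: str
    expected_rule_id: str
    patient: PatientRecord
    consultation: Consultation
    control_patient: PatientRecord
    control_consultation: Consultation
    group_sessions: tuple[GroupSession, ...] = ()
    control_group_sessions: tuple[GroupSession, ...] = ()


def _scenario_patient(idx: int, sex: Sex, age: int,
                      diagnoses: set[Diagnosis]) -> PatientRecord:
    visit = dt.date(2019, 3, 1)
    return PatientRecord(
        patient_id=f"sc{idx:02d}",
        name=f"scenario-{idx:02d}",
        sex=sex,
        birth_date=visit - dt.timedelta(days=int(age * 365.25) + 40),
        diagnoses=diagnoses,
        registered_at=dt.datetime(2018, 1, 10, 12, tzinfo=dt.timezone.utc),
    )


def _scenario_consultation(idx: int, pid: str, *, sbp: float, dbp: float,
                           meds: list[Medication],
                           smoker: bool = False,
                           creatinine: Optional[float] = None,
                           total_chol: Optional[float] = None,
                           hdl: Optional[float] = None,
                           fundoscopy_days_ago: Optional[int] = None,
                           ) -> Consultation:
    visit = dt.date(2019, 3, 1)
    return Consultation(
        consultation_id=f"sc{idx:02d}-1",
        patient_id=pid,
        date=visit,
        professional_role=ProfessionalRole.physician,
        symptoms=[Symptom.asymptomatic],
        medical_history=[Comorbidity.smoking] if smoker else [],
        physical_exam=PhysicalExam(
            bp_sitting=BloodPressure(systolic=sbp, diastolic=dbp),
            weight_kg=72.0, height_m=1.65, waist_cm=92.0,
            foot_exam=FootExamResult.normal,
        ),
        medications=meds,
        labs=LabPanel(
            date=visit,
            serum_creatinine=creatinine,
            total_cholesterol=total_chol,
            hdl_cholesterol=hdl,
            fundoscopy_date=(visit - dt.timedelta(days=fundoscopy_days_ago)
                             if fundoscopy_days_ago is not None else None),
        ),
    )


def _med(name: str, cls: DrugClass, dose: float) -> Medication:
    return Medication(drug_name=name, drug_class=cls, daily_dose_mg=dose)


def exemplar_scenarios() -> list[Scenario]:
    """The six documented reminder/suggestion scenarios with matched controls.

    Each scenario triggers exactly one rule of the shipped bank under the
    default thresholds; its control twin triggers none.
    """
    visit = dt.date(2019, 3, 1)
    scenarios: list[Scenario] = []

    # 1. High cardiovascular risk without a statin -> statin suggestion.
    #    Male smoker, 60 y, controlled BP so no blood-pressure rules fire.
    p = _scenario_patient(1, Sex.male, 60, {Diagnosis.hypertension})
    c = _scenario_consultation(
        1, p.patient_id, sbp=135, dbp=82, smoker=True, creatinine=0.9,
        total_chol=200, hdl=45, meds=[])
    cc = c.model_copy(update={"medications": [
        _med("simvastatin", DrugClass.statin, 20.0)]})
    scenarios.append(Scenario("statin_for_high_risk", "statin_high_cv_risk",
                              p, c, p, cc))

    # 2. Thiazide with substantially reduced renal function -> red flag.
    p = _scenario_patient(2, Sex.female, 65, {Diagnosis.hypertension})
    meds = [_med("hydrochlorothiazide", DrugClass.thiazide, 25.0)]
    c = _scenario_consultation(
        2, p.patient_id, sbp=130, dbp=80, creatinine=2.4,
        total_chol=190, hdl=55, meds=meds)
    cc = c.model_copy(update={"labs": c.labs.model_copy(
        update={"serum_creatinine": 0.8})})
    scenarios.append(Scenario("thiazide_reduced_renal_function",
                              "thiazide_contraindicated_low_egfr",
                              p, c, p, cc))

    # 3. Metformin above the maximum recommended dose.
    p = _scenario_patient(3, Sex.female, 50, {Diagnosis.diabetes})
    c = _scenario_consultation(
        3, p.patient_id, sbp=120, dbp=75, creatinine=0.8,
        total_chol=185, hdl=60, fundoscopy_days_ago=100,
        meds=[_med("metformin", DrugClass.metformin, 3000.0)])
    cc = c.model_copy(update={"medications": [
        _med("metformin", DrugClass.metformin, 1700.0)]})
    scenarios.append(Scenario("metformin_over_maximum",
                              "metformin_above_max_dose", p, c, p, cc))

    # 4. Diabetic without fundoscopic assessment in the last year.
    p = _scenario_patient(4, Sex.female, 50, {Diagnosis.diabetes})
    c = _scenario_consultation(
        4, p.patient_id, sbp=120, dbp=75, creatinine=0.8,
        total_chol=185, hdl=60, fundoscopy_days_ago=None,
        meds=[_med("metformin", DrugClass.metformin, 1700.0)])
    cc = c.model_copy(update={"labs": c.labs.model_copy(
        update={"fundoscopy_date": visit - dt.timedelta(days=90)})})
    scenarios.append(Scenario("fundoscopy_overdue_diabetes",
                              "fundoscopy_overdue", p, c, p, cc))

    # 5. Uncontrolled blood pressure -> one-month reassessment.  No
    #    antihypertensive on board, so the add-a-drug suggestion stays out.
    p = _scenario_patient(5, Sex.female, 45, {Diagnosis.hypertension})
    c = _scenario_consultation(
        5, p.patient_id, sbp=155, dbp=95, creatinine=0.7,
        total_chol=180, hdl=60, meds=[])
    cc = c.model_copy(update={"physical_exam": c.physical_exam.model_copy(
        update={"bp_sitting": BloodPressure(systolic=130, diastolic=80)})})
    scenarios.append(Scenario("uncontrolled_bp_follow_up",
                              "bp_reassess_one_month", p, c, p, cc))

    # 6. Missed educational-group session -> adherence reinforcement.
    p = _scenario_patient(6, Sex.female, 55, {Diagnosis.hypertension})
    c = _scenario_consultation(
        6, p.patient_id, sbp=128, dbp=78, creatinine=0.7,
        total_chol=180, hdl=60,
        meds=[_med("enalapril", DrugClass.ace_inhibitor, 20.0)])
    missed = GroupSession(
        session_id="sc06-g", patient_id=p.patient_id,
        group_type=GroupType.hypertension,
        date=visit - dt.timedelta(days=30), attended=False)
    attended = missed.model_copy(update={"attended": True})
    scenarios.append(Scenario("missed_group_adherence",
                              "adherence_reinforcement", p, c, p, c,
                              group_sessions=(missed,),
                              control_group_sessions=(attended,)))
    return scenarios
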