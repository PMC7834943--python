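"""Structured clinical evaluation data model.

Every other module consumes these types: the patient registration record,
the consultation (symptoms, history, physical exam, medications, labs, care
plan), educational group sessions and professional profiles.  Records are
pydantic models so each document is validated on construction and has a
stable JSON representation (ISO-8601 dates, UTC timestamps) suitable for
the append-only registry and the NDJSON sync format.

Coded vocabularies (symptoms, comorbidities, drug classes, roles) are
closed enums shipped here; free text is confined to the fields the source
system kept free (names, notes, referrals).
"""

from __future__ import annotations

import datetime as dt
import enum
import uuid
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator


class Sex(str, enum.Enum):
    female = "female"
    male = "male"


class Diagnosis(str, enum.Enum):
    hypertension = "hypertension"
    diabetes = "diabetes"


class ProfessionalRole(str, enum.Enum):
    """The five professional profiles that gate application capabilities."""

    physician = "physician"
    nurse = "nurse"
    nurse_technician = "nurse_technician"
    nasf = "nasf"  # multidisciplinary support team
    chw = "chw"  # community health worker


class DrugClass(str, enum.Enum):
    ace_inhibitor = "ace_inhibitor"
    arb = "arb"
    thiazide = "thiazide"
    ccb = "ccb"
    beta_blocker = "beta_blocker"
    statin = "statin"
    metformin = "metformin"
    sulfonylurea = "sulfonylurea"
    insulin = "insulin"
    other = "other"


ANTIHYPERTENSIVE_CLASSES = frozenset(
    {DrugClass.ace_inhibitor, DrugClass.arb, DrugClass.thiazide, DrugClass.ccb,
     DrugClass.beta_blocker}
)

# First-line antihypertensive groups for uncomplicated hypertension.
FIRST_LINE_ANTIHYPERTENSIVES = frozenset(
    {DrugClass.ace_inhibitor, DrugClass.arb, DrugClass.thiazide, DrugClass.ccb}
)


class Symptom(str, enum.Enum):
    headache = "headache"
    dizziness = "dizziness"
    chest_pain = "chest_pain"
    dyspnea = "dyspnea"
    polyuria = "polyuria"
    polydipsia = "polydipsia"
    blurred_vision = "blurred_vision"
    paresthesia = "paresthesia"
    edema = "edema"
    asymptomatic = "asymptomatic"


class Comorbidity(str, enum.Enum):
    smoking = "smoking"
    obesity = "obesity"
    dyslipidemia = "dyslipidemia"
    coronary_disease = "coronary_disease"
    stroke = "stroke"
    heart_failure = "heart_failure"
    chronic_kidney_disease = "chronic_kidney_disease"
    peripheral_artery_disease = "peripheral_artery_disease"


class GroupType(str, enum.Enum):
    hypertension = "hypertension"
    diabetes = "diabetes"
    smoking = "smoking"
    nutrition = "nutrition"


class FootExamResult(str, enum.Enum):
    normal = "normal"
    altered_sensitivity = "altered_sensitivity"
    ulcer = "ulcer"
    amputation = "amputation"
    not_performed = "not_performed"


class ValidationFailure(ValueError):
    """A record violates a hard invariant (as opposed to a soft warning)."""


class Medication(BaseModel):
    model_config = ConfigDict(validate_assignment=True)

    drug_name: str
    drug_class: DrugClass
    daily_dose_mg: float = Field(ge=0)
    active: bool = True

    @field_validator("drug_name")
    @classmethod
    def _normalize_name(cls, v: str) -> str:
        return v.strip().lower()


class BloodPressure(BaseModel):
    """One blood-pressure reading in mmHg."""

    systolic: float = Field(gt=0)
    diastolic: float = Field(gt=0)


class PhysicalExam(BaseModel):
    """Exam block; BP may be recorded in up to three positions."""

    bp_sitting: Optional[BloodPressure] = None
    bp_lying: Optional[BloodPressure] = None
    bp_standing: Optional[BloodPressure] = None
    weight_kg: Optional[float] = Field(default=None, gt=0)
    height_m: Optional[float] = Field(default=None, gt=0)
    waist_cm: Optional[float] = Field(default=None, gt=0)
    foot_exam: Optional[FootExamResult] = None

    def bp_readings(self) -> list[BloodPressure]:
        return [bp for bp in (self.bp_sitting, self.bp_lying, self.bp_standing)
                if bp is not None]


class LabPanel(BaseModel):
    """Laboratory results; every analyte optional, each with its own date."""

    date: Optional[dt.date] = None
    serum_creatinine: Optional[float] = Field(default=None, gt=0)  # mg/dL
    total_cholesterol: Optional[float] = Field(default=None, gt=0)  # mg/dL
    hdl_cholesterol: Optional[float] = Field(default=None, gt=0)  # mg/dL
    fasting_glucose: Optional[float] = Field(default=None, gt=0)  # mg/dL
    hba1c: Optional[float] = Field(default=None, gt=0)  # %
    fundoscopy_date: Optional[dt.date] = None


class CarePlan(BaseModel):
    nonpharmacological: list[str] = Field(default_factory=list)
    exams_requested: list[str] = Field(default_factory=list)
    referral: Optional[str] = None  # physician-only
    prescriptions: list[Medication] = Field(default_factory=list)  # physician-only
    next_consultation_date: Optional[dt.date] = None


class Consultation(BaseModel):
    model_config = ConfigDict(validate_assignment=True)

    consultation_id: str
    patient_id: str
    date: dt.date
    professional_role: ProfessionalRole
    symptoms: list[Symptom] = Field(default_factory=list)
    medical_history: list[Comorbidity] = Field(default_factory=list)
    physical_exam: PhysicalExam = Field(default_factory=PhysicalExam)
    medications: list[Medication] = Field(default_factory=list)
    labs: LabPanel = Field(default_factory=LabPanel)
    care_plan: CarePlan = Field(default_factory=CarePlan)

    @model_validator(mode="after")
    def _role_gating(self) -> "Consultation":
        # Specialist referral and drug prescription are physician-only acts.
        if self.professional_role is not ProfessionalRole.physician:
            if self.care_plan.referral is not None or self.care_plan.prescriptions:
                raise ValueError(
                    "referral and prescriptions may only be recorded by a physician"
                )
        return self


class GroupSession(BaseModel):
    session_id: str
    patient_id: str
    group_type: GroupType
    date: dt.date
    attended: bool
    weight_kg: Optional[float] = Field(default=None, gt=0)
    waist_cm: Optional[float] = Field(default=None, gt=0)
    bp: Optional[BloodPressure] = None
    capillary_glucose: Optional[float] = Field(default=None, gt=0)  # mg/dL
    notes: str = ""


class PatientRecord(BaseModel):
    model_config = ConfigDict(validate_assignment=True)

    patient_id: str
    name: str = Field(min_length=1)
    sex: Sex
    birth_date: dt.date
    address: Optional[str] = None
    phone: Optional[str] = None
    diagnoses: set[Diagnosis] = Field(default_factory=set)
    registered_at: dt.datetime
    registering_unit: str = "unit-0"

    @model_validator(mode="after")
    def _birth_in_past(self) -> "PatientRecord":
        if self.birth_date >= self.registered_at.date():
            raise ValueError("birth_date must precede registration")
        return self

    def age_on(self, on_date: dt.date) -> int:
        """Age in completed years on `on_date`."""
        years = on_date.year - self.birth_date.year
        if (on_date.month, on_date.day) < (self.birth_date.month, self.birth_date.day):
            years -= 1
        return years


ROLE_CAPABILITIES: dict[ProfessionalRole, frozenset[str]] = {
    ProfessionalRole.physician: frozenset(
        {"register", "consult", "prescribe", "refer", "group", "lists"}),
    ProfessionalRole.nurse: frozenset({"register", "consult", "group", "lists"}),
    ProfessionalRole.nurse_technician: frozenset({"register", "consult", "group"}),
    ProfessionalRole.nasf: frozenset({"consult", "group"}),
    ProfessionalRole.chw: frozenset({"register", "group"}),
}


class ProfessionalProfile(BaseModel):
    user_id: str
    role: ProfessionalRole

    @property
    def permissions(self) -> frozenset[str]:
        # Capability set is a pure function of role.
        return ROLE_CAPABILITIES[self.role]


def register_patient(
    *,
    name: str,
    sex: Sex | str,
    birth_date: dt.date | str,
    address: Optional[str] = None,
    phone: Optional[str] = None,
    diagnoses: Optional[set[Diagnosis]] = None,
    registered_at: Optional[dt.datetime] = None,
    registering_unit: str = "unit-0",
    patient_id: Optional[str] = None,
    existing_ids: Optional[set[str]] = None,
) -> PatientRecord:
    """Create a new patient record with a fresh unique identification code.

    Parameters mirror the registration screen: demographics plus optional
    address and telephone.  ``existing_ids`` lets a caller (the registry)
    enforce uniqueness when an explicit ``patient_id`` is forced.

    Raises
    ------
    ValidationFailure
        On a duplicate forced id, a missing required field, or a birth date
        that is not in the past.
    """
    if patient_id is None:
        patient_id = str(uuid.uuid4())
    if existing_ids is not None and patient_id in existing_ids:
        raise ValidationFailure(f"duplicate patient_id {patient_id!r}")
    if registered_at is None:
        registered_at = dt.datetime.now(dt.timezone.utc)
    try:
        return PatientRecord(
            patient_id=patient_id,
            name=name,
            sex=sex,
            birth_date=birth_date,
            address=address,
            phone=phone,
            diagnoses=diagnoses or set(),
            registered_at=registered_at,
            registering_unit=registering_unit,
        )
    except ValueError as exc:
        raise ValidationFailure(str(exc)) from exc


def validate_consultation(
    consultation: Consultation, patient: PatientRecord
) -> list[str]:
    """Return non-blocking completeness warnings for a consultation.

    Few fields are mandatory; instead the application alerts the
    professional to information worth completing.  A warning never blocks
    saving.  Hard domain violations (negative blood pressure, consultation
    before registration) are raised by the model validators or here as
    :class:`ValidationFailure`, not returned as warnings.
    """
    if consultation.date < patient.registered_at.date():
        raise ValidationFailure("consultation predates patient registration")

    warnings: list[str] = []
    exam = consultation.physical_exam
    if not exam.bp_readings():
        warnings.append("no blood pressure recorded")
    elif len(exam.bp_readings()) == 1:
        warnings.append("blood pressure recorded in only one position")
    if exam.weight_kg is None or exam.height_m is None:
        warnings.append("weight/height missing: BMI cannot be computed")
    if exam.waist_cm is None:
        warnings.append("waist circumference missing")
    if Diagnosis.diabetes in patient.diagnoses:
        if exam.foot_exam is None or exam.foot_exam is FootExamResult.not_performed:
            warnings.append("foot examination missing in patient with diabetes")
        if consultation.labs.hba1c is None:
            warnings.append("HbA1c missing in patient with diabetes")
    if consultation.labs.serum_creatinine is None:
        warnings.append("serum creatinine missing: eGFR cannot be computed")
    if not consultation.symptoms:
        warnings.append("no symptoms recorded (use 'asymptomatic' if none)")
    return warnings


def carry_forward(
    previous: Optional[Consultation],
    new_date: dt.date,
    *,
    consultation_id: Optional[str] = None,
    professional_role: ProfessionalRole = ProfessionalRole.physician,
) -> Consultation:
    """Pre-fill a draft consultation from the previous one.

    Active medications and the medical history carry forward so they need
    not be re-entered; per-visit measurements (exam, labs, symptoms) do
    not.  With no previous consultation the draft is empty.
    """
    if consultation_id is None:
        consultation_id = str(uuid.uuid4())
    if previous is None:
        return Consultation(
            consultation_id=consultation_id,
            patient_id="",
            date=new_date,
            professional_role=professional_role,
        )
    return Consultation(
        consultation_id=consultation_id,
        patient_id=previous.patient_id,
        date=new_date,
        professional_role=professional_role,
        medical_history=list(previous.medical_history),
        medications=[m.model_copy() for m in previous.medications if m.active],
    )


def patient_json_schema() -> dict:
    """JSON Schema for patient documents (shipped interface contract)."""
    return PatientRecord.model_json_schema()


def consultation_json_schema() -> dict:
    return Consultation.model_json_schema()
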