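import datetime as dt

import pytest

from cdss.records import (
    BloodPressure, Comorbidity, Consultation, Diagnosis, DrugClass, LabPanel,
    Medication, PatientRecord, PhysicalExam, ProfessionalRole, Sex, Symptom,
)

VISIT = dt.date(2019, 3, 1)
REGISTERED = dt.datetime(2018, 1, 10, 12, 0, tzinfo=dt.timezone.utc)


def make_patient(pid="p1", *, sex=Sex.female, age=55, diagnoses=frozenset(),
                 registered_at=REGISTERED) -> PatientRecord:
    return PatientRecord(
        patient_id=pid,
        name=f"test-{pid}",
        sex=sex,
        birth_date=VISIT - dt.timedelta(days=int(age * 365.25) + 40),
        diagnoses=set(diagnoses),
        registered_at=registered_at,
    )


def make_consultation(pid="p1", cid="c1", *, date=VISIT,
                      role=ProfessionalRole.physician,
                      sbp=120.0, dbp=75.0, weight=70.0, height=1.65,
                      meds=(), creatinine=None, total_chol=None, hdl=None,
                      smoker=False, fundoscopy_date=None) -> Consultation:
    return Consultation(
        consultation_id=cid,
        patient_id=pid,
        date=date,
        professional_role=role,
        symptoms=[Symptom.asymptomatic],
        medical_history=[Comorbidity.smoking] if smoker else [],
        physical_exam=PhysicalExam(
            bp_sitting=BloodPressure(systolic=sbp, diastolic=dbp),
            weight_kg=weight, height_m=height, waist_cm=90.0,
        ),
        medications=list(meds),
        labs=LabPanel(date=date, serum_creatinine=creatinine,
                      total_cholesterol=total_chol, hdl_cholesterol=hdl,
                      fundoscopy_date=fundoscopy_date),
    )


def med(name, cls, dose) -> Medication:
    return Medication(drug_name=name, drug_class=DrugClass(cls),
                      daily_dose_mg=dose)


@pytest.fixture
def patient():
    return make_patient()


@pytest.fixture
def consultation():
    return make_consultation()
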