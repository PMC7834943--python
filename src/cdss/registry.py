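"""Local-first registry, synchronization and indicator reporting.

Each health unit runs against a local registry that works with no
internet connection: an append-only log of versioned documents (patients,
consultations, educational-group sessions).  Edits never mutate in place
— they append a superseding version — so small connection drops cannot
lose data.  When a connection (or a portable storage device) is
available, the unit packages everything newer than the last sync into an
NDJSON batch and the central pool merges it.  Merging is idempotent and
commutative: replaying a batch is a no-op, batches from different units
can arrive in any order, and conflicting versions of one document resolve
last-writer-wins by version timestamp with the losers retained in
history.

On top of the store sit the patient-management reports: indicator-driven
patient lists (the same predicate vocabulary as the decision rules) and
the cohort summary with the registry's diagnosis mix.
"""

from __future__ import annotations

import datetime as dt
import io
import json
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Any, Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .records import Consultation, Diagnosis, GroupSession, PatientRecord, Sex
from .rules import (
    NotEvaluable, Thresholds, build_patient_state, compile_condition,
    condition_holds,
)

_KIND_MODEL = {
    "patient": PatientRecord,
    "consultation": Consultation,
    "group_session": GroupSession,
}


def _doc_kind_and_id(doc: Any) -> tuple[str, str]:
    if isinstance(doc, PatientRecord):
        return "patient", doc.patient_id
    if isinstance(doc, Consultation):
        return "consultation", doc.consultation_id
    if isinstance(doc, GroupSession):
        return "group_session", doc.session_id
    raise TypeError(f"unsupported document type {type(doc).__name__}")


class RegistryError(ValueError):
    pass


@dataclass(frozen=True)
class Envelope:
    """One versioned document in the append-only log / sync stream."""

    kind: str
    doc_id: str
    version: int
    unit_id: str
    updated_at: str  # ISO-8601 UTC timestamp; drives last-writer-wins
    payload: dict

    @property
    def identity(self) -> tuple:
        return (self.unit_id, self.kind, self.doc_id, self.version,
                self.updated_at)

    def to_json(self) -> str:
        return json.dumps({
            "kind": self.kind, "doc_id": self.doc_id,
            "version": self.version, "unit_id": self.unit_id,
            "updated_at": self.updated_at, "payload": self.payload,
        }, sort_keys=True)

    @classmethod
    def from_json(cls, line: str) -> "Envelope":
        d = json.loads(line)
        return cls(kind=d["kind"], doc_id=d["doc_id"], version=d["version"],
                   unit_id=d["unit_id"], updated_at=d["updated_at"],
                   payload=d["payload"])

    def document(self):
        return _KIND_MODEL[self.kind].model_validate(self.payload)


@dataclass
class SyncBatch:
    unit_id: str
    batch_id: int
    created_at: str
    records: list[Envelope] = field(default_factory=list)

    def to_ndjson(self) -> str:
        header = json.dumps({"unit_id": self.unit_id,
                             "batch_id": self.batch_id,
                             "created_at": self.created_at})
        return "\n".join([header] + [e.to_json() for e in self.records]) + "\n"

    @classmethod
    def from_ndjson(cls, text: str) -> "SyncBatch":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        head = json.loads(lines[0])
        return cls(unit_id=head["unit_id"], batch_id=head["batch_id"],
                   created_at=head["created_at"],
                   records=[Envelope.from_json(ln) for ln in lines[1:]])


def _latest(envelopes: Iterable[Envelope]) -> dict[tuple[str, str], Envelope]:
    """Latest version per (kind, doc_id); deterministic last-writer-wins.

    Ordering key is (updated_at, unit_id, version) so concurrent edits
    from different units resolve identically regardless of merge order.
    """
    best: dict[tuple[str, str], Envelope] = {}
    for env in envelopes:
        key = (env.kind, env.doc_id)
        cur = best.get(key)
        if cur is None or (env.updated_at, env.unit_id, env.version) > (
                cur.updated_at, cur.unit_id, cur.version):
            best[key] = env
    return best


class Registry:
    """Append-only store for one health unit."""

    def __init__(self, unit_id: str = "unit-0") -> None:
        self.unit_id = unit_id
        self.log: list[Envelope] = []
        self._clock = 0
        # Incremental indexes; the log itself stays the source of truth.
        self._patient_ids: set[str] = set()
        self._version_counts: dict[tuple[str, str], int] = {}
        self._docs_cache: Optional[tuple[int, dict]] = None

    # -- write path ---------------------------------------------------

    def _next_timestamp(self) -> str:
        # Logical clock folded into the timestamp keeps versions from one
        # unit totally ordered even within one wall-clock second.
        self._clock += 1
        base = dt.datetime(2000, 1, 1, tzinfo=dt.timezone.utc)
        return (base + dt.timedelta(seconds=self._clock)).isoformat()

    def append(self, doc: Union[PatientRecord, Consultation, GroupSession],
               *, updated_at: Optional[str] = None) -> Envelope:
        """Append a document (or a superseding version of one).

        Consultations and group sessions must reference a registered
        patient; prior versions of an edited document stay in the log.
        """
        kind, doc_id = _doc_kind_and_id(doc)
        if kind in ("consultation", "group_session"):
            if doc.patient_id not in self._patient_ids:
                raise RegistryError(
                    f"{kind} references unknown patient {doc.patient_id!r}")
        version = 1 + self._version_counts.get((kind, doc_id), 0)
        env = Envelope(
            kind=kind, doc_id=doc_id, version=version, unit_id=self.unit_id,
            updated_at=updated_at or self._next_timestamp(),
            payload=doc.model_dump(mode="json"),
        )
        self.log.append(env)
        self._version_counts[(kind, doc_id)] = version
        if kind == "patient":
            self._patient_ids.add(doc_id)
        return env

    # -- read path ----------------------------------------------------

    def latest(self) -> dict[tuple[str, str], Envelope]:
        return _latest(self.log)

    def _materialized(self) -> dict:
        """Latest documents deserialized once per log state, then cached."""
        if self._docs_cache is not None and self._docs_cache[0] == len(self.log):
            return self._docs_cache[1]
        latest = _latest(self.log)
        patients: dict[str, PatientRecord] = {}
        consults: dict[str, list[Consultation]] = {}
        sessions: dict[str, list[GroupSession]] = {}
        for (kind, doc_id), env in latest.items():
            doc = env.document()
            if kind == "patient":
                patients[doc_id] = doc
            elif kind == "consultation":
                consults.setdefault(doc.patient_id, []).append(doc)
            else:
                sessions.setdefault(doc.patient_id, []).append(doc)
        for lst in consults.values():
            lst.sort(key=lambda c: (c.date, c.consultation_id))
        for lst in sessions.values():
            lst.sort(key=lambda s: (s.date, s.session_id))
        views = {"patients": patients, "consultations": consults,
                 "group_sessions": sessions}
        self._docs_cache = (len(self.log), views)
        return views

    def patient_ids(self) -> set[str]:
        return set(self._patient_ids)

    def patients(self) -> list[PatientRecord]:
        return [p for _, p in sorted(self._materialized()["patients"].items())]

    def consultations(self, patient_id: Optional[str] = None) -> list[Consultation]:
        by_patient = self._materialized()["consultations"]
        if patient_id is not None:
            return list(by_patient.get(patient_id, []))
        return sorted((c for lst in by_patient.values() for c in lst),
                      key=lambda c: (c.date, c.consultation_id))

    def group_sessions(self, patient_id: Optional[str] = None) -> list[GroupSession]:
        by_patient = self._materialized()["group_sessions"]
        if patient_id is not None:
            return list(by_patient.get(patient_id, []))
        return sorted((s for lst in by_patient.values() for s in lst),
                      key=lambda s: (s.date, s.session_id))

    def versions(self, kind: str, doc_id: str) -> list[Envelope]:
        return [e for e in self.log if e.kind == kind and e.doc_id == doc_id]

    # -- persistence / sync -------------------------------------------

    def to_ndjson(self) -> str:
        return "".join(e.to_json() + "\n" for e in self.log)

    @classmethod
    def from_ndjson(cls, text: str, unit_id: Optional[str] = None) -> "Registry":
        reg = cls(unit_id or "unit-0")
        for line in text.splitlines():
            if line.strip():
                env = Envelope.from_json(line)
                reg.log.append(env)
                reg._version_counts[(env.kind, env.doc_id)] = max(
                    reg._version_counts.get((env.kind, env.doc_id), 0),
                    env.version)
                if env.kind == "patient":
                    reg._patient_ids.add(env.doc_id)
                if unit_id is None:
                    reg.unit_id = env.unit_id
        reg._clock = len(reg.log)
        return reg

    def make_sync_batch(self, since: int = 0, *, batch_id: Optional[int] = None
                        ) -> SyncBatch:
        """Package every log entry after position ``since`` for the pool."""
        return SyncBatch(
            unit_id=self.unit_id,
            batch_id=batch_id if batch_id is not None else since,
            created_at=self._next_timestamp(),
            records=list(self.log[since:]),
        )


class CentralPool:
    """Central database receiving batches from every unit."""

    def __init__(self, known_units: Optional[Iterable[str]] = None) -> None:
        self.known_units: Optional[set[str]] = (
            set(known_units) if known_units is not None else None)
        self._envelopes: dict[tuple, Envelope] = {}  # identity -> envelope
        self.quarantine: list[SyncBatch] = []

    def merge_batch(self, batch: SyncBatch) -> int:
        """Merge a batch; returns the number of new envelopes applied.

        Idempotent (re-applying is a no-op) and commutative across units.
        A batch from an unknown unit is quarantined, never silently
        dropped.
        """
        if self.known_units is not None and batch.unit_id not in self.known_units:
            self.quarantine.append(batch)
            return 0
        applied = 0
        for env in batch.records:
            if env.identity not in self._envelopes:
                self._envelopes[env.identity] = env
                applied += 1
        return applied

    def all_envelopes(self) -> list[Envelope]:
        return [self._envelopes[k] for k in sorted(self._envelopes)]

    def latest(self) -> dict[tuple[str, str], Envelope]:
        return _latest(self._envelopes.values())

    def history(self, kind: str, doc_id: str) -> list[Envelope]:
        """Every retained version of a document, superseded ones included."""
        return sorted(
            (e for e in self._envelopes.values()
             if e.kind == kind and e.doc_id == doc_id),
            key=lambda e: (e.updated_at, e.unit_id, e.version))

    def snapshot(self) -> set[tuple]:
        return set(self._envelopes)


# ---------------------------------------------------------------------------
# Flat export for the analysis team
# ---------------------------------------------------------------------------

EXPORT_COLUMNS = [
    "unit_id", "patient_id", "consultation_id", "consultation_date",
    "professional_role", "name", "sex", "birth_date", "age_at_consultation",
    "hypertension", "diabetes", "systolic_bp", "diastolic_bp", "weight_kg",
    "height_m", "waist_cm", "serum_creatinine", "total_cholesterol",
    "hdl_cholesterol", "fasting_glucose", "hba1c",
]


def export_central(pool_or_registry: Union[CentralPool, Registry]) -> pd.DataFrame:
    """One flat row per consultation, joined with patient scalars.

    Column order is ``EXPORT_COLUMNS``, stable across releases; scalar
    fields round-trip losslessly through CSV.
    """
    latest = pool_or_registry.latest()
    patients = {doc_id: env.document() for (kind, doc_id), env in latest.items()
                if kind == "patient"}
    rows = []
    for (kind, _), env in sorted(latest.items()):
        if kind != "consultation":
            continue
        c: Consultation = env.document()
        p = patients.get(c.patient_id)
        exam = c.physical_exam
        readings = exam.bp_readings()
        rows.append({
            "unit_id": env.unit_id,
            "patient_id": c.patient_id,
            "consultation_id": c.consultation_id,
            "consultation_date": c.date.isoformat(),
            "professional_role": c.professional_role.value,
            "name": p.name if p else None,
            "sex": p.sex.value if p else None,
            "birth_date": p.birth_date.isoformat() if p else None,
            "age_at_consultation": p.age_on(c.date) if p else None,
            "hypertension": (Diagnosis.hypertension in p.diagnoses) if p else None,
            "diabetes": (Diagnosis.diabetes in p.diagnoses) if p else None,
            "systolic_bp": max((r.systolic for r in readings), default=None),
            "diastolic_bp": max((r.diastolic for r in readings), default=None),
            "weight_kg": exam.weight_kg,
            "height_m": exam.height_m,
            "waist_cm": exam.waist_cm,
            "serum_creatinine": c.labs.serum_creatinine,
            "total_cholesterol": c.labs.total_cholesterol,
            "hdl_cholesterol": c.labs.hdl_cholesterol,
            "fasting_glucose": c.labs.fasting_glucose,
            "hba1c": c.labs.hba1c,
        })
    df = pd.DataFrame(rows, columns=EXPORT_COLUMNS)
    return df.sort_values(["patient_id", "consultation_date", "consultation_id"],
                          ignore_index=True) if len(df) else df


def export_central_csv(pool_or_registry: Union[CentralPool, Registry]) -> str:
    buf = io.StringIO()
    export_central(pool_or_registry).to_csv(buf, index=False)
    return buf.getvalue()


def import_central_csv(text: str) -> pd.DataFrame:
    return pd.read_csv(io.StringIO(text), dtype={"patient_id": str,
                                                 "consultation_id": str})


# ---------------------------------------------------------------------------
# Indicators and the cohort summary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IndicatorDefinition:
    """A monitoring indicator: a predicate over latest patient state."""

    indicator_id: str
    condition: dict
    description: str = ""

    def __post_init__(self) -> None:
        compile_condition(self.condition, rule_id=self.indicator_id)


DEFAULT_INDICATORS: dict[str, IndicatorDefinition] = {
    ind.indicator_id: ind for ind in [
        IndicatorDefinition(
            "diabetes_fundoscopy_overdue",
            {"all": [{"pred": "has_diabetes"}, {"pred": "fundoscopy_overdue"}]},
            "Patients with diabetes without fundoscopic assessment in the last year"),
        IndicatorDefinition(
            "uncontrolled_bp",
            {"pred": "bp_uncontrolled"},
            "Patients whose latest blood pressure is above goal"),
        IndicatorDefinition(
            "high_cv_risk_without_statin",
            {"all": [{"pred": "risk_pct", "op": "gt", "value": 20},
                     {"not": {"pred": "on_statin"}}]},
            "High 10-year cardiovascular risk without statin therapy"),
        IndicatorDefinition(
            "reduced_renal_function",
            {"pred": "egfr", "op": "lt", "value": 60},
            "Patients with eGFR below 60 mL/min/1.73m2"),
    ]
}


def latest_patient_state(registry: Registry, patient: PatientRecord,
                         thresholds: Thresholds = Thresholds()) -> Optional[dict]:
    consults = registry.consultations(patient.patient_id)
    if not consults:
        return None
    latest = consults[-1]
    return build_patient_state(
        patient, latest, history=consults[:-1],
        group_sessions=registry.group_sessions(patient.patient_id),
        thresholds=thresholds)


def patient_list(registry: Registry, indicator: IndicatorDefinition,
                 thresholds: Thresholds = Thresholds()) -> list[str]:
    """Ids of patients whose latest state satisfies the indicator, sorted.

    Patients with no consultation yet, or whose state lacks a value the
    predicate needs, do not qualify.
    """
    out = []
    for patient in registry.patients():
        state = latest_patient_state(registry, patient, thresholds)
        if state is None:
            continue
        try:
            if condition_holds(indicator.condition, state, thresholds):
                out.append(patient.patient_id)
        except NotEvaluable:
            continue
    return sorted(out)


def _pct(numerator: int, denominator: int) -> Optional[float]:
    """Percentage with half-up rounding at two decimals (printed convention)."""
    if denominator == 0:
        return None
    q = Decimal(100 * numerator) / Decimal(denominator)
    return float(q.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def cohort_summary(registry: Union[Registry, CentralPool]) -> dict[str, Any]:
    """Counts and percentages describing the registered cohort.

    Ages are taken at each patient's latest consultation (registration
    date if none); median and quartiles use linear interpolation.
    """
    latest = registry.latest()
    patients = [env.document() for (kind, _), env in latest.items()
                if kind == "patient"]
    consults = [env.document() for (kind, _), env in latest.items()
                if kind == "consultation"]
    last_consult: dict[str, dt.date] = {}
    for c in consults:
        cur = last_consult.get(c.patient_id)
        if cur is None or c.date > cur:
            last_consult[c.patient_id] = c.date

    n = len(patients)
    n_htn = sum(Diagnosis.hypertension in p.diagnoses for p in patients)
    n_dm = sum(Diagnosis.diabetes in p.diagnoses for p in patients)
    n_both = sum(Diagnosis.hypertension in p.diagnoses
                 and Diagnosis.diabetes in p.diagnoses for p in patients)
    n_female = sum(p.sex is Sex.female for p in patients)
    ages = [p.age_on(last_consult.get(p.patient_id, p.registered_at.date()))
            for p in patients]

    summary: dict[str, Any] = {
        "patients": n,
        "consultations": len(consults),
        "hypertension_n": n_htn,
        "hypertension_pct": _pct(n_htn, n),
        "diabetes_n": n_dm,
        "diabetes_pct": _pct(n_dm, n),
        "both_n": n_both,
        "both_pct": _pct(n_both, n),
        "female_n": n_female,
        "female_pct": _pct(n_female, n),
        "age_median": float(np.median(ages)) if ages else None,
        "age_q1": float(np.percentile(ages, 25)) if ages else None,
        "age_q3": float(np.percentile(ages, 75)) if ages else None,
    }
    return summary
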