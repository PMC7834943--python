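"""Declarative decision-support rule engine.

A rule bank is an ordered list of rules, each a boolean condition over a
closed predicate vocabulary plus a short tailored message (with auxiliary
detail text and an evidence reference).  Evaluating a bank against the
assembled patient state yields the recommendations whose conditions hold,
after conflict resolution (within a conflict group, the recommendation
with the best level of evidence wins) and ordered by severity with red
flags first.

The condition language is deliberately tiny — conjunction, disjunction,
negation over ``{"pred": <name>, "op": <cmp>, "value": <scalar>}`` leaves —
so clinical content stays auditable and the engine can be checked against
a brute-force evaluator.  Clinical cutoffs (metformin maximum dose,
thiazide eGFR cutoff, fundoscopy interval, …) live in a named constants
table and are referenced from conditions as ``"$name"``, keeping every
threshold in one documented place.

A condition that touches a value absent from the record (e.g. eGFR with
no creatinine result) makes the rule *not evaluable*: it is skipped and
reported, never raised.
"""

from __future__ import annotations

import json
import os
import re
from dataclasses import dataclass, field, asdict
from typing import Any, Iterable, Mapping, Optional, Sequence, Union

from pydantic import BaseModel, Field, field_validator, model_validator

from . import calculators
from .calculators import (
    BpStatus, CalculatorError, FraminghamVariant, RiskProfile,
    ckd_stage, classify_bp, compute_bmi, compute_egfr, framingham_risk,
    risk_category,
)
from .records import (
    ANTIHYPERTENSIVE_CLASSES, Consultation, Diagnosis, DrugClass,
    GroupSession, Medication, PatientRecord, Comorbidity,
)

SEVERITIES = ("red_flag", "alert", "suggestion", "info")
_SEVERITY_RANK = {s: i for i, s in enumerate(SEVERITIES)}

EVIDENCE_LEVELS = ("A", "B", "C", "D")
_EVIDENCE_RANK = {e: i for i, e in enumerate(EVIDENCE_LEVELS)}

_OPS = {
    "eq": lambda a, b: a == b,
    "ne": lambda a, b: a != b,
    "lt": lambda a, b: a < b,
    "le": lambda a, b: a <= b,
    "gt": lambda a, b: a > b,
    "ge": lambda a, b: a >= b,
    "in": lambda a, b: a in b,
    "not_in": lambda a, b: a not in b,
}


@dataclass(frozen=True)
class Thresholds:
    """Named clinical constants referenced from rule conditions as ``$name``.

    Each default is configuration with a guideline-citation slot, not a
    hard-coded magic number: the source system names the rules but not the
    cutoffs, so deployments can adapt them.
    """

    statin_risk_threshold_pct: float = 20.0  # 10-y CVD risk above which a statin is suggested
    thiazide_egfr_cutoff: float = 30.0  # mL/min/1.73m2; below -> thiazide contraindicated
    metformin_max_daily_mg: float = 2550.0  # maximum recommended metformin daily dose
    fundoscopy_interval_days: int = 365  # annual fundoscopic assessment for diabetes
    bp_goal_systolic: float = 140.0  # mmHg
    bp_goal_diastolic: float = 90.0  # mmHg
    group_window_days: int = 180  # look-back window for educational-group adherence
    simvastatin_max_with_amlodipine_mg: float = 20.0  # interaction dose cap

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


class NotEvaluable(Exception):
    """Condition references a value missing from the patient state."""


# ---------------------------------------------------------------------------
# Patient state: the predicate vocabulary over which conditions are written.
# ---------------------------------------------------------------------------

def _vocabulary_names() -> frozenset[str]:
    base = {
        "age", "sex", "has_hypertension", "has_diabetes", "smoker",
        "systolic_bp", "diastolic_bp", "bp_uncontrolled", "bmi", "egfr",
        "ckd_stage", "risk_pct", "risk_category",
        "n_antihypertensive_classes", "on_first_line_antihypertensive",
        "metformin_daily_dose_mg", "simvastatin_daily_dose_mg",
        "on_amlodipine", "days_since_fundoscopy", "fundoscopy_overdue",
        "missed_group_session", "days_since_last_consultation",
    }
    base.update(f"on_{c.value}" for c in DrugClass)
    return frozenset(base)


PREDICATE_VOCABULARY = _vocabulary_names()

# Placeholders usable in message templates, with display rounding applied.
PLACEHOLDERS = frozenset({
    "egfr", "risk_pct", "bmi", "ckd_stage", "ckd_stage_short",
    "systolic_bp", "diastolic_bp", "metformin_daily_dose_mg",
    "simvastatin_daily_dose_mg", "age",
})


def build_patient_state(
    patient: PatientRecord,
    consultation: Consultation,
    *,
    history: Sequence[Consultation] = (),
    group_sessions: Sequence[GroupSession] = (),
    thresholds: Thresholds = Thresholds(),
) -> dict[str, Any]:
    """Assemble the predicate vocabulary values for one consultation.

    Time-dependent predicates (days since last exam, group attendance) are
    computed against the consultation date, not the wall clock.  A value
    that cannot be derived (no creatinine → no eGFR) is ``None``, which
    the engine surfaces as "not evaluable" for rules touching it.
    """
    today = consultation.date
    age = patient.age_on(today)
    exam = consultation.physical_exam
    meds = [m for m in consultation.medications if m.active]
    classes = {m.drug_class for m in meds}
    smoker = Comorbidity.smoking in consultation.medical_history

    # Classification uses the highest reading across recorded positions
    # (conservative alerting).
    readings = exam.bp_readings()
    systolic = max((r.systolic for r in readings), default=None)
    diastolic = max((r.diastolic for r in readings), default=None)
    bp_uncontrolled: Optional[bool] = None
    if systolic is not None and diastolic is not None:
        bp_uncontrolled = classify_bp(
            systolic, diastolic,
            goal_systolic=thresholds.bp_goal_systolic,
            goal_diastolic=thresholds.bp_goal_diastolic,
        ) is BpStatus.uncontrolled

    bmi = None
    if exam.weight_kg is not None and exam.height_m is not None:
        bmi = compute_bmi(exam.weight_kg, exam.height_m)

    egfr = stage = None
    if consultation.labs.serum_creatinine is not None and age >= 18:
        egfr = compute_egfr(consultation.labs.serum_creatinine, age, patient.sex)
        stage = ckd_stage(egfr).value

    risk = category = None
    if systolic is not None:
        labs = consultation.labs
        try:
            profile = RiskProfile(
                age=age, sex=patient.sex, systolic_bp=systolic,
                bp_treated=bool(classes & ANTIHYPERTENSIVE_CLASSES),
                smoker=smoker,
                diabetic=Diagnosis.diabetes in patient.diagnoses,
                total_cholesterol=labs.total_cholesterol,
                hdl_cholesterol=labs.hdl_cholesterol,
                bmi=bmi,
            )
            variant = (FraminghamVariant.lipid
                       if labs.total_cholesterol is not None
                       and labs.hdl_cholesterol is not None
                       else FraminghamVariant.bmi)
            risk = framingham_risk(profile, variant)
            category = risk_category(risk).value
        except CalculatorError:
            pass  # out of validity range or inputs missing -> not evaluable

    # Fundoscopy recency: search the current consultation then history.
    fundo_date = consultation.labs.fundoscopy_date
    if fundo_date is None:
        for prev in sorted(history, key=lambda c: c.date, reverse=True):
            if prev.labs.fundoscopy_date is not None:
                fundo_date = prev.labs.fundoscopy_date
                break
    days_since_fundo = (today - fundo_date).days if fundo_date else None
    fundoscopy_overdue = (
        days_since_fundo is None
        or days_since_fundo > thresholds.fundoscopy_interval_days
    )

    recent_sessions = [
        s for s in group_sessions
        if 0 <= (today - s.date).days <= thresholds.group_window_days
    ]
    missed_group = any(not s.attended for s in recent_sessions)

    prior_dates = [c.date for c in history if c.date < today]
    days_since_last = (today - max(prior_dates)).days if prior_dates else None

    def dose(drug_name: str) -> float:
        return sum(m.daily_dose_mg for m in meds if m.drug_name == drug_name)

    state: dict[str, Any] = {
        "age": age,
        "sex": patient.sex.value,
        "has_hypertension": Diagnosis.hypertension in patient.diagnoses,
        "has_diabetes": Diagnosis.diabetes in patient.diagnoses,
        "smoker": smoker,
        "systolic_bp": systolic,
        "diastolic_bp": diastolic,
        "bp_uncontrolled": bp_uncontrolled,
        "bmi": bmi,
        "egfr": egfr,
        "ckd_stage": stage,
        "risk_pct": risk,
        "risk_category": category,
        "n_antihypertensive_classes": len(classes & ANTIHYPERTENSIVE_CLASSES),
        "on_first_line_antihypertensive": bool(
            classes & {DrugClass.ace_inhibitor, DrugClass.arb,
                       DrugClass.thiazide, DrugClass.ccb}),
        "metformin_daily_dose_mg": sum(
            m.daily_dose_mg for m in meds if m.drug_class is DrugClass.metformin),
        "simvastatin_daily_dose_mg": dose("simvastatin"),
        "on_amlodipine": any(m.drug_name == "amlodipine" for m in meds),
        "days_since_fundoscopy": days_since_fundo,
        "fundoscopy_overdue": fundoscopy_overdue,
        "missed_group_session": missed_group,
        "days_since_last_consultation": days_since_last,
    }
    for c in DrugClass:
        state[f"on_{c.value}"] = c in classes
    return state


# ---------------------------------------------------------------------------
# Rules and banks
# ---------------------------------------------------------------------------

class RuleBankError(ValueError):
    """Bank fails to load (unknown predicate, duplicate id, bad template)."""


class Rule(BaseModel):
    rule_id: str
    condition: dict
    message_template: str
    detail_text: str = ""
    evidence_ref: str = ""
    evidence_level: Optional[str] = None  # A (best) .. D
    severity: str = "suggestion"
    conflict_group: Optional[str] = None

    @field_validator("severity")
    @classmethod
    def _known_severity(cls, v: str) -> str:
        if v not in _SEVERITY_RANK:
            raise ValueError(f"unknown severity {v!r}")
        return v

    @field_validator("evidence_level")
    @classmethod
    def _known_level(cls, v: Optional[str]) -> Optional[str]:
        if v is not None and v not in _EVIDENCE_RANK:
            raise ValueError(f"unknown evidence level {v!r}")
        return v

    @model_validator(mode="after")
    def _conflict_needs_evidence(self) -> "Rule":
        if self.conflict_group is not None and self.evidence_level is None:
            raise ValueError(
                "evidence_level required whenever conflict_group is set")
        return self


class Recommendation(BaseModel):
    rule_id: str
    rendered_message: str
    detail_text: str = ""
    severity: str
    evidence_ref: str = ""


class RecommendationList(list):
    """Recommendations plus the ids of rules skipped as not evaluable."""

    def __init__(self, items: Iterable[Recommendation] = (),
                 not_evaluable: Sequence[str] = ()) -> None:
        super().__init__(items)
        self.not_evaluable: list[str] = list(not_evaluable)


@dataclass
class RuleBank:
    rules: list[Rule] = field(default_factory=list)
    version: str = "0"

    def __iter__(self):
        return iter(self.rules)

    def __len__(self) -> int:
        return len(self.rules)


def _validate_condition(node: Any, thresholds: Thresholds, rule_id: str) -> None:
    where = f"rule {rule_id!r}"
    if not isinstance(node, dict):
        raise RuleBankError(f"{where}: condition node must be an object")
    if "all" in node or "any" in node:
        key = "all" if "all" in node else "any"
        children = node[key]
        if not isinstance(children, list) or not children:
            raise RuleBankError(f"{where}: '{key}' needs a nonempty list")
        for child in children:
            _validate_condition(child, thresholds, rule_id)
    elif "not" in node:
        _validate_condition(node["not"], thresholds, rule_id)
    elif "pred" in node:
        pred = node["pred"]
        if pred not in PREDICATE_VOCABULARY:
            raise RuleBankError(f"{where}: unknown predicate {pred!r}")
        if "op" in node:
            if node["op"] not in _OPS:
                raise RuleBankError(f"{where}: unknown operator {node['op']!r}")
            if "value" not in node:
                raise RuleBankError(f"{where}: operator without value")
            value = node["value"]
            if isinstance(value, str) and value.startswith("$"):
                if value[1:] not in thresholds.as_dict():
                    raise RuleBankError(
                        f"{where}: unknown named constant {value!r}")
    else:
        raise RuleBankError(f"{where}: leaf must contain 'pred'")


_PLACEHOLDER_RE = re.compile(r"\{([a-z_]+)\}")


def _validate_template(template: str, rule_id: str) -> None:
    for name in _PLACEHOLDER_RE.findall(template):
        if name not in PLACEHOLDERS:
            raise RuleBankError(
                f"rule {rule_id!r}: unexpandable placeholder {{{name}}}")


def compile_condition(condition: dict,
                      thresholds: Thresholds = Thresholds(),
                      rule_id: str = "<anonymous>") -> dict:
    """Validate a condition tree against the vocabulary; returns it unchanged."""
    _validate_condition(condition, thresholds, rule_id)
    return condition


def load_rule_bank(source: Union[str, "os.PathLike[str]", dict],
                   thresholds: Thresholds = Thresholds()) -> RuleBank:
    """Load and validate a rule bank; all-or-nothing.

    ``source`` is a path to a bank JSON document or an already-parsed dict
    with keys ``version`` and ``rules``.
    """
    if isinstance(source, dict):
        doc = source
    else:
        with open(source, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
    rules: list[Rule] = []
    seen: set[str] = set()
    for raw in doc.get("rules", []):
        try:
            rule = Rule.model_validate(raw)
        except Exception as exc:
            raise RuleBankError(
                f"rule {raw.get('rule_id', '<missing id>')!r}: {exc}") from exc
        if rule.rule_id in seen:
            raise RuleBankError(f"duplicate rule_id {rule.rule_id!r}")
        seen.add(rule.rule_id)
        _validate_condition(rule.condition, thresholds, rule.rule_id)
        _validate_template(rule.message_template, rule.rule_id)
        rules.append(rule)
    return RuleBank(rules=rules, version=str(doc.get("version", "0")))


def default_rule_bank(thresholds: Thresholds = Thresholds()) -> RuleBank:
    """The shipped bank: the documented exemplar reminders and suggestions."""
    from importlib import resources
    text = resources.files("cdss.data").joinpath("default_rules.json").read_text()
    return load_rule_bank(json.loads(text), thresholds)


def _eval_condition(node: dict, state: Mapping[str, Any],
                    thresholds: Thresholds) -> bool:
    if "all" in node:
        return all(_eval_condition(c, state, thresholds) for c in node["all"])
    if "any" in node:
        return any(_eval_condition(c, state, thresholds) for c in node["any"])
    if "not" in node:
        return not _eval_condition(node["not"], state, thresholds)
    value = state.get(node["pred"])
    if value is None:
        raise NotEvaluable(node["pred"])
    if "op" not in node:
        return bool(value)
    target = node["value"]
    if isinstance(target, str) and target.startswith("$"):
        target = thresholds.as_dict()[target[1:]]
    return _OPS[node["op"]](value, target)


def condition_holds(condition: dict, state: Mapping[str, Any],
                    thresholds: Thresholds = Thresholds()) -> bool:
    """Evaluate one condition; raises :class:`NotEvaluable` on missing data."""
    return _eval_condition(condition, state, thresholds)


def resolve_conflicts(fired: Sequence[Rule]) -> list[Rule]:
    """Keep, within each conflict group, the rule with the best evidence.

    Best = highest ordinal level (A over B over C over D); ties broken by
    lowest rule_id so the outcome is deterministic.  Rules outside any
    conflict group pass through; input order is preserved.
    """
    winners: dict[str, Rule] = {}
    for rule in fired:
        g = rule.conflict_group
        if g is None:
            continue
        best = winners.get(g)
        key = (_EVIDENCE_RANK[rule.evidence_level], rule.rule_id)
        if best is None or key < (_EVIDENCE_RANK[best.evidence_level], best.rule_id):
            winners[g] = rule
    return [r for r in fired
            if r.conflict_group is None or winners[r.conflict_group] is r]


def _display_values(state: Mapping[str, Any]) -> dict[str, Any]:
    out: dict[str, Any] = {}
    for name in PLACEHOLDERS:
        if name == "ckd_stage_short":
            stage = state.get("ckd_stage")
            out[name] = stage[1:] if stage else None  # "G3a" -> "3a"
        else:
            value = state.get(name)
            if value is None:
                out[name] = None
            elif name == "egfr":
                out[name] = calculators.display_egfr(value)
            elif name in ("risk_pct", "bmi"):
                out[name] = round(value, 1)
            elif isinstance(value, float) and value == int(value):
                out[name] = int(value)
            else:
                out[name] = value
    return out


def render_message(rule: Rule, state: Mapping[str, Any]) -> str:
    """Expand template placeholders with display-rounded state values."""
    values = _display_values(state)
    needed = _PLACEHOLDER_RE.findall(rule.message_template)
    for name in needed:
        if values.get(name) is None:
            raise NotEvaluable(name)
    return rule.message_template.format(**{n: values[n] for n in needed})


def evaluate_rules(bank: RuleBank, state: Mapping[str, Any],
                   thresholds: Thresholds = Thresholds()) -> RecommendationList:
    """Evaluate every rule against the patient state.

    Returns exactly the rules whose conditions hold, after conflict
    resolution, ordered by severity (red flags first) then rule id.  Rules
    whose condition (or message) touches missing data are skipped and
    listed in ``result.not_evaluable``.  Deterministic: identical state
    and bank give identical output.
    """
    fired: list[Rule] = []
    skipped: list[str] = []
    for rule in bank:
        try:
            if _eval_condition(rule.condition, state, thresholds):
                render_message(rule, state)  # probe placeholders
                fired.append(rule)
        except NotEvaluable:
            skipped.append(rule.rule_id)
    surviving = resolve_conflicts(fired)
    surviving.sort(key=lambda r: (_SEVERITY_RANK[r.severity], r.rule_id))
    recs = [
        Recommendation(
            rule_id=r.rule_id,
            rendered_message=render_message(r, state),
            detail_text=r.detail_text,
            severity=r.severity,
            evidence_ref=r.evidence_ref,
        )
        for r in surviving
    ]
    return RecommendationList(recs, not_evaluable=sorted(skipped))
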