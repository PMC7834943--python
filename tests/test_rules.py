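"""Rule engine: bank loading, golden scenarios, conflicts, oracle equivalence."""

import datetime as dt
import itertools
import random

import pytest

from cdss.records import DrugClass
from cdss.rules import (
    EVIDENCE_LEVELS, PREDICATE_VOCABULARY, NotEvaluable, Rule, RuleBank,
    RuleBankError, Thresholds, build_patient_state, condition_holds,
    default_rule_bank, evaluate_rules, load_rule_bank, render_message,
    resolve_conflicts,
)
from cdss.synthetic import exemplar_scenarios
from conftest import make_consultation, make_patient


# ---------------------------------------------------------------------------
# Independent brute-force oracle (kept deliberately naive)
# ---------------------------------------------------------------------------

_SEV_ORDER = {"red_flag": 0, "alert": 1, "suggestion": 2, "info": 3}
_EV_ORDER = {"A": 0, "B": 1, "C": 2, "D": 3}


def oracle_leaf(node, state, constants):
    value = state[node["pred"]]
    if value is None:
        raise NotEvaluable(node["pred"])
    if "op" not in node:
        return bool(value)
    target = node["value"]
    if isinstance(target, str) and target.startswith("$"):
        target = constants[target[1:]]
    op = node["op"]
    if op == "eq":
        return value == target
    if op == "ne":
        return value != target
    if op == "lt":
        return value < target
    if op == "le":
        return value <= target
    if op == "gt":
        return value > target
    if op == "ge":
        return value >= target
    if op == "in":
        return value in target
    if op == "not_in":
        return value not in target
    raise AssertionError(f"unknown op {op}")


def oracle_condition(node, state, constants):
    if "all" in node:
        return all(oracle_condition(c, state, constants) for c in node["all"])
    if "any" in node:
        return any(oracle_condition(c, state, constants) for c in node["any"])
    if "not" in node:
        return not oracle_condition(node["not"], state, constants)
    return oracle_leaf(node, state, constants)


def oracle_evaluate(bank, state, thresholds=Thresholds()):
    """Test every rule independently, then resolve conflicts, then sort."""
    constants = thresholds.as_dict()
    fired, skipped = [], []
    for rule in bank:
        try:
            if oracle_condition(rule.condition, state, constants):
                fired.append(rule)
        except NotEvaluable:
            skipped.append(rule.rule_id)
    survivors = []
    for rule in fired:
        if rule.conflict_group is None:
            survivors.append(rule)
            continue
        rivals = [r for r in fired if r.conflict_group == rule.conflict_group]
        best = min(rivals, key=lambda r: (_EV_ORDER[r.evidence_level], r.rule_id))
        if best is rule:
            survivors.append(rule)
    survivors.sort(key=lambda r: (_SEV_ORDER[r.severity], r.rule_id))
    return [r.rule_id for r in survivors], sorted(skipped)


def random_state(rng: random.Random) -> dict:
    state = {
        "age": rng.randint(20, 90),
        "sex": rng.choice(["female", "male"]),
        "has_hypertension": rng.random() < 0.6,
        "has_diabetes": rng.random() < 0.3,
        "smoker": rng.random() < 0.2,
        "systolic_bp": rng.choice([None, rng.uniform(95, 200)]),
        "diastolic_bp": rng.choice([None, rng.uniform(55, 120)]),
        "bp_uncontrolled": rng.choice([None, True, False]),
        "bmi": rng.choice([None, rng.uniform(17, 45)]),
        "egfr": rng.choice([None, rng.uniform(5, 130)]),
        "ckd_stage": rng.choice([None, "G1", "G2", "G3a", "G3b", "G4", "G5"]),
        "risk_pct": rng.choice([None, rng.uniform(0, 60)]),
        "risk_category": rng.choice([None, "low", "intermediate", "high"]),
        "n_antihypertensive_classes": rng.randint(0, 4),
        "on_first_line_antihypertensive": rng.random() < 0.5,
        "metformin_daily_dose_mg": rng.choice([0.0, 850.0, 1700.0, 2550.0, 3000.0]),
        "simvastatin_daily_dose_mg": rng.choice([0.0, 20.0, 40.0]),
        "on_amlodipine": rng.random() < 0.3,
        "days_since_fundoscopy": rng.choice([None, rng.randint(0, 900)]),
        "fundoscopy_overdue": rng.random() < 0.5,
        "missed_group_session": rng.random() < 0.3,
        "days_since_last_consultation": rng.choice([None, rng.randint(1, 400)]),
    }
    for c in DrugClass:
        state[f"on_{c.value}"] = rng.random() < 0.3
    return state


_NUMERIC_PREDS = ["age", "egfr", "risk_pct", "bmi", "systolic_bp",
                  "metformin_daily_dose_mg", "n_antihypertensive_classes",
                  "days_since_fundoscopy"]
_BOOL_PREDS = ["has_hypertension", "has_diabetes", "smoker", "bp_uncontrolled",
               "on_thiazide", "on_statin", "fundoscopy_overdue",
               "missed_group_session", "on_amlodipine"]


def random_condition(rng: random.Random, depth: int = 0) -> dict:
    if depth < 2 and rng.random() < 0.4:
        kind = rng.choice(["all", "any", "not"])
        if kind == "not":
            return {"not": random_condition(rng, depth + 1)}
        return {kind: [random_condition(rng, depth + 1)
                       for _ in range(rng.randint(1, 3))]}
    if rng.random() < 0.5:
        return {"pred": rng.choice(_BOOL_PREDS)}
    pred = rng.choice(_NUMERIC_PREDS)
    op = rng.choice(["lt", "le", "gt", "ge"])
    return {"pred": pred, "op": op, "value": rng.uniform(0, 100)}


def random_bank(rng: random.Random, max_rules: int = 20) -> RuleBank:
    n = rng.randint(0, max_rules)
    groups = [None, None, "g1", "g2"]
    rules = []
    for i in range(n):
        group = rng.choice(groups)
        rules.append(Rule(
            rule_id=f"r{i:03d}",
            condition=random_condition(rng),
            message_template=f"message {i}",
            severity=rng.choice(list(_SEV_ORDER)),
            conflict_group=group,
            evidence_level=rng.choice(EVIDENCE_LEVELS) if group else None,
        ))
    return RuleBank(rules=rules)


# ---------------------------------------------------------------------------
# Bank loading
# ---------------------------------------------------------------------------

class TestLoadRuleBank:
    def test_shipped_default_bank_has_the_exemplars(self):
        bank = default_rule_bank()
        assert len(bank) >= 7
        ids = {r.rule_id for r in bank}
        assert {"statin_high_cv_risk", "thiazide_contraindicated_low_egfr",
                "metformin_above_max_dose", "fundoscopy_overdue",
                "bp_reassess_one_month", "adherence_reinforcement"} <= ids

    def test_unknown_predicate_error_names_rule(self):
        bad = {"rules": [{"rule_id": "rx", "condition": {"pred": "foo"},
                          "message_template": "m"}]}
        with pytest.raises(RuleBankError, match="rx.*foo"):
            load_rule_bank(bad)

    def test_duplicate_rule_id_rejected(self):
        rule = {"rule_id": "dup", "condition": {"pred": "smoker"},
                "message_template": "m"}
        with pytest.raises(RuleBankError, match="duplicate"):
            load_rule_bank({"rules": [rule, dict(rule)]})

    def test_unexpandable_placeholder_fails_at_load_time(self):
        bad = {"rules": [{"rule_id": "rx", "condition": {"pred": "smoker"},
                          "message_template": "value {nonsense}"}]}
        with pytest.raises(RuleBankError, match="placeholder"):
            load_rule_bank(bad)

    def test_unknown_named_constant_rejected(self):
        bad = {"rules": [{"rule_id": "rx", "message_template": "m",
                          "condition": {"pred": "egfr", "op": "lt",
                                        "value": "$no_such_cutoff"}}]}
        with pytest.raises(RuleBankError, match="constant"):
            load_rule_bank(bad)

    def test_conflict_group_requires_evidence_level(self):
        bad = {"rules": [{"rule_id": "rx", "condition": {"pred": "smoker"},
                          "message_template": "m", "conflict_group": "g"}]}
        with pytest.raises(RuleBankError, match="evidence"):
            load_rule_bank(bad)

    def test_empty_bank_is_valid(self):
        assert len(load_rule_bank({"rules": []})) == 0


# ---------------------------------------------------------------------------
# Golden exemplar scenarios
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("scenario", exemplar_scenarios(),
                         ids=lambda s: s.name)
def test_exemplar_fires_exactly_its_rule_and_control_is_silent(scenario):
    bank = default_rule_bank()
    state = build_patient_state(scenario.patient, scenario.consultation,
                                group_sessions=scenario.group_sessions)
    fired = evaluate_rules(bank, state)
    assert [r.rule_id for r in fired] == [scenario.expected_rule_id]
    control_state = build_patient_state(
        scenario.control_patient, scenario.control_consultation,
        group_sessions=scenario.control_group_sessions)
    assert list(evaluate_rules(bank, control_state)) == []


def test_stage_g3a_message_renders_stage_short_form():
    patient = make_patient(sex="female", age=70)
    # creatinine chosen so eGFR lands in 45-59 (stage G3a)
    cons = make_consultation(creatinine=1.1, sbp=128, dbp=78)
    state = build_patient_state(patient, cons)
    assert state["ckd_stage"] == "G3a"
    fired = evaluate_rules(default_rule_bank(), state)
    msgs = {r.rule_id: r.rendered_message for r in fired}
    assert "stage 3a" in msgs["ckd_stage_flag"]


def test_missing_value_makes_rule_not_evaluable_not_a_crash():
    patient = make_patient(diagnoses=set())
    cons = make_consultation(creatinine=None)  # no eGFR, no lipids
    state = build_patient_state(patient, cons)
    bank = load_rule_bank({"rules": [
        {"rule_id": "needs_egfr", "message_template": "m",
         "condition": {"pred": "egfr", "op": "lt", "value": 60}},
        {"rule_id": "always", "message_template": "m",
         "condition": {"pred": "age", "op": "ge", "value": 0}},
    ]})
    result = evaluate_rules(bank, state)
    assert result.not_evaluable == ["needs_egfr"]
    assert [r.rule_id for r in result] == ["always"]


def test_determinism_identical_output_across_runs():
    scenario = exemplar_scenarios()[0]
    state = build_patient_state(scenario.patient, scenario.consultation)
    bank = default_rule_bank()
    first = evaluate_rules(bank, state)
    second = evaluate_rules(bank, state)
    assert [r.model_dump() for r in first] == [r.model_dump() for r in second]


def test_adding_unrelated_rule_does_not_change_other_firings():
    scenario = exemplar_scenarios()[4]  # uncontrolled BP
    state = build_patient_state(scenario.patient, scenario.consultation)
    bank = default_rule_bank()
    before = {r.rule_id for r in evaluate_rules(bank, state)}
    extra = Rule(rule_id="zzz_extra", condition={"pred": "smoker"},
                 message_template="m", severity="info")
    grown = RuleBank(rules=bank.rules + [extra], version=bank.version)
    after = {r.rule_id for r in evaluate_rules(grown, state)}
    assert after - {"zzz_extra"} == before


# ---------------------------------------------------------------------------
# Conflict resolution
# ---------------------------------------------------------------------------

def _rule(rid, level, group="g"):
    return Rule(rule_id=rid, condition={"pred": "smoker"},
                message_template="m", evidence_level=level,
                conflict_group=group)


class TestResolveConflicts:
    def test_best_evidence_level_wins(self):
        a, c = _rule("r1", "A"), _rule("r2", "C")
        assert resolve_conflicts([c, a]) == [a]

    def test_single_rule_in_group_unchanged(self):
        a = _rule("r1", "B")
        assert resolve_conflicts([a]) == [a]

    def test_rules_outside_groups_pass_through(self):
        free = Rule(rule_id="r0", condition={"pred": "smoker"},
                    message_template="m")
        a, c = _rule("r1", "A"), _rule("r2", "C")
        assert resolve_conflicts([free, c, a]) == [free, a]

    def test_tie_at_best_level_keeps_lowest_rule_id(self):
        a1, a2 = _rule("r1", "A"), _rule("r2", "A")
        assert resolve_conflicts([a2, a1]) == [a1]

    def test_exhaustive_three_rule_groups_match_enumeration_oracle(self):
        for levels in itertools.product("ABCD", repeat=3):
            rules = [_rule(f"r{i}", lv) for i, lv in enumerate(levels)]
            got = resolve_conflicts(rules)
            best_rank = min(_EV_ORDER[lv] for lv in levels)
            candidates = [r for r in rules
                          if _EV_ORDER[r.evidence_level] == best_rank]
            expected = [min(candidates, key=lambda r: r.rule_id)]
            assert got == expected, levels


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

class TestRenderMessage:
    def test_template_without_placeholders_is_verbatim(self):
        rule = Rule(rule_id="r", condition={"pred": "smoker"},
                    message_template="plain text")
        assert render_message(rule, {"smoker": True}) == "plain text"

    def test_risk_placeholder_display_rounded_to_one_decimal(self):
        rule = Rule(rule_id="r", condition={"pred": "smoker"},
                    message_template="risk {risk_pct}%")
        assert render_message(rule, {"smoker": True,
                                     "risk_pct": 25.31}) == "risk 25.3%"

    def test_egfr_placeholder_display_rounded_to_integer(self):
        rule = Rule(rule_id="r", condition={"pred": "smoker"},
                    message_template="eGFR {egfr}")
        assert render_message(rule, {"smoker": True,
                                     "egfr": 57.66}) == "eGFR 58"

    def test_rendered_messages_have_no_unexpanded_placeholders(self):
        for scenario in exemplar_scenarios():
            state = build_patient_state(scenario.patient, scenario.consultation,
                                        group_sessions=scenario.group_sessions)
            for rec in evaluate_rules(default_rule_bank(), state):
                assert "{" not in rec.rendered_message


# ---------------------------------------------------------------------------
# Brute-force oracle equivalence on random instances
# ---------------------------------------------------------------------------

def test_engine_matches_brute_force_oracle_on_random_instances():
    rng = random.Random(20190301)
    for _ in range(300):
        state = random_state(rng)
        bank = random_bank(rng)
        expected_fired, expected_skipped = oracle_evaluate(bank, state)
        got = evaluate_rules(bank, state)
        assert [r.rule_id for r in got] == expected_fired
        assert got.not_evaluable == expected_skipped


def test_condition_holds_matches_oracle_on_exemplar_states():
    rng = random.Random(7)
    thresholds = Thresholds()
    for scenario in exemplar_scenarios():
        state = build_patient_state(scenario.patient, scenario.consultation,
                                    group_sessions=scenario.group_sessions)
        for _ in range(50):
            cond = random_condition(rng)
            try:
                expected = oracle_condition(cond, state, thresholds.as_dict())
            except NotEvaluable:
                with pytest.raises(NotEvaluable):
                    condition_holds(cond, state, thresholds)
                continue
            assert condition_holds(cond, state, thresholds) == expected
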