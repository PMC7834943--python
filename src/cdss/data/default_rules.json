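{
  "version": "1.0",
  "rules": [
    {
      "rule_id": "adherence_reinforcement",
      "condition": {"pred": "missed_group_session"},
      "message_template": "Reinforce the importance of adherence to treatment and participation in the educational group. Request a visit from the community health worker.",
      "detail_text": "The patient missed at least one scheduled educational group session in the recent look-back window. Structured group education improves blood-pressure and glycemic control in primary care.",
      "evidence_ref": "guideline-citation-slot: educational groups in chronic disease management",
      "evidence_level": "B",
      "severity": "info"
    },
    {
      "rule_id": "statin_high_cv_risk",
      "condition": {"all": [
        {"pred": "risk_pct", "op": "gt", "value": "$statin_risk_threshold_pct"},
        {"not": {"pred": "on_statin"}}
      ]},
      "message_template": "Cardiovascular risk greater than 20% in 10 years. The prescription of statin is suggested.",
      "detail_text": "Estimated 10-year general cardiovascular risk is {risk_pct}% by the Framingham score. Statin therapy is recommended for primary prevention at high risk.",
      "evidence_ref": "guideline-citation-slot: statins for primary prevention at 10-year risk > 20%",
      "evidence_level": "A",
      "severity": "suggestion"
    },
    {
      "rule_id": "thiazide_contraindicated_low_egfr",
      "condition": {"all": [
        {"pred": "egfr", "op": "lt", "value": "$thiazide_egfr_cutoff"},
        {"pred": "on_thiazide"}
      ]},
      "message_template": "Do not prescribe thiazide diuretic for this patient due to reduced renal function.",
      "detail_text": "Estimated GFR is {egfr} mL/min/1.73m2. Thiazide diuretics lose efficacy and may be harmful at substantially reduced renal function; consider a loop diuretic if a diuretic is needed.",
      "evidence_ref": "guideline-citation-slot: diuretic choice in chronic kidney disease",
      "evidence_level": "A",
      "severity": "red_flag"
    },
    {
      "rule_id": "add_first_line_antihypertensive",
      "condition": {"all": [
        {"pred": "has_hypertension"},
        {"pred": "bp_uncontrolled"},
        {"pred": "n_antihypertensive_classes", "op": "ge", "value": 1},
        {"pred": "n_antihypertensive_classes", "op": "le", "value": 3}
      ]},
      "message_template": "If you decide to add another anti-hypertensive, choose one of the first-line groups (ACE inhibitor, angiotensin receptor II blocker, thiazide diuretic, long-acting calcium channel blocker), taking the contraindications into account.",
      "detail_text": "Blood pressure {systolic_bp}/{diastolic_bp} mmHg remains above goal on current therapy.",
      "evidence_ref": "guideline-citation-slot: first-line antihypertensive classes",
      "evidence_level": "A",
      "severity": "suggestion"
    },
    {
      "rule_id": "metformin_above_max_dose",
      "condition": {"pred": "metformin_daily_dose_mg", "op": "gt", "value": "$metformin_max_daily_mg"},
      "message_template": "Metformin is being used at a dosage above the maximum recommendation. Dose reduction is suggested.",
      "detail_text": "Current metformin dose is {metformin_daily_dose_mg} mg/day, above the recommended maximum.",
      "evidence_ref": "guideline-citation-slot: metformin maximum daily dose",
      "evidence_level": "A",
      "severity": "alert"
    },
    {
      "rule_id": "fundoscopy_overdue",
      "condition": {"all": [
        {"pred": "has_diabetes"},
        {"pred": "fundoscopy_overdue"}
      ]},
      "message_template": "This patient did not have a fundoscopic assessment in the last year.",
      "detail_text": "Annual fundoscopic screening detects treatable diabetic retinopathy before visual loss.",
      "evidence_ref": "guideline-citation-slot: annual retinopathy screening in diabetes",
      "evidence_level": "A",
      "severity": "suggestion"
    },
    {
      "rule_id": "bp_reassess_one_month",
      "condition": {"pred": "bp_uncontrolled"},
      "message_template": "It is suggested to schedule the next consultation in one month, to reassess blood pressure levels.",
      "detail_text": "Blood pressure {systolic_bp}/{diastolic_bp} mmHg is above the patient's goal.",
      "evidence_ref": "guideline-citation-slot: follow-up interval for uncontrolled hypertension",
      "evidence_level": "B",
      "severity": "suggestion"
    },
    {
      "rule_id": "ckd_stage_flag",
      "condition": {"pred": "ckd_stage", "op": "eq", "value": "G3a"},
      "message_template": "This patient is in stage {ckd_stage_short} renal failure.",
      "detail_text": "Estimated GFR {egfr} mL/min/1.73m2 (KDIGO stage {ckd_stage}). Review nephrotoxic drugs and dose adjustments; consider nephrology referral from stage G4.",
      "evidence_ref": "guideline-citation-slot: KDIGO CKD evaluation and management",
      "evidence_level": "A",
      "severity": "red_flag"
    },
    {
      "rule_id": "simvastatin_amlodipine_interaction",
      "condition": {"all": [
        {"pred": "on_amlodipine"},
        {"pred": "simvastatin_daily_dose_mg", "op": "gt", "value": "$simvastatin_max_with_amlodipine_mg"}
      ]},
      "message_template": "Adjust the dosage of simvastatin to 20 milligrams: amlodipine may increase the serum concentration of simvastatin and thus increase the risk of adverse effects.",
      "detail_text": "Current simvastatin dose is {simvastatin_daily_dose_mg} mg/day with concomitant amlodipine.",
      "evidence_ref": "guideline-citation-slot: simvastatin dose cap with amlodipine",
      "evidence_level": "B",
      "severity": "alert"
    }
  ]
}
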