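"""Computed clinical variables and their classification layers.

Three quantities are derived from entered data and drive the decision
rules:

* **BMI** — weight/height² in kg/m².
* **eGFR** — the CKD-EPI 2009 creatinine equation,
  ``eGFR = 141 · min(Scr/κ, 1)^α · max(Scr/κ, 1)^−1.209 · 0.993^age ·
  1.018[female] (· 1.159[black, optional])``, in mL/min/1.73 m²,
  with KDIGO staging G1–G5 on top.
* **10-year cardiovascular risk** — the Framingham general-CVD sex-specific
  survival equation ``risk = 1 − S₀(10)^exp(L − L̄)``, where L is a linear
  combination of log age, log lipids (or log BMI in the office-based
  variant), log systolic pressure split by treatment status, smoking and
  diabetes, and L̄ is the cohort mean of L.

All published coefficients live in ``data/coefficients.csv`` (one row per
term) so provenance is auditable; the file is checksum-verified at import.
Calculators are pure functions; display rounding (risk to 1 decimal, eGFR
to integer, BMI to 1 decimal) is applied only by the ``display_*``
helpers, full precision is kept internally.
"""

from __future__ import annotations

import csv
import enum
import hashlib
import math
from importlib import resources
from typing import Optional, Union

from .records import Sex

_COEFFICIENTS_SHA256 = (
    "67edb3d2a69eaf8673a333a09e8c4d49e219101b15a2bdf725f93d03d49ca5bc"
)


class CalculatorError(ValueError):
    """Invalid input to a clinical calculator."""


class CkdStage(str, enum.Enum):
    G1 = "G1"
    G2 = "G2"
    G3a = "G3a"
    G3b = "G3b"
    G4 = "G4"
    G5 = "G5"


class RiskCategory(str, enum.Enum):
    low = "low"
    intermediate = "intermediate"
    high = "high"


class BpStatus(str, enum.Enum):
    controlled = "controlled"
    uncontrolled = "uncontrolled"


class FraminghamVariant(str, enum.Enum):
    lipid = "lipid"
    bmi = "bmi"


def _load_coefficients() -> dict[tuple[str, str], dict[str, float]]:
    data = resources.files("cdss.data").joinpath("coefficients.csv").read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _COEFFICIENTS_SHA256:
        raise RuntimeError(
            "coefficient table checksum mismatch: the shipped published "
            f"coefficients appear modified (got {digest})"
        )
    table: dict[tuple[str, str], dict[str, float]] = {}
    for row in csv.DictReader(data.decode().splitlines()):
        key = (row["variant"], row["sex"])
        table.setdefault(key, {})[row["term"]] = float(row["coefficient"])
    for terms in table.values():
        if not all(math.isfinite(v) for v in terms.values()):
            raise RuntimeError("non-finite coefficient in shipped table")
    return table


COEFFICIENTS = _load_coefficients()


def coefficient_set(variant: str, sex: Union[Sex, str]) -> dict[str, float]:
    """Return the named coefficient table for one published equation variant."""
    sex = Sex(sex).value if not isinstance(sex, str) or sex in ("female", "male") else sex
    merged = dict(COEFFICIENTS.get((variant, "any"), {}))
    merged.update(COEFFICIENTS[(variant, Sex(sex).value)])
    return merged


def compute_bmi(weight_kg: float, height_m: float) -> float:
    """Body-mass index in kg/m² (full precision)."""
    if weight_kg <= 0 or height_m <= 0:
        raise CalculatorError("weight and height must be positive")
    return weight_kg / height_m**2


def display_bmi(bmi: float) -> float:
    return round(bmi, 1)


def compute_egfr(
    serum_creatinine: float,
    age: float,
    sex: Union[Sex, str],
    *,
    black: bool = False,
) -> float:
    """Estimated GFR (mL/min/1.73 m²) by the CKD-EPI 2009 creatinine equation.

    The race term is off by default (race-free application); ``black=True``
    enables the published 2009 multiplier, kept configurable so the choice
    is auditable.
    """
    if serum_creatinine <= 0:
        raise CalculatorError("serum creatinine must be positive")
    if age < 18:
        raise CalculatorError("equation validated for adults (age >= 18)")
    c = coefficient_set("ckd_epi_2009", sex)
    ratio = serum_creatinine / c["kappa"]
    egfr = (
        c["scale"]
        * min(ratio, 1.0) ** c["alpha"]
        * max(ratio, 1.0) ** c["max_exponent"]
        * c["age_base"] ** age
        * c["sex_multiplier"]
    )
    if black:
        egfr *= c["race_black_multiplier"]
    return egfr


def display_egfr(egfr: float) -> int:
    return int(round(egfr))


# KDIGO bands: (stage, inclusive lower bound); exact band minimum belongs
# to the higher-function stage (60 -> G2, 45 -> G3a).
_KDIGO_BANDS = (
    (CkdStage.G1, 90.0),
    (CkdStage.G2, 60.0),
    (CkdStage.G3a, 45.0),
    (CkdStage.G3b, 30.0),
    (CkdStage.G4, 15.0),
    (CkdStage.G5, 0.0),
)


def ckd_stage(egfr: float) -> CkdStage:
    """KDIGO G-stage for an eGFR value."""
    if egfr < 0:
        raise CalculatorError("eGFR cannot be negative")
    for stage, lower in _KDIGO_BANDS:
        if egfr >= lower:
            return stage
    return CkdStage.G5


class RiskProfile:
    """Inputs to the Framingham general-CVD risk equation.

    The published validity range restricts age to 30–74 years.  Either the
    lipid pair (total and HDL cholesterol, mg/dL) or BMI must be present;
    the BMI-based variant exists precisely so risk can be estimated before
    laboratory results are available.
    """

    __slots__ = ("age", "sex", "systolic_bp", "bp_treated", "smoker",
                 "diabetic", "total_cholesterol", "hdl_cholesterol", "bmi")

    def __init__(
        self,
        *,
        age: float,
        sex: Union[Sex, str],
        systolic_bp: float,
        bp_treated: bool,
        smoker: bool,
        diabetic: bool,
        total_cholesterol: Optional[float] = None,
        hdl_cholesterol: Optional[float] = None,
        bmi: Optional[float] = None,
    ) -> None:
        if not 30 <= age <= 74:
            raise CalculatorError(
                f"age {age} outside the published validity range [30, 74]"
            )
        if systolic_bp <= 0:
            raise CalculatorError("systolic blood pressure must be positive")
        has_lipids = total_cholesterol is not None and hdl_cholesterol is not None
        if not has_lipids and bmi is None:
            raise CalculatorError("need either the lipid pair or BMI")
        self.age = float(age)
        self.sex = Sex(sex)
        self.systolic_bp = float(systolic_bp)
        self.bp_treated = bool(bp_treated)
        self.smoker = bool(smoker)
        self.diabetic = bool(diabetic)
        self.total_cholesterol = total_cholesterol
        self.hdl_cholesterol = hdl_cholesterol
        self.bmi = bmi


def framingham_risk(
    profile: RiskProfile,
    variant: Union[FraminghamVariant, str] = FraminghamVariant.lipid,
) -> float:
    """10-year general-CVD risk as a percentage in (0, 100).

    ``100 · (1 − S₀^exp(L − L̄))`` with the sex-specific published
    coefficients of the chosen variant.  The general-CVD composite covers
    coronary disease, stroke, peripheral artery disease and heart failure.
    """
    variant = FraminghamVariant(variant)
    c = coefficient_set(f"framingham_{variant.value}", profile.sex)
    lp = c["ln_age"] * math.log(profile.age)
    if variant is FraminghamVariant.lipid:
        if profile.total_cholesterol is None or profile.hdl_cholesterol is None:
            raise CalculatorError("lipid variant requires total and HDL cholesterol")
        lp += c["ln_total_cholesterol"] * math.log(profile.total_cholesterol)
        lp += c["ln_hdl_cholesterol"] * math.log(profile.hdl_cholesterol)
    else:
        if profile.bmi is None:
            raise CalculatorError("bmi variant requires BMI")
        lp += c["ln_bmi"] * math.log(profile.bmi)
    sbp_term = "ln_sbp_treated" if profile.bp_treated else "ln_sbp_untreated"
    lp += c[sbp_term] * math.log(profile.systolic_bp)
    if profile.smoker:
        lp += c["smoker"]
    if profile.diabetic:
        lp += c["diabetes"]
    survival = c["baseline_survival"] ** math.exp(lp - c["mean_linear_predictor"])
    return 100.0 * (1.0 - survival)


def display_risk(risk_pct: float) -> float:
    return round(risk_pct, 1)


def risk_category(risk_pct: float) -> RiskCategory:
    """Categorize 10-year risk: high strictly above 20%, low strictly below 10%."""
    if not 0 <= risk_pct <= 100:
        raise CalculatorError("risk must be a percentage in [0, 100]")
    if risk_pct > 20:
        return RiskCategory.high
    if risk_pct < 10:
        return RiskCategory.low
    return RiskCategory.intermediate


def classify_bp(
    systolic: float,
    diastolic: float,
    *,
    goal_systolic: float = 140.0,
    goal_diastolic: float = 90.0,
) -> BpStatus:
    """Controlled/uncontrolled against a per-patient goal (default 140/90).

    Uncontrolled iff systolic ≥ goal or diastolic ≥ goal (boundary counts
    as uncontrolled).
    """
    if systolic <= 0 or diastolic <= 0:
        raise CalculatorError("blood pressures must be positive")
    if systolic >= goal_systolic or diastolic >= goal_diastolic:
        return BpStatus.uncontrolled
    return BpStatus.controlled
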