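"""Gestational weight gain and postpartum weight retention.

Weight gain during pregnancy is predicted from the pre-pregnancy WHO BMI
category using the IOM (2009) recommendations: a total-gain range per
category and a central weekly rate for trimesters 2-3.  Postpartum weight
retention follows fitted quadratic curves in postpartum weeks, one per BMI
category, anchored at week 0 to half the category's average total gain.
The six-month anchors of those curves were transferred from a Taiwanese
cohort (Huang et al.) to IOM gain levels by the arithmetic rule of three.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError


class BmiCategory(enum.Enum):
    """WHO pre-pregnancy BMI classes partitioning (0, inf) kg/m^2."""

    UNDERWEIGHT = "underweight"
    NORMAL = "normal"
    OVERWEIGHT = "overweight"
    OBESE = "obese"

    @property
    def bounds(self) -> tuple[float, float]:
        return _BOUNDS[self]


# Half-open partition [lo, hi); the published ranges (18.5-24.9, 25.0-29.9)
# leave gaps that the half-open convention closes.
_BOUNDS = {
    BmiCategory.UNDERWEIGHT: (0.0, 18.5),
    BmiCategory.NORMAL: (18.5, 25.0),
    BmiCategory.OVERWEIGHT: (25.0, 30.0),
    BmiCategory.OBESE: (30.0, float("inf")),
}


@dataclass(frozen=True)
class GwgPolicy:
    """IOM total-gain range and trimester-2/3 weekly rate for one category."""

    total_gain_range_kg: tuple[float, float]
    weekly_rate_kg: float                 # central value used for prediction
    weekly_rate_range_kg: tuple[float, float]

    @property
    def avg_total_kg(self) -> float:
        lo, hi = self.total_gain_range_kg
        return (lo + hi) / 2.0


#: IOM 2009 recommendations (kg; weekly rates for trimesters 2-3).
GWG_POLICY = {
    BmiCategory.UNDERWEIGHT: GwgPolicy((12.73, 18.18), 0.45, (0.45, 0.59)),
    BmiCategory.NORMAL: GwgPolicy((11.36, 15.91), 0.45, (0.36, 0.45)),
    BmiCategory.OVERWEIGHT: GwgPolicy((6.82, 11.36), 0.27, (0.23, 0.32)),
    BmiCategory.OBESE: GwgPolicy((5.00, 9.09), 0.23, (0.18, 0.27)),
}

#: Quadratic retention curves: retention_kg = a*week^2 + b*week + c for
#: postpartum weeks 0-24.  The intercept c is half the category's IOM
#: average total gain (the week-0 anchor).
RETENTION_CURVES = {
    BmiCategory.UNDERWEIGHT: (0.0064, -0.3268, 7.7275),
    BmiCategory.NORMAL: (0.0068, -0.3452, 6.8175),
    BmiCategory.OVERWEIGHT: (0.0052, -0.2662, 4.5450),
    BmiCategory.OBESE: (0.0057, -0.2915, 3.5225),
}

#: Inputs and result of the rule-of-three transfer of Huang's six-month
#: retention onto IOM average gain levels.  The normal-weight derived value
#: was printed as 2.430 in the source even though the rule of three gives
#: 2.439; the printed value is kept (it is what the curves were built from)
#: and the mismatch is documented rather than corrected.
RETENTION_DERIVATION = pd.DataFrame(
    {
        "huang_gwg_kg": [14.36, 14.37, 13.07, 11.15],
        "huang_retention_6mo_kg": [3.32, 2.57, 1.67, -0.29],
        "iom_avg_gwg_kg": [15.455, 13.635, 9.09, 7.045],
        "printed_retention_6mo_kg": [3.573, 2.430, 1.161, -0.183],
    },
    index=pd.Index([c.value for c in BmiCategory], name="category"),
)

#: Average pregnancy weight-gain breakdown (kg) published by the American
#: Pregnancy Association; components sum to 13.63 kg (30 lb).
APA_WEIGHT_GAIN_DISTRIBUTION = pd.DataFrame(
    {
        "weight_kg": [3.4, 0.68, 1.82, 1.82, 0.91, 0.91, 3.18, 0.91],
        "belongs_to": [
            "baby", "baby", "baby", "baby/mom", "mom", "mom", "mom", "mom",
        ],
    },
    index=pd.Index(
        [
            "baby at term",
            "placenta",
            "increased fluid volume",
            "increased blood volume",
            "uterus",
            "breast tissue",
            "maternal stores",
            "amniotic fluid",
        ],
        name="component",
    ),
)

#: Weeks where the first trimester ends / term; gain accrual switches from
#: the linear ramp to the IOM weekly rate at FIRST_TRIMESTER_END.
FIRST_TRIMESTER_END = 12.0
TERM_WEEK = 40.0


def classify_bmi(bmi_kg_m2: float) -> BmiCategory:
    """Map a BMI to its WHO category (half-open intervals)."""
    if not bmi_kg_m2 > 0:
        raise InvalidArgumentError(f"BMI must be positive, got {bmi_kg_m2}")
    for cat, (lo, hi) in _BOUNDS.items():
        if lo <= bmi_kg_m2 < hi:
            return cat
    raise AssertionError("unreachable: bounds partition (0, inf)")


def iom_average_gwg(category: BmiCategory) -> float:
    """Midpoint of the IOM total-gain range (kg)."""
    return GWG_POLICY[category].avg_total_kg


def predict_weight_gain(category: BmiCategory, gestational_week: float) -> float:
    """Cumulative gestational weight gain (kg) at a given week.

    The IOM tables pin two facts only: the weekly rate over trimesters 2-3
    and the total at term.  The remainder (avg_total - 28*rate) is taken as
    first-trimester gain accrued linearly over weeks 0-12, giving the
    simplest continuous curve through both anchors.
    """
    if gestational_week < 0 or gestational_week > TERM_WEEK:
        warnings.warn(
            f"gestational week {gestational_week} outside [0, {TERM_WEEK}]; clamping",
            stacklevel=2,
        )
        gestational_week = float(np.clip(gestational_week, 0.0, TERM_WEEK))
    pol = GWG_POLICY[category]
    first_tri_total = pol.avg_total_kg - (TERM_WEEK - FIRST_TRIMESTER_END) * pol.weekly_rate_kg
    if gestational_week <= FIRST_TRIMESTER_END:
        return first_tri_total * gestational_week / FIRST_TRIMESTER_END
    return first_tri_total + pol.weekly_rate_kg * (gestational_week - FIRST_TRIMESTER_END)


def retention_rule_of_three(
    huang_retention_kg: float, iom_gwg_kg: float, huang_gwg_kg: float
) -> float:
    """Scale a reference retention by the ratio of gain levels (rule of three)."""
    if huang_gwg_kg == 0:
        raise InvalidArgumentError("reference GWG must be nonzero")
    return huang_retention_kg * iom_gwg_kg / huang_gwg_kg


def predict_retention(category: BmiCategory, postpartum_week: float) -> float:
    """Postpartum weight retention (kg) from the fitted quadratic curve."""
    if postpartum_week < 0 or postpartum_week > 24:
        warnings.warn(
            f"postpartum week {postpartum_week} outside [0, 24]; clamping",
            stacklevel=2,
        )
        postpartum_week = float(np.clip(postpartum_week, 0.0, 24.0))
    a, b, c = RETENTION_CURVES[category]
    return a * postpartum_week**2 + b * postpartum_week + c


def predict_postpartum_weight(
    pre_pregnancy_weight_kg: float, category: BmiCategory, postpartum_week: float
) -> float:
    """Postpartum weight = pre-pregnancy weight + predicted retention."""
    if pre_pregnancy_weight_kg <= 0:
        raise InvalidArgumentError("pre-pregnancy weight must be positive")
    return pre_pregnancy_weight_kg + predict_retention(category, postpartum_week)
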