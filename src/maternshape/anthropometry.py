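"""Regression-based prediction of maternal body measurements.

The statistical core: five body girths (chest, waist, hip, upper arm,
thigh) are predicted by multiple linear regression from simple covariates
(age, pre-pregnancy weight, height, gravida, gestational or postpartum
week, and the current weight change).  The coefficient tables shipped here
were fitted on longitudinal cohorts of 98 pregnant (587 visit records) and
83 postpartum (503 records) women; they are treated as fixed published
constants, with CSV round-tripping for alternative fits.

A separate set of non-pregnant baseline equations maps (weight, height) to
chest/waist/hip/inseam for an average female body; the baseline girths at
*pre-pregnancy* weight are what drives the morph-target weights in
:mod:`maternshape.morphspace`, while inseam is treated as static through
pregnancy (it is measured once, early, and leg length does not change).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

Mode = Literal["pregnant", "postpartum"]

#: Responses predicted by the girth regressions, in fixed order.
RESPONSES = ("chest", "waist", "hip", "upper_arm", "thigh")

#: Covariate order of the pregnant regression: value = A*age + B*w_pp +
#: C*height + D*gravida + E*week + F*weight_gain + intercept.
PREGNANT_COVARIATES = (
    "age_years",
    "pre_pregnancy_weight_kg",
    "height_cm",
    "gravida",
    "gestational_week",
    "weight_gain_kg",
)

#: Covariate order of the postpartum regression: value = A*age + B*w_pp +
#: C*height + D*gravida + E*baby_weight + F*week + G*postpartum_weight + H.
POSTPARTUM_COVARIATES = (
    "age_years",
    "pre_pregnancy_weight_kg",
    "height_cm",
    "gravida",
    "baby_weight_kg",
    "postpartum_week",
    "postpartum_weight_kg",
)

# Fitted girth-regression coefficients, pregnant cohort (rows: response;
# columns: A..F then intercept G).
_PREGNANT_TABLE = {
    "chest": (-0.016, 0.674, -0.132, 0.090, 0.100, 0.457, 69.896),
    "waist": (0.108, 0.752, -0.203, 1.315, 0.591, 0.840, 59.394),
    "hip": (-0.022, 0.736, -0.012, -0.491, -0.074, 0.970, 58.071),
    "upper_arm": (0.017, 0.306, -0.075, 0.004, 0.016, 0.272, 21.423),
    "thigh": (0.031, 0.516, -0.026, -0.064, -0.066, 0.668, 29.115),
}

# Postpartum cohort (columns: A..G then intercept H).
_POSTPARTUM_TABLE = {
    "chest": (-0.036, 0.033, 0.013, 0.689, -0.066, -0.066, 0.550, 53.038),
    "waist": (0.041, -0.064, -0.213, 2.880, -2.098, -0.396, 0.870, 75.729),
    "hip": (0.058, -0.074, -0.180, -0.022, -0.387, -0.196, 0.780, 83.935),
    "upper_arm": (0.002, -0.014, -0.164, 0.984, -0.533, -0.013, 0.297, 35.833),
    "thigh": (-0.046, 0.162, -0.124, -1.189, 1.112, -0.072, 0.390, 41.065),
}

# Non-pregnant baseline: girth = a*weight + b*height + c (cm), fitted on a
# national female sizing survey.
BASELINE_COEFFICIENTS = {
    "chest": (0.872260, -0.437949, 110.131573),
    "waist": (0.931735, -0.497702, 104.780946),
    "hip": (0.729978, -0.152380, 78.526838),
    "inseam": (-0.059182, 0.547734, -14.226815),
}


def bmi(weight_kg: float, height_cm: float) -> float:
    """Body mass index in kg/m^2."""
    if weight_kg <= 0 or height_cm <= 0:
        raise InvalidArgumentError(
            f"weight and height must be positive, got {weight_kg}, {height_cm}"
        )
    return weight_kg / (height_cm / 100.0) ** 2


def baseline_measurements(
    weight_kg: float, height_cm: float, *, validate: bool = True
) -> tuple[float, float, float, float]:
    """Non-pregnant (chest, waist, hip, inseam) in cm at a given weight/height.

    ``validate=False`` skips the positivity check so the linear forms can be
    probed analytically (e.g. at the origin, where chest equals the
    intercept 110.131573).
    """
    if validate and (weight_kg <= 0 or height_cm <= 0):
        raise InvalidArgumentError(
            f"weight and height must be positive, got {weight_kg}, {height_cm}"
        )
    out = tuple(
        a * weight_kg + b * height_cm + c
        for a, b, c in (BASELINE_COEFFICIENTS[k] for k in ("chest", "waist", "hip", "inseam"))
    )
    return out  # type: ignore[return-value]


@dataclass(frozen=True)
class BodyMeasurements:
    """Girths and lengths (cm) passed between statistics and mesh code."""

    chest_cm: float
    waist_cm: float
    hip_cm: float
    upper_arm_cm: float
    thigh_cm: float
    inseam_cm: float
    height_cm: float

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not v > 0:
                raise InvalidArgumentError(f"{f.name} must be positive, got {v}")
        if not self.inseam_cm < self.height_cm:
            raise InvalidArgumentError(
                f"inseam ({self.inseam_cm}) must be below height ({self.height_cm})"
            )

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _clamped_week(week: float, lo: float, hi: float, what: str) -> float:
    if week < lo or week > hi:
        warnings.warn(
            f"{what} {week} outside [{lo}, {hi}]; clamping", stacklevel=3
        )
        return float(np.clip(week, lo, hi))
    return float(week)


@dataclass(frozen=True)
class PregnancyProfile:
    """Covariates of the pregnant girth regression.

    ``weight_gain_kg`` may be left ``None`` and resolved from the
    BMI-category gain schedule in :mod:`maternshape.weight_dynamics`.
    """

    pre_pregnancy_weight_kg: float
    height_cm: float
    gestational_week: float
    age_years: float = 30.0
    gravida: int = 1
    weight_gain_kg: float | None = None

    def __post_init__(self):
        if self.pre_pregnancy_weight_kg <= 0 or self.height_cm <= 0:
            raise InvalidArgumentError("weight and height must be positive")
        if self.gravida < 1:
            raise InvalidArgumentError(f"gravida must be >= 1, got {self.gravida}")
        object.__setattr__(
            self,
            "gestational_week",
            _clamped_week(self.gestational_week, 0.0, 42.0, "gestational week"),
        )

    @property
    def pre_pregnancy_bmi(self) -> float:
        return bmi(self.pre_pregnancy_weight_kg, self.height_cm)

    def covariate_vector(self) -> np.ndarray:
        if self.weight_gain_kg is None:
            raise InvalidArgumentError(
                "weight_gain_kg unresolved; predict it via weight_dynamics "
                "or supply it explicitly"
            )
        return np.array(
            [
                self.age_years,
                self.pre_pregnancy_weight_kg,
                self.height_cm,
                self.gravida,
                self.gestational_week,
                self.weight_gain_kg,
            ],
            dtype=float,
        )


@dataclass(frozen=True)
class PostpartumProfile:
    """Covariates of the postpartum girth regression."""

    pre_pregnancy_weight_kg: float
    height_cm: float
    postpartum_week: float
    age_years: float = 30.0
    gravida: int = 1
    baby_weight_kg: float = 3.0
    postpartum_weight_kg: float | None = None

    def __post_init__(self):
        if self.pre_pregnancy_weight_kg <= 0 or self.height_cm <= 0:
            raise InvalidArgumentError("weight and height must be positive")
        if self.baby_weight_kg <= 0:
            raise InvalidArgumentError("baby weight must be positive")
        if self.gravida < 1:
            raise InvalidArgumentError(f"gravida must be >= 1, got {self.gravida}")
        object.__setattr__(
            self,
            "postpartum_week",
            _clamped_week(self.postpartum_week, 0.0, 24.0, "postpartum week"),
        )

    @property
    def pre_pregnancy_bmi(self) -> float:
        return bmi(self.pre_pregnancy_weight_kg, self.height_cm)

    def covariate_vector(self) -> np.ndarray:
        if self.postpartum_weight_kg is None:
            raise InvalidArgumentError(
                "postpartum_weight_kg unresolved; predict it via "
                "weight_dynamics or supply it explicitly"
            )
        return np.array(
            [
                self.age_years,
                self.pre_pregnancy_weight_kg,
                self.height_cm,
                self.gravida,
                self.baby_weight_kg,
                self.postpartum_week,
                self.postpartum_weight_kg,
            ],
            dtype=float,
        )


@dataclass(frozen=True)
class RegressionCoefficients:
    """Per-response linear coefficients + intercept for one mode.

    ``table`` is indexed by response name and has one column per covariate
    (order fixed by :data:`PREGNANT_COVARIATES` / :data:`POSTPARTUM_COVARIATES`)
    plus a final ``intercept`` column.
    """

    mode: Mode
    table: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        expected = list(self.covariates) + ["intercept"]
        if list(self.table.columns) != expected:
            raise InvalidArgumentError(
                f"coefficient columns must be {expected}, got {list(self.table.columns)}"
            )
        missing = set(RESPONSES) - set(self.table.index)
        if missing:
            raise InvalidArgumentError(f"missing responses: {sorted(missing)}")

    @property
    def covariates(self) -> tuple[str, ...]:
        return PREGNANT_COVARIATES if self.mode == "pregnant" else POSTPARTUM_COVARIATES

    @classmethod
    def pregnant_default(cls) -> "RegressionCoefficients":
        return cls._from_table("pregnant", _PREGNANT_TABLE)

    @classmethod
    def postpartum_default(cls) -> "RegressionCoefficients":
        return cls._from_table("postpartum", _POSTPARTUM_TABLE)

    @classmethod
    def _from_table(cls, mode: Mode, rows: dict) -> "RegressionCoefficients":
        covs = PREGNANT_COVARIATES if mode == "pregnant" else POSTPARTUM_COVARIATES
        df = pd.DataFrame.from_dict(rows, orient="index", columns=list(covs) + ["intercept"])
        return cls(mode=mode, table=df.loc[list(RESPONSES)])

    def predict(self, covariate_vector: np.ndarray) -> dict[str, float]:
        x = np.append(np.asarray(covariate_vector, dtype=float), 1.0)
        vals = self.table.to_numpy() @ x
        return dict(zip(self.table.index, vals))

    # -- CSV round trip ----------------------------------------------------
    def to_csv(self, path: str | Path | io.TextIOBase) -> None:
        """Write as CSV (``response`` index column, covariates + intercept)."""
        self.table.to_csv(path, index_label="response")

    @classmethod
    def from_csv(cls, path: str | Path | io.TextIOBase, mode: Mode) -> "RegressionCoefficients":
        df = pd.read_csv(path, index_col="response")
        return cls(mode=mode, table=df)


def _finalize(
    girths: dict[str, float], pre_weight: float, height: float
) -> BodyMeasurements:
    neg = {k: v for k, v in girths.items() if v <= 0}
    if neg:
        raise InvalidArgumentError(
            f"regression extrapolated to non-positive girths {neg}; "
            "inputs are outside the model's plausible range"
        )
    inseam = baseline_measurements(pre_weight, height)[3]
    return BodyMeasurements(
        chest_cm=girths["chest"],
        waist_cm=girths["waist"],
        hip_cm=girths["hip"],
        upper_arm_cm=girths["upper_arm"],
        thigh_cm=girths["thigh"],
        inseam_cm=inseam,
        height_cm=height,
    )


def predict_pregnant_measurements(
    profile: PregnancyProfile,
    coeffs: RegressionCoefficients | None = None,
) -> BodyMeasurements:
    """Predict pregnant girths; inseam from the static baseline equation.

    Inseam is evaluated at *pre-pregnancy* weight: leg length is measured
    once early in pregnancy and does not change with gestation.
    """
    coeffs = coeffs or RegressionCoefficients.pregnant_default()
    if coeffs.mode != "pregnant":
        raise InvalidArgumentError(f"expected pregnant coefficients, got {coeffs.mode}")
    girths = coeffs.predict(profile.covariate_vector())
    return _finalize(girths, profile.pre_pregnancy_weight_kg, profile.height_cm)


def predict_postpartum_measurements(
    profile: PostpartumProfile,
    coeffs: RegressionCoefficients | None = None,
) -> BodyMeasurements:
    """Predict postpartum girths; inseam from the static baseline equation."""
    coeffs = coeffs or RegressionCoefficients.postpartum_default()
    if coeffs.mode != "postpartum":
        raise InvalidArgumentError(f"expected postpartum coefficients, got {coeffs.mode}")
    girths = coeffs.predict(profile.covariate_vector())
    return _finalize(girths, profile.pre_pregnancy_weight_kg, profile.height_cm)


def resolve_profile(profile):
    """Fill the missing weight field of a profile from the BMI-category model.

    Returns a completed copy; profiles with the field already set are
    returned unchanged.
    """
    from . import weight_dynamics as wd

    cat = wd.classify_bmi(profile.pre_pregnancy_bmi)
    if isinstance(profile, PregnancyProfile):
        if profile.weight_gain_kg is not None:
            return profile
        gain = wd.predict_weight_gain(cat, profile.gestational_week)
        return replace(profile, weight_gain_kg=gain)
    if isinstance(profile, PostpartumProfile):
        if profile.postpartum_weight_kg is not None:
            return profile
        w = wd.predict_postpartum_weight(
            profile.pre_pregnancy_weight_kg, cat, profile.postpartum_week
        )
        return replace(profile, postpartum_weight_kg=w)
    raise InvalidArgumentError(f"unsupported profile type {type(profile)!r}")
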