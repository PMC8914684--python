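"""Refitting and validation machinery.

Three independent jobs live here:

* ``fit_measurement_regression`` -- ordinary least squares refit of the
  girth regressions from cohort records (e.g. the synthetic cohorts of
  :mod:`maternshape.synthetic_cohort`).
* ``calibrate_alp`` -- re-derivation of the morph-correction tensor against
  an arbitrary avatar set: on a grid of (BMI, week) cells the corrections
  alp1..alp5 are solved by bounded least squares so that the blended mesh,
  measured by cross-sections, matches the statistical girth predictions;
  the per-cell corrections are then condensed into the quadratic-in-BMI /
  quadratic-in-week tensor form.
* ``agreement_stats`` -- the mean/SD/95% CI/relative-error/correlation
  summary used to compare two measurement methods variable by variable.

The pregnant belly correction alp0 is not identifiable from horizontal
girths alone (an anterior bulge and an all-round waist expansion read
almost the same under the tape protocol), so it follows a fixed gestation
ramp -- zero at conception, full belly at term -- expressed exactly in the
tensor's polynomial form; the girth budget is carried by alp1..alp5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .anthropometry import (
    POSTPARTUM_COVARIATES,
    PREGNANT_COVARIATES,
    RESPONSES,
    Mode,
    PostpartumProfile,
    PregnancyProfile,
    RegressionCoefficients,
    predict_postpartum_measurements,
    predict_pregnant_measurements,
    resolve_profile,
)
from .avatars import AvatarSet
from .errors import InvalidArgumentError, SingularDesignError
from .measure import MeasureConfig, measure_core
from .morphspace import AlpCalibration, MorphWeights, base_weights, blend
from .pipeline import baseline_body

#: Belly ramp slope: alp0 = week/40 at the polynomial-evaluation week, so
#: K0 reaches 1 (the full pregnant-thin target) at term.
BELLY_RAMP_PER_WEEK = 1.0 / 40.0

#: Girths entering the calibration objective (no dedicated morph target
#: exists for the upper arm / thigh, so they are excluded).
CALIBRATION_TARGETS = ("chest_cm", "waist_cm", "hip_cm", "inseam_cm", "height_cm")


# ---------------------------------------------------------------------------
# OLS refit
# ---------------------------------------------------------------------------


def fit_measurement_regression(records: pd.DataFrame, mode: Mode) -> RegressionCoefficients:
    """Ordinary least-squares refit of the five girth regressions.

    ``records`` must contain the mode's covariate columns plus one column
    per response (``chest`` .. ``thigh``).
    """
    covs = PREGNANT_COVARIATES if mode == "pregnant" else POSTPARTUM_COVARIATES
    missing = [c for c in (*covs, *RESPONSES) if c not in records.columns]
    if missing:
        raise InvalidArgumentError(f"records missing columns: {missing}")
    n, p = len(records), len(covs)
    if n < p + 2:
        raise SingularDesignError(f"need more than {p + 1} records, got {n}")
    x = np.column_stack([records[list(covs)].to_numpy(float), np.ones(n)])
    if np.linalg.matrix_rank(x) < p + 1:
        raise SingularDesignError("design matrix is rank deficient (collinear covariates)")
    beta, *_ = np.linalg.lstsq(x, records[list(RESPONSES)].to_numpy(float), rcond=None)
    table = pd.DataFrame(beta.T, index=list(RESPONSES), columns=list(covs) + ["intercept"])
    return RegressionCoefficients(mode=mode, table=table)


def polyfit_quadratic(xs, ys) -> tuple[float, float, float]:
    """Least-squares quadratic fit -> (a, b, c) with y = a x^2 + b x + c."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if len(np.unique(xs)) < 3:
        raise InvalidArgumentError("need at least 3 distinct x values")
    a, b, c = np.polyfit(xs, ys, 2)
    return float(a), float(b), float(c)


# ---------------------------------------------------------------------------
# Agreement statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AgreementSummary:
    """Per-variable comparison of two paired measurement series."""

    table: pd.DataFrame

    def __getitem__(self, variable: str) -> pd.Series:
        return self.table.loc[variable]


def _agreement_row(first, second, reference: str) -> dict[str, float]:
    a = np.asarray(first, dtype=float)
    b = np.asarray(second, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise InvalidArgumentError("need two equal-length 1-d series of >= 2 pairs")
    n = len(a)
    out = {}
    for tag, v in (("1", a), ("2", b)):
        mean, sd = float(v.mean()), float(v.std(ddof=1))
        half = 1.96 * sd / np.sqrt(n)
        out.update(
            {
                f"mean_{tag}": mean,
                f"sd_{tag}": sd,
                f"ci_lower_{tag}": mean - half,
                f"ci_upper_{tag}": mean + half,
            }
        )
    ref_mean = out["mean_1"] if reference == "first" else out["mean_2"]
    if ref_mean == 0:
        raise InvalidArgumentError("reference mean is zero; relative error undefined")
    out["relative_error_pct"] = abs(out["mean_1"] - out["mean_2"]) / abs(ref_mean) * 100.0
    if a.std() == 0 or b.std() == 0:
        raise InvalidArgumentError("zero variance in a series; correlation undefined")
    out["correlation"] = float(np.corrcoef(a, b)[0, 1])
    out["n"] = n
    return out


def agreement_stats(pairs, reference: str = "first") -> AgreementSummary:
    """Summarize agreement between paired measurement methods.

    ``pairs`` maps a variable name to a pair of equal-length series
    (method 1, method 2); a single ``(first, second)`` tuple is also
    accepted and reported under the variable name ``"value"``.
    ``reference`` selects which method's mean normalizes the relative
    error -- published comparisons are inconsistent on this point, so it
    is explicit here.
    """
    if reference not in ("first", "second"):
        raise InvalidArgumentError("reference must be 'first' or 'second'")
    if isinstance(pairs, tuple):
        pairs = {"value": pairs}
    rows = {var: _agreement_row(a, b, reference) for var, (a, b) in pairs.items()}
    return AgreementSummary(table=pd.DataFrame.from_dict(rows, orient="index"))


# ---------------------------------------------------------------------------
# Alp tensor calibration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CalibrationGrid:
    """The (BMI x week) cells a tensor is fitted on, plus the fixed profile.

    Defaults span the four BMI categories and the fit domain of each mode
    (pregnant weeks 12-36, postpartum 0-24).
    """

    bmis: tuple[float, ...] = (17.0, 22.0, 27.5, 33.0)
    weeks: tuple[float, ...] = (12.0, 16.0, 20.0, 24.0, 28.0, 32.0, 36.0)
    height_cm: float = 160.0
    age_years: float = 30.0
    gravida: int = 1
    baby_weight_kg: float = 3.0

    @classmethod
    def postpartum_default(cls) -> "CalibrationGrid":
        return cls(weeks=(0.0, 4.0, 8.0, 12.0, 16.0, 20.0, 24.0))


@dataclass
class CalibrationResult:
    calibration: AlpCalibration
    #: per-cell solved corrections and girth residuals
    cells: pd.DataFrame = field(repr=False)
    flagged: list[tuple[float, float]] = field(default_factory=list)


def _statistical_targets(grid: CalibrationGrid, bmi: float, week: float, mode: Mode):
    """Girth targets (cm) for one grid cell from the regression models."""
    w_pp = bmi * (grid.height_cm / 100.0) ** 2
    if mode == "pregnant":
        profile = resolve_profile(
            PregnancyProfile(
                pre_pregnancy_weight_kg=w_pp,
                height_cm=grid.height_cm,
                gestational_week=week,
                age_years=grid.age_years,
                gravida=grid.gravida,
            )
        )
        pred = predict_pregnant_measurements(profile)
    else:
        profile = resolve_profile(
            PostpartumProfile(
                pre_pregnancy_weight_kg=w_pp,
                height_cm=grid.height_cm,
                postpartum_week=week,
                age_years=grid.age_years,
                gravida=grid.gravida,
                baby_weight_kg=grid.baby_weight_kg,
            )
        )
        pred = predict_postpartum_measurements(profile)
    return pred, w_pp


def _scheduled_alp0(week: float, mode: Mode) -> float:
    if mode == "postpartum":
        return 0.0
    return BELLY_RAMP_PER_WEEK * float(np.clip(week, 12.0, 40.0))


def _solve_cell(
    avatars: AvatarSet,
    base: np.ndarray,
    alp0: float,
    targets: np.ndarray,
    mode: Mode,
    config: MeasureConfig,
    bound: float = 1.0,
):
    """Bounded least squares for alp1..alp5 at one grid cell."""

    def residual(alp15: np.ndarray) -> np.ndarray:
        k = base.copy()
        k[0] += alp0
        k[1:] += alp15
        if mode == "postpartum":
            k[0] = 0.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # sanity-band warnings during search
            weights = MorphWeights(mode, *k)
            mesh = blend(avatars, weights)
            got = measure_core(mesh, config)
        return np.array([got[t] for t in CALIBRATION_TARGETS]) - targets

    res = least_squares(
        residual,
        x0=np.zeros(5),
        bounds=(-bound, bound),
        diff_step=0.01,
        xtol=1e-9,
        ftol=1e-9,
        gtol=1e-12,
        max_nfev=60,
    )
    return res.x, residual(res.x)


def calibrate_alp(
    avatars: AvatarSet,
    grid: CalibrationGrid | None = None,
    mode: Mode = "pregnant",
    config: MeasureConfig | None = None,
    residual_flag_cm: float = 2.0,
    target_source=None,
) -> CalibrationResult:
    """Fit a correction tensor so blended meshes match statistical girths.

    Per cell, the corrections minimize the squared mismatch between the
    mesh-measured and regression-predicted chest/waist/hip/inseam/height;
    cells whose residual exceeds ``residual_flag_cm`` on any girth are
    flagged and excluded from the polynomial condensation stage.

    ``target_source(grid, bmi, week, mode)`` may replace the statistical
    targets with any per-cell ``(BodyMeasurements, pre_pregnancy_weight)``
    pair -- e.g. a forward model for parameter-recovery checks.
    """
    grid = grid or (
        CalibrationGrid() if mode == "pregnant" else CalibrationGrid.postpartum_default()
    )
    config = config or MeasureConfig()

    source = target_source or _statistical_targets
    rows = []
    flagged = []
    for bmi in grid.bmis:
        for week in grid.weeks:
            pred, w_pp = source(grid, bmi, week, mode)
            body = baseline_body(w_pp, grid.height_cm, pred)
            base = base_weights(body, mode).as_array()
            alp0 = _scheduled_alp0(week, mode)
            targets = np.array([getattr(pred, t) for t in CALIBRATION_TARGETS])
            alp15, resid = _solve_cell(avatars, base, alp0, targets, mode, config)
            row = {"bmi": bmi, "week": week, "alp0": alp0}
            row.update({f"alp{j}": alp15[j - 1] for j in range(1, 6)})
            row.update(
                {f"resid_{t}": resid[i] for i, t in enumerate(CALIBRATION_TARGETS)}
            )
            ok = np.max(np.abs(resid)) <= residual_flag_cm
            row["converged"] = ok
            if not ok:
                flagged.append((bmi, week))
                warnings.warn(
                    f"calibration cell (bmi={bmi}, week={week}) residual "
                    f"{np.max(np.abs(resid)):.2f} cm > {residual_flag_cm}; excluded"
                )
            rows.append(row)
    cells = pd.DataFrame(rows)
    good = cells[cells["converged"]]
    if len(good["bmi"].unique()) < 3 or len(good["week"].unique()) < 3:
        raise InvalidArgumentError(
            "too few converged cells to fit the quadratic surfaces"
        )

    tensor = np.zeros((6, 3, 3))
    first = 0 if mode == "pregnant" else 1
    weeks = sorted(good["week"].unique())
    for x in range(first, 6):
        # stage 1: quadratic in BMI per week -> AlpXY(week)
        per_week = {}
        for week in weeks:
            sub = good[good["week"] == week]
            per_week[week] = polyfit_quadratic(sub["bmi"], sub[f"alp{x}"])
        # stage 2: quadratic in week per (X, Y) slot
        for y in (1, 2, 3):
            a, b, c = polyfit_quadratic(
                weeks, [per_week[w][y - 1] for w in weeks]
            )
            # polyfit returns highest power first; tensor stores (A, B, C)
            tensor[x, y - 1] = (c, b, a)
    return CalibrationResult(
        calibration=AlpCalibration(mode=mode, tensor=tensor),
        cells=cells,
        flagged=flagged,
    )


def evaluate_calibration(
    avatars: AvatarSet,
    cal: AlpCalibration,
    grid: CalibrationGrid | None = None,
    config: MeasureConfig | None = None,
    girths: tuple[str, ...] = ("chest_cm", "waist_cm", "hip_cm", "inseam_cm"),
) -> pd.DataFrame:
    """Measure blended meshes against statistical predictions on a grid.

    Returns one row per (BMI, week) cell with predicted and measured
    girths and their relative errors; ``mare_pct`` on the result's attrs
    holds the mean absolute relative error across cells and girths.
    """
    from .morphspace import morph_weights

    mode = cal.mode
    grid = grid or (
        CalibrationGrid() if mode == "pregnant" else CalibrationGrid.postpartum_default()
    )
    config = config or MeasureConfig()
    rows = []
    for bmi in grid.bmis:
        for week in grid.weeks:
            pred, w_pp = _statistical_targets(grid, bmi, week, mode)
            body = baseline_body(w_pp, grid.height_cm, pred)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                weights = morph_weights(body, bmi, week, cal, mode)
                mesh = blend(avatars, weights)
                got = measure_core(mesh, config)
            row = {"bmi": bmi, "week": week}
            for t in girths:
                p, g = getattr(pred, t), got[t]
                row[f"pred_{t}"] = p
                row[f"meas_{t}"] = g
                row[f"relerr_{t}"] = abs(g - p) / p * 100.0
            rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["mare_pct"] = float(
        df[[f"relerr_{t}" for t in girths]].to_numpy().mean()
    )
    return df
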