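"""Regression prediction, baseline equations and coefficient I/O."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from maternshape import (
    BodyMeasurements,
    PostpartumProfile,
    PregnancyProfile,
    RegressionCoefficients,
    baseline_measurements,
    bmi,
    predict_postpartum_measurements,
    predict_pregnant_measurements,
    resolve_profile,
)
from maternshape.errors import InvalidArgumentError


class TestBmi:
    @pytest.mark.parametrize(
        "weight,height,expected",
        [(100, 100, 100.0), (60, 165, 60 / 1.65**2), (54, 160, 54 / 1.6**2)],
    )
    def test_values(self, weight, height, expected):
        assert bmi(weight, height) == pytest.approx(expected)

    @pytest.mark.parametrize("weight,height", [(0, 165), (60, 0), (-5, 165)])
    def test_rejects_non_positive(self, weight, height):
        with pytest.raises(InvalidArgumentError):
            bmi(weight, height)


class TestBaselineEquations:
    def test_chest_intercept_is_analytic_anchor(self):
        chest, waist, hip, inseam = baseline_measurements(0, 0, validate=False)
        assert chest == pytest.approx(110.131573)

    def test_reference_female(self):
        chest, waist, hip, inseam = baseline_measurements(60, 165)
        assert chest == pytest.approx(90.2056, abs=1e-3)
        # thin-avatar leg length: the baseline inseam of a 60 kg / 165 cm body
        assert inseam == pytest.approx(72.598, abs=1e-3)

    def test_rejects_non_positive(self):
        with pytest.raises(InvalidArgumentError):
            baseline_measurements(0, 165)


class TestPregnantPrediction:
    def test_intercepts_at_zero_covariates(self):
        coeffs = RegressionCoefficients.pregnant_default()
        vals = coeffs.predict(np.zeros(6))
        assert vals["chest"] == pytest.approx(69.896)
        assert vals["waist"] == pytest.approx(59.394)

    def test_reference_profile(self):
        profile = PregnancyProfile(
            age_years=30, pre_pregnancy_weight_kg=60, height_cm=160,
            gravida=1, gestational_week=24, weight_gain_kg=8,
        )
        meas = predict_pregnant_measurements(profile)
        assert meas.chest_cm == pytest.approx(94.882, abs=1e-3)
        # inseam comes from the static baseline equation at pre-pregnancy weight
        assert meas.inseam_cm == pytest.approx(baseline_measurements(60, 160)[3])
        assert meas.height_cm == 160

    def test_weight_gain_sensitivity_matches_coefficient(self):
        base = dict(pre_pregnancy_weight_kg=60, height_cm=160, gestational_week=24)
        lo = predict_pregnant_measurements(PregnancyProfile(**base, weight_gain_kg=8))
        hi = predict_pregnant_measurements(PregnancyProfile(**base, weight_gain_kg=9))
        assert hi.chest_cm - lo.chest_cm == pytest.approx(0.457)

    def test_week_sensitivity_matches_coefficient(self):
        base = dict(pre_pregnancy_weight_kg=60, height_cm=160, weight_gain_kg=8)
        lo = predict_pregnant_measurements(PregnancyProfile(**base, gestational_week=20))
        hi = predict_pregnant_measurements(PregnancyProfile(**base, gestational_week=21))
        assert hi.waist_cm - lo.waist_cm == pytest.approx(0.591)

    def test_mode_mismatch_rejected(self):
        profile = PregnancyProfile(
            pre_pregnancy_weight_kg=60, height_cm=160, gestational_week=24, weight_gain_kg=8
        )
        with pytest.raises(InvalidArgumentError):
            predict_pregnant_measurements(profile, RegressionCoefficients.postpartum_default())

    def test_unresolved_weight_gain_rejected(self):
        profile = PregnancyProfile(
            pre_pregnancy_weight_kg=60, height_cm=160, gestational_week=24
        )
        with pytest.raises(InvalidArgumentError):
            predict_pregnant_measurements(profile)

    def test_extreme_extrapolation_errors_not_clamps(self):
        profile = PregnancyProfile(
            pre_pregnancy_weight_kg=1.0, height_cm=400, gestational_week=0,
            weight_gain_kg=0, age_years=18,
        )
        with pytest.raises(InvalidArgumentError, match="non-positive"):
            predict_pregnant_measurements(profile)


class TestPostpartumPrediction:
    def test_intercept_at_zero_covariates(self):
        coeffs = RegressionCoefficients.postpartum_default()
        assert coeffs.predict(np.zeros(7))["chest"] == pytest.approx(53.038)

    def test_reference_profile(self):
        profile = PostpartumProfile(
            age_years=30, pre_pregnancy_weight_kg=60, height_cm=160, gravida=1,
            baby_weight_kg=3, postpartum_week=12, postpartum_weight_kg=65,
        )
        assert predict_postpartum_measurements(profile).chest_cm == pytest.approx(
            91.467, abs=1e-3
        )

    def test_postpartum_weight_sensitivity_matches_coefficient(self):
        base = dict(pre_pregnancy_weight_kg=60, height_cm=160, postpartum_week=12)
        lo = predict_postpartum_measurements(
            PostpartumProfile(**base, postpartum_weight_kg=65)
        )
        hi = predict_postpartum_measurements(
            PostpartumProfile(**base, postpartum_weight_kg=66)
        )
        assert hi.hip_cm - lo.hip_cm == pytest.approx(0.780)


class TestProfiles:
    def test_defaults_applied_only_when_absent(self):
        p = PregnancyProfile(pre_pregnancy_weight_kg=60, height_cm=160, gestational_week=20)
        assert p.age_years == 30 and p.gravida == 1
        q = PostpartumProfile(
            pre_pregnancy_weight_kg=60, height_cm=160, postpartum_week=4, baby_weight_kg=2.5
        )
        assert q.baby_weight_kg == 2.5

    def test_out_of_range_week_clamps_with_warning(self):
        with pytest.warns(UserWarning, match="clamping"):
            p = PostpartumProfile(
                pre_pregnancy_weight_kg=60, height_cm=160, postpartum_week=30
            )
        assert p.postpartum_week == 24

    def test_gravida_below_one_rejected(self):
        with pytest.raises(InvalidArgumentError):
            PregnancyProfile(pre_pregnancy_weight_kg=60, height_cm=160,
                             gestational_week=20, gravida=0)

    def test_resolve_fills_weight_gain_from_bmi_category(self):
        p = resolve_profile(
            PregnancyProfile(pre_pregnancy_weight_kg=60, height_cm=160, gestational_week=24)
        )
        from maternshape import classify_bmi, predict_weight_gain

        cat = classify_bmi(bmi(60, 160))
        assert p.weight_gain_kg == pytest.approx(predict_weight_gain(cat, 24))


class TestBodyMeasurements:
    def test_rejects_inseam_above_height(self):
        with pytest.raises(InvalidArgumentError):
            BodyMeasurements(90, 70, 95, 28, 50, 170, 165)

    def test_rejects_non_positive_girth(self):
        with pytest.raises(InvalidArgumentError):
            BodyMeasurements(0, 70, 95, 28, 50, 70, 165)


class TestCoefficientRoundTrip:
    @pytest.mark.parametrize("mode", ["pregnant", "postpartum"])
    def test_csv_round_trip_is_bit_identical(self, mode):
        coeffs = getattr(RegressionCoefficients, f"{mode}_default")()
        buf = io.StringIO()
        coeffs.to_csv(buf)
        buf.seek(0)
        back = RegressionCoefficients.from_csv(buf, mode)
        x = np.array([30.0, 60.0, 160.0, 1.0, 24.0, 8.0, 65.0])[: len(coeffs.covariates)]
        for resp, val in coeffs.predict(x).items():
            assert back.predict(x)[resp] == val  # exact, not approx

    def test_wrong_columns_rejected(self):
        table = RegressionCoefficients.pregnant_default().table
        with pytest.raises(InvalidArgumentError):
            RegressionCoefficients(mode="postpartum", table=table)


@settings(max_examples=30, deadline=None)
@given(
    weights=st.lists(st.floats(40, 100), min_size=3, max_size=8),
    week=st.floats(12, 36),
)
def test_prediction_linearity_in_covariates(weights, week):
    """Prediction at the covariate mean equals the mean of predictions."""
    profiles = [
        PregnancyProfile(
            pre_pregnancy_weight_kg=w, height_cm=160, gestational_week=week,
            weight_gain_kg=6.0,
        )
        for w in weights
    ]
    per_record = np.mean(
        [predict_pregnant_measurements(p).chest_cm for p in profiles]
    )
    mean_profile = PregnancyProfile(
        pre_pregnancy_weight_kg=float(np.mean(weights)), height_cm=160,
        gestational_week=week, weight_gain_kg=6.0,
    )
    assert predict_pregnant_measurements(mean_profile).chest_cm == pytest.approx(
        per_record, abs=1e-9
    )
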