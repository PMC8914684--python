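"""End-to-end profile -> mesh synthesis."""

from __future__ import annotations

from .anthropometry import (
    BodyMeasurements,
    PostpartumProfile,
    PregnancyProfile,
    baseline_measurements,
    predict_postpartum_measurements,
    predict_pregnant_measurements,
    resolve_profile,
)
from .avatars import AvatarSet
from .errors import InvalidArgumentError
from .morphspace import AlpCalibration, blend, morph_weights


def baseline_body(
    pre_pregnancy_weight_kg: float,
    height_cm: float,
    predicted: BodyMeasurements | None = None,
) -> BodyMeasurements:
    """Non-pregnant baseline girths packaged as :class:`BodyMeasurements`.

    The morph base weights are functions of chest/waist/hip/height/inseam
    only; the upper-arm/thigh slots (which have no baseline equation) are
    filled from the statistical prediction when given, else with nominal
    values, purely to satisfy the container's positivity contract.
    """
    chest, waist, hip, inseam = baseline_measurements(pre_pregnancy_weight_kg, height_cm)
    return BodyMeasurements(
        chest_cm=chest,
        waist_cm=waist,
        hip_cm=hip,
        upper_arm_cm=predicted.upper_arm_cm if predicted else 28.0,
        thigh_cm=predicted.thigh_cm if predicted else 50.0,
        inseam_cm=inseam,
        height_cm=height_cm,
    )


def synthesize(
    profile: PregnancyProfile | PostpartumProfile,
    avatars: AvatarSet,
    cal: AlpCalibration | None = None,
):
    """Full pipeline: profile -> statistical girths -> morph weights -> mesh.

    Missing weight fields are resolved from the BMI-category weight model.
    Returns ``(mesh, predicted_measurements, morph_weights)``.
    """
    profile = resolve_profile(profile)
    if isinstance(profile, PregnancyProfile):
        mode = "pregnant"
        predicted = predict_pregnant_measurements(profile)
        week = profile.gestational_week
    elif isinstance(profile, PostpartumProfile):
        mode = "postpartum"
        predicted = predict_postpartum_measurements(profile)
        week = profile.postpartum_week
    else:
        raise InvalidArgumentError(f"unsupported profile type {type(profile)!r}")
    body = baseline_body(profile.pre_pregnancy_weight_kg, profile.height_cm, predicted)
    weights = morph_weights(body, profile.pre_pregnancy_bmi, week, cal, mode)
    mesh = blend(avatars, weights)
    return mesh, predicted, weights
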