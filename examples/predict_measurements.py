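"""Predict body measurements through pregnancy for one woman.

A 30-year-old, 160 cm, 60 kg before pregnancy (BMI 23.4, normal weight).
Weight gain is predicted from her BMI category when not supplied.
"""

from maternshape import (
    PregnancyProfile,
    predict_pregnant_measurements,
    resolve_profile,
)

for week in (12, 20, 28, 36):
    profile = resolve_profile(
        PregnancyProfile(pre_pregnancy_weight_kg=60, height_cm=160, gestational_week=week)
    )
    m = predict_pregnant_measurements(profile)
    print(
        f"week {week:2d}: gain {profile.weight_gain_kg:5.2f} kg | "
        f"chest {m.chest_cm:6.2f}  waist {m.waist_cm:6.2f}  hip {m.hip_cm:6.2f}  "
        f"upper arm {m.upper_arm_cm:5.2f}  thigh {m.thigh_cm:5.2f} cm"
    )

print(
    "\nEach girth follows the fixed linear regression in age, pre-pregnancy "
    "weight,\nheight, gravida, week and weight gain; the waist grows fastest "
    "(0.591 cm/week\nplus 0.840 cm per kg gained)."
)
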