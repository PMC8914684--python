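"""Gestational weight gain and postpartum retention per BMI category.

Prints the gain schedule anchors (week 12, 24 and term) and the retention
curve at delivery, six weeks and six months postpartum.
"""

from maternshape import (
    BmiCategory,
    iom_average_gwg,
    predict_retention,
    predict_weight_gain,
)

print("gestational weight gain (kg):")
for cat in BmiCategory:
    g12, g24, g40 = (predict_weight_gain(cat, w) for w in (12, 24, 40))
    print(
        f"  {cat.value:12s} wk12 {g12:5.2f}  wk24 {g24:5.2f}  term {g40:6.3f} "
        f"(= IOM average {iom_average_gwg(cat):6.3f})"
    )

print("\npostpartum weight retention (kg):")
for cat in BmiCategory:
    r0, r6, r24 = (predict_retention(cat, w) for w in (0, 6, 24))
    print(f"  {cat.value:12s} wk0 {r0:7.4f}  wk6 {r6:6.3f}  wk24 {r24:7.4f}")

print(
    "\nAt delivery a woman retains about half her average total gain; the\n"
    "quadratic curves then decay over 24 weeks -- obese women end slightly\n"
    "below their pre-pregnancy weight (negative retention)."
)
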