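# maternshape

Statistical prediction and 3D morph-target synthesis of pregnant and
postpartum women's body shapes.

Most parametric 3D body models are built from laser scans, which pregnant
women are rarely willing (or able) to undergo. `maternshape` takes the
opposite route: body girths are *predicted* from a handful of simple
inputs — age, height, pre-pregnancy weight, gravida, and gestational or
postpartum week — using multiple linear regressions fitted on longitudinal
tape-measure cohorts of Thai mothers (98 pregnant women / 587 visit
records; 83 postpartum women / 503 records), and a 3D mesh is then
synthesized by blending seven topology-identical avatars with BMI- and
week-calibrated morph weights. The package is for researchers in maternal
anthropometry, body-shape visualization, and garment sizing who need
plausible pregnant/postpartum 3D shapes without scan data.

## The model

**Girth regressions.** Each girth (chest, waist, hip, upper arm, thigh) is
a fixed linear form. Pregnant:

    value = A·Y_w + B·W_pp + C·H_w + D·Gr + E·Wk_p + F·W_g + G

with age Y_w, pre-pregnancy weight W_pp (kg), height H_w (cm), gravida Gr,
gestational week Wk_p and weight gain W_g (kg); postpartum adds baby
weight W_b and current weight W_ppt. Inseam is static (legs don't grow)
and comes from non-pregnant baseline equations in (weight, height).

**Weight dynamics.** When W_g / W_ppt are unknown they are predicted from
the WHO pre-pregnancy BMI category: gestational gain follows the IOM 2009
ranges (linear first-trimester ramp, then the category's weekly rate), and
postpartum retention follows per-category quadratics in postpartum week,
anchored at delivery to half the category's average total gain and at six
months to values transferred from a Taiwanese reference cohort by the rule
of three.

**Morph synthesis.** The output mesh is a per-vertex affine blend

    P = (1 − ΣK)·A + K0·X + K1·B + K2·C + K3·D + K4·E + K5·F

of a thin base avatar A, extreme targets B–F (big breast, big waist, big
hip, tall, long legs) and a pregnant-belly target X. Base weights K0j are
affine rescalings of the baseline girths (e.g. K01 = (chest−57)/(200−57));
all gestational change is carried by additive corrections Alp0..Alp5, each
a quadratic in BMI whose coefficients are quadratics in week — a small
tensor that can be recalibrated against any avatar family.

**Measurement & calibration.** Girths are read back off a mesh as convex-
hull perimeters of horizontal cross-sections (tape semantics), with
landmark bands at fixed fractions of height. The calibration module
refits the regressions from cohort CSVs, re-derives the correction tensor
by bounded least squares against any `AvatarSet`, and computes the
mean/SD/95% CI/relative-error/correlation summaries used for method
agreement.

The bundled avatars are procedurally generated stand-ins hitting the
documented anchor dimensions (thin ≈ 57/40/68 cm chest/waist/hip, 165 cm
tall, 73 cm inseam; extremes 200/160/180/200/120).

## Worked example

```bash
python examples/weight_curves.py
```

```
gestational weight gain (kg):
  underweight  wk12  2.86  wk24  8.26  term 15.455 (= IOM average 15.455)
  normal       wk12  1.04  wk24  6.44  term 13.635 (= IOM average 13.635)
  ...
postpartum weight retention (kg):
  underweight  wk0  7.7275  wk6  5.997  wk24  3.5707
  obese        wk0  3.5225  wk6  1.979  wk24 -0.1903
```

At delivery a woman retains roughly half her average total gain; obese
women fall slightly below pre-pregnancy weight by six months (negative
retention). `examples/predict_measurements.py` prints the girth
trajectory for one profile (a 60 kg / 160 cm woman reaches a predicted
waist of 107.8 cm at week 36); `examples/synthesize_and_measure.py` and
`examples/calibrate_tensor.py` run the full mesh pipeline.

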