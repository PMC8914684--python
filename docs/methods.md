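# Methods

## Scope and moving parts

`maternshape` chains four stages: (1) regression prediction of body girths
from scalar covariates; (2) a BMI-category model of gestational weight gain
and postpartum weight retention that fills in the weight covariates when
they are unknown; (3) synthesis of a 3D mesh by affine blending of seven
topology-identical avatars; (4) tape-style measurement of meshes by
horizontal cross-sections, which closes the loop for calibration and
validation. The regression tables, gain/retention constants, morph anchor
constants and the built-in correction tensors are published values and are
shipped verbatim; everything geometric (the avatar family, the measurement
protocol, the calibration solver) is this package's own construction.

## Girth regressions

Five responses (chest, waist, hip, upper arm, thigh, all cm) are linear in
the covariates with fixed coefficients; pregnant and postpartum modes have
separate tables. Points worth noting:

* **Inseam is static.** Leg length is measured once (early pregnancy /
  week 0 postpartum) and predicted from the non-pregnant baseline equations
  at *pre-pregnancy* weight; it does not vary with week.
* **One symmetric limb value.** The source cohorts recorded left/right arm
  and thigh but fitted a single row per response; we model one value.
* **Extrapolation policy.** Weeks are clamped to [0, 42] pregnant /
  [0, 24] postpartum with a warning (the validation cohorts included 6–39
  week inputs). A predicted girth ≤ 0 raises an error rather than being
  clamped: it always signals misuse, never a plausible body.
* **Gravida** accepts any integer ≥ 1, although the fitting cohorts only
  contained 1–2; larger values are linear extrapolation.
* Coefficients round-trip through CSV bit-identically (plain `repr`
  floats), so alternative fits can be supplied without precision loss.

## Weight dynamics

WHO BMI categories partition (0, ∞) as [0, 18.5), [18.5, 25), [25, 30),
[30, ∞); the half-open convention closes the gaps left by the printed
ranges (24.9→25.0, 29.9→30.0).

**Gain schedule.** The IOM tables pin only the trimester-2/3 weekly rate
and the total range at term. We take the category's average total gain
(range midpoint), assign `avg_total − 28·rate` to the first trimester
accrued linearly over weeks 0–12, then add the central weekly rate — the
simplest continuous curve through both published anchors.

**Retention curves.** Quadratics in postpartum week per category, shipped
with their printed coefficients. Their week-0 intercepts equal exactly
half the category's average total gain, and their six-month levels derive
from a Taiwanese cohort via the rule of three. The printed normal-weight
six-month value (2.430 kg) disagrees with its own rule-of-three derivation
(2.439 kg) by ~9 g; we ship the printed curves and document the
discrepancy rather than "fixing" it, because the curves are what the
downstream model actually uses. Weeks beyond 24 clamp to 24 (fit domain).

## Avatar family

The seven avatars are parametric humanoids lofted from elliptical
cross-section rings (torso+head, two legs, two arms, flat fan caps), all
generated from one station template so vertex counts, face lists and
anatomical correspondence are identical — the precondition for per-vertex
blending. Conventions: centimetres, Y-up, feet plane at y = 0, bilateral
symmetry about x = 0.

* Each ring polygon is scaled so its *inscribed-polygon perimeter* equals
  the target girth exactly, making the anchor dimensions independent of
  ring resolution.
* The thin avatar's height is fixed at 165 cm (the base anchor of the
  height morph; the published material implies but never states it) and
  its inseam at 73 cm, consistent with the baseline equations at
  60 kg / 165 cm.
* Morph targets are confined to windows around their landmark: the chest
  and hip targets are smooth bumps supported inside their measurement
  bands; the big-waist target lifts the whole waist band to a flat 160 cm
  plateau (the waist landmark is a band *minimum*, so the plateau must
  cover the band) with short cosine ramps outside it; the tall avatar is a
  pure y-scaling and long-legs stretches the legs with the torso shifted
  rigidly upward.
* The pregnant-thin avatar adds an anterior-only belly (18 cm peak
  protrusion, supported from pubis to just below the chest band).
* A seed drives a small (0.02 cm SD) surface jitter applied identically to
  all seven avatars, so morph deltas and blend identities are unaffected.
* The published K05 inseam anchor (offset 78, range 48–120) is internally
  inconsistent with the 73 cm thin inseam; it ships as printed and the
  calibration stage absorbs the offset. Likewise the 1.36 gain factor on
  the height weight makes blended height overshoot its target; the
  calibrated alp4 correction compensates.

## Measurement protocol

Girths are read as the **convex hull perimeter** of a cross-section loop —
a tape measure bridges concavities — with the raw polygon perimeter
available via `MeasureConfig(method="polygon")`. Loops are classified by
centroid: mid-sagittal (|x| ≤ 3 cm) → torso, otherwise arm/leg by side.

Slicing is an exact edge-crossing scan: edges straddling the plane are
intersected and chained into loops through face adjacency, so loop closure
is a topological fact rather than a coordinate-snapping heuristic; the
scan is vectorized over edges and topology is cached per face list.
trimesh's independent `section` routine is used as an oracle in the tests,
not in the pipeline.

Landmark heights are fractions of total height — chest band [0.66, 0.78]
(maximum girth), waist [0.55, 0.66] (minimum), hip [0.45, 0.55] (maximum),
upper arm at 0.75·h, thigh 5 cm below the crotch; the crotch (= inseam) is
found by bisection on the appearance of a mid-sagittal loop. The bands are
this package's convention: the underlying girth protocol prescribes no
heights. Within each band we slice a 9-sample grid over an *interior
window* (chest [0.695, 0.745], hip [0.455, 0.515], waist full band): the
margins keep a landmark from bleeding into a neighbouring band when a
blended body's crotch/height proportion (≈ 0.427–0.450 over realistic
covariates) differs from the template's 0.442, and each window is placed so
its grid hits the template's landmark extremum exactly. A 10⁻⁴·h nudge
keeps sample planes off ring stations.

## Calibration

Per (BMI, week) grid cell, corrections alp1..alp5 are solved so that the
blended mesh, measured by the protocol above, matches the statistical
chest/waist/hip/inseam/height. Upper arm and thigh are excluded: they
have no dedicated morph target (and were the source cohorts' worst
agreement rows). The solver is SciPy's bounded trust-region least squares
(bounds ±1, deterministic start at 0, finite-difference Jacobian,
step 0.01) — a bounded least-squares formulation chosen over per-coordinate
descent because each objective evaluation costs a full blend-and-measure.

**Belly identifiability.** A horizontal-girth protocol cannot separate an
anterior belly (K0) from an all-round waist expansion (K2): six unknowns
would chase five targets. The belly correction therefore follows a fixed
gestation ramp, alp0 = week/40 evaluated at the polynomial-clamped week
(so the full pregnant-belly target is reached at term), expressed exactly
in the tensor's own quadratic form; the girth budget is carried by
alp1..alp5, making the per-cell solve a well-posed 5×5 problem and the
forward/inverse tensor recovery exact to ~10⁻⁴. Consequence: on these
avatars the measured waist growth of a pregnant blend is realized mostly
by the waist morph, with the belly providing the anterior silhouette.

The per-cell corrections are condensed into the tensor form by two
quadratic least-squares stages (in BMI per week, then in week per slot).
Corrections are near-affine in the targets, and the targets are linear in
week and piecewise-smooth in BMI (the gain schedule jumps ~1–2 kg at
category boundaries), so the double quadratic fit loses little: on the
default 4×7 grid the end-to-end mean absolute relative error between
mesh-measured and predicted chest/waist/hip/inseam is ≈ 0.3%, far inside
the 3% fidelity bar used as the acceptance criterion. Cells whose solved
residual exceeds 2 cm are flagged and excluded from the polynomial stage
(none on the default grid).

The default grid (BMI 17/22/27.5/33 × weeks 12–36 pregnant, 0–24
postpartum, at height 160 cm) spans the four BMI categories and each
mode's fit domain; the exact cells are a design choice.

**Agreement statistics** use the normal 1.96·SD/√n 95% CI (not Student-t;
this is what reproduces the published bounds, e.g. 90.76 from mean 94.51,
SD 10.49, n = 30) and an explicit `reference` argument for the
relative-error denominator, because the published comparisons normalize
inconsistently (sometimes by the model mean, sometimes by the manual
mean).

## Synthetic cohorts

Cohorts emulate the source studies' populations: truncated-normal age /
pre-pregnancy weight / height (/ baby weight) with the published
range/mean/SD — the underlying location is shifted so the *truncated* mean
matches the published mean; the SD of the truncated draw is accordingly
slightly below the printed SD — gravida 1–2 at the published mix, visits
every 4 weeks, and independent per-visit Bernoulli retention calibrated to
the published visit counts (expected 587 pregnant / 503 postpartum
records). Weight gain / retention trajectories are the BMI-category curves
scaled by a subject-level multiplier (SD 0.30), and responses are the
regression predictions plus i.i.d. Gaussian noise, default SD 1.0 cm so
~95% of repeat measurements fall within the ±2 cm interrater spread
reported for home tape measurement. Covariates are drawn independently
(the source publishes no correlation structure).

What the cohorts do *not* emulate: covariate correlations (weight–height),
informative dropout, left/right asymmetry, parity > 2, twin pregnancies.
Tests passing on these cohorts therefore demonstrate correctness of the
statistical machinery (exact noise-free recovery, unbiasedness under
noise), not robustness to real-data pathologies.

## Problem sizes and numerical choices

Defaults were chosen so the full loop is comfortable on one CPU: avatars
at 40 vertices/ring (~6k vertices, ~13k faces), 9 samples per landmark
band, 14 crotch bisections (≈ 0.01 cm resolution), calibration grids of
3×3 to 4×7 cells at ≤ 60 objective evaluations per cell. Monte-Carlo
checks of coefficient recovery use 200 seeded replicates at the study's
~587-record scale. Determinism: every stochastic stage takes an explicit
seed; hypothesis runs derandomized.

## Known limitations

* The bundled avatars are geometric stand-ins, not scanned bodies; the
  built-in correction tensors were calibrated against the original
  commercial avatar family and drive only loose girth fidelity on the
  synthetic family — recalibrate (`calibrate_alp`) for faithful output.
* Upper arm and thigh are predicted statistically but not calibrated on
  the mesh.
* The belly/waist split is conventional (see above): silhouettes are
  plausible but the anterior-vs-lateral partition of waist growth is not
  validated against scan data.
* Published cohort-level correlations with real volunteers cannot be
  reproduced here: the underlying raw measurements are not public.
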