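"""Round-trip the girth regressions through a synthetic cohort.

Generates a longitudinal pregnant cohort (98 subjects, 7 visits, per-visit
attrition matching the study's visit counts, 1 cm measurement noise),
refits the regressions by OLS, and compares the recovered chest row with
the shipped coefficients.
"""

from maternshape import CohortSpec, RegressionCoefficients, fit_measurement_regression, generate_cohort

spec = CohortSpec(mode="pregnant", n_subjects=98, seed=42, noise_sd_cm=1.0)
records = generate_cohort(spec)
print(f"{len(records)} visit records from {spec.n_subjects} subjects")

fitted = fit_measurement_regression(records, "pregnant")
truth = RegressionCoefficients.pregnant_default()
print("\nchest row (fitted vs shipped):")
for col in fitted.table.columns:
    print(f"  {col:26s} {fitted.table.loc['chest', col]:8.3f} {truth.table.loc['chest', col]:8.3f}")

print(
    "\nWith ~590 noisy records the OLS refit lands close to the shipped\n"
    "coefficients; with noise_sd_cm=0 the recovery is exact to machine\n"
    "precision (see the test suite)."
)
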