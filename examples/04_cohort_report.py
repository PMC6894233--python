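"""Simulate a 5-year cohort and build the full results report.

Draws 60 patients with the study's lesion rates, progression mixtures,
DAPSA trajectories and treatment exposure, classifies every lesion's
change, and assembles lesion counts, volume statistics with the paired
longitudinal test, and the SDL / TNFi group comparisons.
"""

from erosiotrack import (
    CohortSpec,
    build_report,
    classify_table,
    format_report,
    simulate_cohort,
)

lesions, patients = simulate_cohort(CohortSpec(seed=42))
print(
    f"simulated {len(patients)} patients, "
    f"{(lesions.kind == 'erosion').sum()} erosions, "
    f"{(lesions.kind == 'enthesiophyte').sum()} enthesiophytes"
)

dynamics = classify_table(lesions)
report = build_report(dynamics, patients)
print(format_report(report))
# Counts and proportions echo the study's structure (about 108 erosions
# and 99 enthesiophytes at baseline, ~1/3 of erosions and ~1/2 of
# enthesiophytes progressing); the SDL group shows the lower progression
# rates its mixture encodes. p-values are uncorrected Pearson chi-square
# for progression counts and a normality-gated two-sample test for mean
# volume change.
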