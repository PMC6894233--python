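"""Smallest detectable change and SDC-thresholded progression calls.

Estimates the measurement-error floor from lesions scored twice, then
classifies the study's printed per-lesion change structure against the
working thresholds (0.5 mm^3 erosions, 0.3 mm^3 enthesiophytes).
"""

import numpy as np
import pandas as pd

from erosiotrack import (
    classify_table,
    cumulative_probability_data,
    smallest_detectable_change,
    summarize_dynamics,
)

# 30 erosions scored twice with reader noise of ~0.36 mm^3 per reading
rng = np.random.default_rng(0)
true_vol = rng.uniform(0.5, 12.0, 30)
reading_1 = true_vol + rng.normal(0, 0.36, 30)
reading_2 = true_vol + rng.normal(0, 0.36, 30)
est = smallest_detectable_change(reading_2 - reading_1, k=2, kind="erosion")
print(
    f"SDC from {est.n_lesions} repeated readings: {est.sdc_mm3:.2f} mm^3 "
    f"(change-score SD {est.sd_change_scores:.2f}, k={est.k})"
)
# With ~0.36 mm^3 reader noise the SDC lands near the study's working
# erosion threshold of 0.5 mm^3.

# per-lesion changes with the study's class structure: 37/64/10 of 111
# erosions (3 new), 50/38/11 of 99 enthesiophytes, at each class's mean
rows = []
for kind, n, delta, new in [
    ("erosion", 34, 1.9, False), ("erosion", 3, 1.2, True),
    ("erosion", 64, 0.1, False), ("erosion", 10, -1.4, False),
    ("enthesiophyte", 50, 1.0, False), ("enthesiophyte", 38, 0.1, False),
    ("enthesiophyte", 11, -0.7, False),
]:
    for _ in range(n):
        rows.append({"lesion_id": len(rows), "kind": kind,
                     "delta_mm3": delta, "is_new": new})
dynamics = classify_table(pd.DataFrame(rows))

print(summarize_dynamics(dynamics).to_string(index=False))
# Erosions: 37/111 (33.3%) progress, 64/111 (57.7%) stable, 10/111 (9.0%)
# regress; enthesiophytes: 50/99 (50.5%) progress.

series = cumulative_probability_data(dynamics)
ero = series[series.kind == "erosion"]
print(
    f"cumulative-probability series: {len(ero)} erosion points, "
    f"deltas {ero.delta_mm3.min():+.1f} .. {ero.delta_mm3.max():+.1f} mm^3"
)
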