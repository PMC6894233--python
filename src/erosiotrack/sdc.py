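"""Smallest detectable change and SDC-thresholded progression calls.

SDC is the Bland–Altman-type measurement-error floor derived from lesions
scored repeatedly:

    SDC = 1.96 * SD_change_scores / (sqrt(2) * sqrt(k))

with k the number of readings and the SD taken over per-lesion differences
between readings (n-1 denominator). A lesion progresses when its 5-year
volume change strictly exceeds +SDC — or when it is newly formed —
regresses when the change strictly exceeds -SDC downward, and is stable
otherwise. The study's working thresholds are 0.5 mm^3 for erosions and
0.3 mm^3 for enthesiophytes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SDCEstimate",
    "DEFAULT_SDC_MM3",
    "smallest_detectable_change",
    "sdc_from_readings",
    "classify_lesion_change",
    "classify_table",
    "summarize_dynamics",
    "cumulative_probability_data",
]

#: study working thresholds, mm^3
DEFAULT_SDC_MM3 = {"erosion": 0.5, "enthesiophyte": 0.3}


@dataclass(frozen=True)
class SDCEstimate:
    kind: str
    sdc_mm3: float
    k: int
    n_lesions: int
    sd_change_scores: float


def smallest_detectable_change(
    change_scores, k: int = 2, kind: str = ""
) -> SDCEstimate:
    """SDC from per-lesion differences between repeated readings."""
    scores = np.asarray(change_scores, dtype=float)
    if scores.ndim != 1 or len(scores) < 2:
        raise ValueError("need at least 2 change scores")
    if k < 2:
        raise ValueError("k (number of readings) must be >= 2")
    sd = float(np.std(scores, ddof=1))
    sdc = 1.96 * sd / (np.sqrt(2.0) * np.sqrt(k))
    return SDCEstimate(kind=kind, sdc_mm3=float(sdc), k=k, n_lesions=len(scores),
                       sd_change_scores=sd)


def sdc_from_readings(readings: pd.DataFrame, kind: str = "") -> SDCEstimate:
    """SDC from a table with ``reading_1_mm3`` and ``reading_2_mm3`` columns."""
    cols = [c for c in readings.columns if c.startswith("reading_")]
    if len(cols) < 2:
        raise ValueError("readings table needs >= 2 reading_* columns")
    r = readings[sorted(cols)].to_numpy(dtype=float)
    if (r < 0).any():
        raise ValueError("readings must be non-negative volumes")
    return smallest_detectable_change(r[:, 1] - r[:, 0], k=r.shape[1], kind=kind)


def classify_lesion_change(
    delta_mm3: float, sdc_mm3: float, is_new: bool = False
) -> str:
    """Progression / stable / regression call for one lesion.

    Strict inequalities (change must *exceed* the SDC); a newly formed
    lesion is progression regardless of its volume.
    """
    if sdc_mm3 < 0:
        raise ValueError("sdc_mm3 must be >= 0")
    if is_new or delta_mm3 > sdc_mm3:
        return "progression"
    if delta_mm3 < -sdc_mm3:
        return "regression"
    return "stable"


def classify_table(
    pairs: pd.DataFrame, sdc_mm3: dict[str, float] | None = None
) -> pd.DataFrame:
    """Attach a ``category`` column to a lesion-pair/change table.

    Expects ``kind``, ``delta_mm3`` and (optionally) ``is_new`` columns;
    kind-specific SDC thresholds default to the study values.
    """
    sdc = DEFAULT_SDC_MM3 if sdc_mm3 is None else sdc_mm3
    out = pairs.copy()
    is_new = out["is_new"] if "is_new" in out else pd.Series(False, index=out.index)
    out["category"] = [
        classify_lesion_change(d, sdc[k], bool(n))
        for d, k, n in zip(out["delta_mm3"], out["kind"], is_new)
    ]
    return out


def summarize_dynamics(dynamics: pd.DataFrame) -> pd.DataFrame:
    """Per-kind, per-category counts, proportions and delta mean +/- SD.

    Proportions are percentages of the kind's total (follow-up denominator:
    new lesions included). SD is NaN for singleton categories.
    """
    if len(dynamics) == 0:
        raise ValueError("empty dynamics table")
    rows = []
    for kind, g in dynamics.groupby("kind", sort=True):
        total = len(g)
        for cat in ("progression", "stable", "regression"):
            sub = g[g["category"] == cat]
            d = sub["delta_mm3"].to_numpy(dtype=float)
            rows.append(
                {
                    "kind": kind,
                    "category": cat,
                    "n": len(sub),
                    "total": total,
                    "proportion_pct": 100.0 * len(sub) / total,
                    "mean_delta_mm3": float(d.mean()) if len(d) else np.nan,
                    "sd_delta_mm3": float(d.std(ddof=1)) if len(d) > 1 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def cumulative_probability_data(dynamics: pd.DataFrame) -> pd.DataFrame:
    """Ordered per-lesion series behind a cumulative-probability plot.

    Within each kind, lesions are sorted by ascending volume change (ties
    by lesion id) and ranked 1..n, carrying their category — one dot per
    lesion, colored by dynamic, as the plot draws them.
    """
    if len(dynamics) == 0:
        raise ValueError("empty dynamics table")
    parts = []
    for _, g in dynamics.groupby("kind", sort=True):
        g = g.sort_values(["delta_mm3", "lesion_id"], kind="stable").copy()
        g["rank"] = np.arange(1, len(g) + 1)
        parts.append(g)
    cols = ["kind", "rank", "lesion_id", "delta_mm3", "category"]
    return pd.concat(parts, ignore_index=True)[cols]
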