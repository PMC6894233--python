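"""Patient-level grouping and group-comparison statistics.

DAPSA (Disease Activity index for PSoriatic Arthritis) is the sum of
tender joint count, swollen joint count, patient pain VAS (cm), patient
global VAS (cm) and CRP (mg/dL), banded REM <=4 < LDA <=14 < MDA <=28 <
HDA. Patients sustaining DAPSA-LDA at both time points form the SDL group;
patients on a TNF inhibitor throughout follow-up form the TNFi group.
Lesion-level progression counts are compared between groups with the
uncorrected Pearson chi-square; volume changes with a normality-gated
two-sample test; longitudinal change with a normality-gated paired test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DAPSAComponents",
    "GroupComparison",
    "PairedTestResult",
    "dapsa_score",
    "dapsa_category",
    "assign_groups",
    "chi_square_2x2",
    "compare_progression_counts",
    "compare_mean_deltas",
    "paired_change_test",
    "build_report",
    "format_report",
]

GROUPINGS = {"sdl": ("SDL", "non-SDL"), "tnfi": ("TNFi", "non-TNFi")}


@dataclass(frozen=True)
class DAPSAComponents:
    tender_joint_count: float
    swollen_joint_count: float
    patient_pain_vas_cm: float
    patient_global_vas_cm: float
    crp_mg_dl: float

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        for name in ("patient_pain_vas_cm", "patient_global_vas_cm"):
            if getattr(self, name) > 10:
                raise ValueError(f"{name} is a 0-10 cm VAS, got {getattr(self, name)}")


@dataclass
class GroupComparison:
    grouping: str
    kind: str
    outcome: str
    group_labels: tuple[str, str]
    group_summaries: tuple[dict, dict]
    statistic: float
    p_value: float
    test: str


@dataclass
class PairedTestResult:
    test: str
    statistic: float
    p_value: float
    n: int
    all_zero: bool = False


def dapsa_score(c: DAPSAComponents) -> float:
    """Sum of the five DAPSA components."""
    return (
        c.tender_joint_count
        + c.swollen_joint_count
        + c.patient_pain_vas_cm
        + c.patient_global_vas_cm
        + c.crp_mg_dl
    )


def dapsa_category(score: float) -> str:
    """Disease-activity band: REM <=4, LDA <=14, MDA <=28, HDA >28."""
    if score < 0:
        raise ValueError("DAPSA score must be >= 0")
    if score <= 4:
        return "REM"
    if score <= 14:
        return "LDA"
    if score <= 28:
        return "MDA"
    return "HDA"


def assign_groups(patients: pd.DataFrame) -> pd.DataFrame:
    """Derive SDL and TNFi group flags from a patient table.

    Requires ``dapsa_t0``/``dapsa_t5`` and ``tnfi_throughout`` columns; SDL
    means DAPSA <= 14 at both time points. Patients with a missing DAPSA
    time point are dropped with a warning.
    """
    out = patients.copy()
    missing = out["dapsa_t0"].isna() | out["dapsa_t5"].isna()
    if missing.any():
        warnings.warn(
            f"excluding {int(missing.sum())} patient(s) with a missing DAPSA "
            "time point",
            stacklevel=2,
        )
        out = out[~missing].copy()
    out["sdl"] = (out["dapsa_t0"] <= 14) & (out["dapsa_t5"] <= 14)
    out["tnfi"] = out["tnfi_throughout"].astype(bool)
    return out


def chi_square_2x2(table) -> tuple[float, float]:
    """Uncorrected Pearson chi-square on a 2x2 count table.

    Rows are groups, columns (progressed, not progressed). Returns
    ``(nan, nan)`` when a margin is empty.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return (np.nan, np.nan)
    chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(chi2), float(p)


def _split_by_group(dynamics, patients, grouping):
    flag = {"sdl": "sdl", "tnfi": "tnfi"}[grouping]
    merged = dynamics.merge(patients[["patient_id", flag]], on="patient_id",
                            validate="many_to_one")
    if merged[flag].isna().any() or len(merged) != len(dynamics):
        raise ValueError("every lesion must map to a grouped patient")
    return merged[merged[flag]], merged[~merged[flag]]


def compare_progression_counts(
    dynamics: pd.DataFrame, patients: pd.DataFrame, kind: str, grouping: str = "sdl"
) -> GroupComparison:
    """Lesion-level 2x2 progression comparison between patient groups."""
    g1, g2 = _split_by_group(dynamics[dynamics["kind"] == kind], patients, grouping)
    table = []
    summaries = []
    for g in (g1, g2):
        prog = int((g["category"] == "progression").sum())
        table.append([prog, len(g) - prog])
        summaries.append(
            {
                "n_lesions": len(g),
                "n_progressed": prog,
                "progressed_pct": 100.0 * prog / len(g) if len(g) else np.nan,
            }
        )
    chi2, p = chi_square_2x2(table)
    return GroupComparison(
        grouping=grouping,
        kind=kind,
        outcome="progression counts",
        group_labels=GROUPINGS[grouping],
        group_summaries=tuple(summaries),
        statistic=chi2,
        p_value=p,
        test="pearson chi-square (uncorrected)",
    )


def _two_sample_test(a: np.ndarray, b: np.ndarray) -> tuple[str, float, float]:
    if np.ptp(np.concatenate([a, b])) == 0:  # all values identical
        return ("degenerate", 0.0, 1.0)
    if a.std(ddof=1) == 0 or b.std(ddof=1) == 0:
        u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        return ("mann-whitney", float(u), float(p))
    if stats.shapiro(a).pvalue > 0.05 and stats.shapiro(b).pvalue > 0.05:
        t, p = stats.ttest_ind(a, b)
        return ("t-test", float(t), float(p))
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return ("mann-whitney", float(u), float(p))


def compare_mean_deltas(
    dynamics: pd.DataFrame, patients: pd.DataFrame, kind: str, grouping: str = "sdl"
) -> GroupComparison:
    """Per-group mean +/- SD volume change with a normality-gated test.

    Shapiro–Wilk at alpha 0.05 on each group selects Student's t (both
    normal) or the Mann–Whitney rank test; degenerate variance falls back
    to the rank test.
    """
    g1, g2 = _split_by_group(dynamics[dynamics["kind"] == kind], patients, grouping)
    a = g1["delta_mm3"].to_numpy(dtype=float)
    b = g2["delta_mm3"].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 lesions per group")
    test, statistic, p = _two_sample_test(a, b)
    summaries = tuple(
        {"n_lesions": len(x), "mean_delta_mm3": float(x.mean()),
         "sd_delta_mm3": float(x.std(ddof=1))}
        for x in (a, b)
    )
    return GroupComparison(
        grouping=grouping,
        kind=kind,
        outcome="mean volume change",
        group_labels=GROUPINGS[grouping],
        group_summaries=summaries,
        statistic=statistic,
        p_value=p,
        test=test,
    )


def paired_change_test(volumes_t0, volumes_t5) -> PairedTestResult:
    """Baseline-vs-follow-up test on paired lesion volumes.

    Shapiro–Wilk at alpha 0.05 on the paired differences selects the paired
    t test (normal) or the Wilcoxon signed-rank test; identical series give
    p = 1 with a flag.
    """
    t0 = np.asarray(volumes_t0, dtype=float)
    t5 = np.asarray(volumes_t5, dtype=float)
    if t0.shape != t5.shape or t0.ndim != 1:
        raise ValueError("paired series must be 1-D and equal length")
    if len(t0) < 3:
        raise ValueError("need >= 3 pairs")
    d = t5 - t0
    if np.all(d == 0):
        return PairedTestResult("degenerate", 0.0, 1.0, len(d), all_zero=True)
    if stats.shapiro(d).pvalue > 0.05:
        t, p = stats.ttest_rel(t5, t0)
        return PairedTestResult("paired t", float(t), float(p), len(d))
    w, p = stats.wilcoxon(d, alternative="two-sided")
    return PairedTestResult("wilcoxon signed-rank", float(w), float(p), len(d))


# ---------------------------------------------------------------------------
# reporting


def _vol_stats(x: np.ndarray) -> dict:
    if len(x) == 0:
        return {"n": 0, "mean": np.nan, "sd": np.nan}
    return {
        "n": int(len(x)),
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)) if len(x) > 1 else np.nan,
    }


def build_report(
    dynamics: pd.DataFrame,
    patients: pd.DataFrame | None = None,
    compartments: tuple[str, ...] = ("MCH2", "MCH3"),
) -> dict:
    """Assemble the study-style results report from a classified table.

    ``dynamics`` needs kind / compartment / vol_t0_mm3 / vol_t5_mm3 /
    delta_mm3 / is_new / category (and patient_id when ``patients`` is
    given). Produces lesion counts per kind and compartment, per-lesion
    volume summaries with the paired longitudinal test, dynamics
    proportions, cumulative-probability series, and — with a patient table
    — SDL and TNFi group comparisons.
    """
    from .sdc import cumulative_probability_data, summarize_dynamics

    report: dict = {"counts": {}, "volumes": {}, "dynamics": {}, "figure1": {}}
    for kind in ("erosion", "enthesiophyte"):
        g = dynamics[dynamics["kind"] == kind]
        if len(g) == 0:
            report["counts"][kind] = None
            report["volumes"][kind] = None
            continue
        existing = g[~g["is_new"]]
        counts = {
            "baseline_total": int(len(existing)),
            "followup_total": int(len(g)),
            "new": int(g["is_new"].sum()),
        }
        for comp in compartments:
            gc = g[g["compartment"] == comp]
            counts[comp] = {
                "baseline": int((~gc["is_new"]).sum()),
                "followup": int(len(gc)),
                "new": int(gc["is_new"].sum()),
            }
        report["counts"][kind] = counts

        vols = {}
        for comp in list(compartments) + ["all"]:
            gc = g if comp == "all" else g[g["compartment"] == comp]
            ex = gc[~gc["is_new"]]
            entry = {
                "baseline": _vol_stats(ex["vol_t0_mm3"].to_numpy(float)),
                "followup": _vol_stats(gc["vol_t5_mm3"].to_numpy(float)),
                "change": _vol_stats(gc["delta_mm3"].to_numpy(float)),
            }
            if len(gc) >= 3:
                pt = paired_change_test(gc["vol_t0_mm3"], gc["vol_t5_mm3"])
                entry["paired_test"] = {"test": pt.test, "p_value": pt.p_value}
            vols[comp] = entry
        report["volumes"][kind] = vols

    report["dynamics"] = summarize_dynamics(dynamics).to_dict(orient="records")
    report["figure1"] = {
        kind: g.drop(columns="kind").to_dict(orient="records")
        for kind, g in cumulative_probability_data(dynamics).groupby("kind")
    }

    if patients is not None:
        grouped = assign_groups(patients)
        comp = {}
        for grouping in ("sdl", "tnfi"):
            comp[grouping] = {}
            for kind in ("erosion", "enthesiophyte"):
                if len(dynamics[dynamics["kind"] == kind]) == 0:
                    comp[grouping][kind] = None
                    continue
                try:
                    counts_cmp = compare_progression_counts(
                        dynamics, grouped, kind, grouping
                    )
                    deltas_cmp = compare_mean_deltas(
                        dynamics, grouped, kind, grouping
                    )
                except ValueError:  # a group too small to compare
                    comp[grouping][kind] = None
                    continue
                comp[grouping][kind] = {
                    "progression": {
                        "groups": counts_cmp.group_summaries,
                        "chi2": counts_cmp.statistic,
                        "p_value": counts_cmp.p_value,
                    },
                    "mean_change": {
                        "groups": deltas_cmp.group_summaries,
                        "test": deltas_cmp.test,
                        "p_value": deltas_cmp.p_value,
                    },
                }
        report["group_comparisons"] = comp
        report["patients"] = {
            "n": int(len(grouped)),
            "n_sdl": int(grouped["sdl"].sum()),
            "n_tnfi": int(grouped["tnfi"].sum()),
        }
    return report


def format_report(report: dict) -> str:
    """Human-readable rendering: volumes to 1 decimal, proportions to 0.1%."""
    lines = []
    for kind in ("erosion", "enthesiophyte"):
        c = report["counts"].get(kind)
        if c is None:
            lines.append(f"{kind}: not available")
            continue
        lines.append(
            f"{kind}s: {c['baseline_total']} baseline / "
            f"{c['followup_total']} follow-up / {c['new']} new"
        )
        v = report["volumes"][kind]["all"]
        lines.append(
            f"  volume (mm3): {v['baseline']['mean']:.1f} ± {v['baseline']['sd']:.1f}"
            f" -> {v['followup']['mean']:.1f} ± {v['followup']['sd']:.1f}"
            f" (change {v['change']['mean']:.1f} ± {v['change']['sd']:.1f}"
            + (
                f", p={v['paired_test']['p_value']:.3g}" if "paired_test" in v else ""
            )
            + ")"
        )
    for row in report["dynamics"]:
        lines.append(
            f"  {row['kind']} {row['category']}: {row['n']}/{row['total']} "
            f"({row['proportion_pct']:.1f}%)"
        )
    for grouping, kinds in report.get("group_comparisons", {}).items():
        for kind, entry in kinds.items():
            if entry is None:
                continue
            g1, g2 = entry["progression"]["groups"]
            lines.append(
                f"{GROUPINGS[grouping][0]} vs {GROUPINGS[grouping][1]}, {kind}: "
                f"progression {g1['n_progressed']}/{g1['n_lesions']} "
                f"({g1['progressed_pct']:.1f}%) vs "
                f"{g2['n_progressed']}/{g2['n_lesions']} "
                f"({g2['progressed_pct']:.1f}%), p={entry['progression']['p_value']:.3f}"
            )
    return "\n".join(lines)
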