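"""Relative expression from Cq tables via the 2^-ddCq method.

Per condition, dCq = mean Cq(assay) - mean Cq(reference); ddCq subtracts the
calibrator condition's dCq, and fold change = 2^-ddCq, so the calibrator is
exactly 1. Replicates are aggregated by the arithmetic mean of Cq before
subtraction; spread is reported both as the SD of per-replicate dCq and as
the SD of the per-replicate fold changes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["fold_changes", "call_stress_responsive", "crosstalk"]

REQUIRED_COLUMNS = {"condition", "assay", "replicate", "cq"}


def fold_changes(
    records: pd.DataFrame,
    reference_assay: str,
    calibrator: str,
) -> pd.DataFrame:
    """2^-ddCq fold-change profile per assay and condition.

    Conditions lacking the reference assay are reported with NaN fold change
    (missing, not zero). The reference must be measured in the calibrator.
    """
    missing = REQUIRED_COLUMNS - set(records.columns)
    if missing:
        raise ValueError(f"Cq table lacks columns: {sorted(missing)}")
    if (records["cq"] <= 0).any():
        raise ValueError("Cq values must be positive")
    if calibrator not in set(records["condition"]):
        raise ValueError(f"calibrator condition {calibrator!r} absent from table")

    ref = records[records["assay"] == reference_assay]
    if ref.empty:
        raise ValueError(f"reference assay {reference_assay!r} absent from table")
    ref_mean = ref.groupby("condition")["cq"].mean()
    if calibrator not in ref_mean:
        raise ValueError("reference assay missing in the calibrator condition")

    rows = []
    for (assay, condition), group in records.groupby(["assay", "condition"], sort=True):
        if assay == reference_assay:
            continue
        if condition not in ref_mean.index:
            rows.append(
                {
                    "assay": assay,
                    "condition": condition,
                    "n_replicates": len(group),
                    "delta_cq": np.nan,
                    "fold_change": np.nan,
                    "sd_delta_cq": np.nan,
                    "sd_fold": np.nan,
                    "missing_reference": True,
                }
            )
            continue
        dcq_reps = group["cq"].to_numpy() - ref_mean[condition]
        rows.append(
            {
                "assay": assay,
                "condition": condition,
                "n_replicates": len(group),
                "delta_cq": float(np.mean(dcq_reps)),
                "fold_change": np.nan,  # filled after the calibrator pass
                "sd_delta_cq": float(np.std(dcq_reps, ddof=1)) if len(dcq_reps) > 1 else 0.0,
                "sd_fold": np.nan,
                "missing_reference": False,
                "_dcq_reps": dcq_reps,
            }
        )
    profile = pd.DataFrame(rows)
    if profile.empty:
        return profile

    for assay, group in profile.groupby("assay"):
        cal = group[group["condition"] == calibrator]
        if cal.empty or cal.iloc[0]["missing_reference"]:
            raise ValueError(f"assay {assay!r} lacks a calibrator measurement")
        cal_dcq = cal.iloc[0]["delta_cq"]
        for idx in group.index:
            if profile.at[idx, "missing_reference"]:
                continue
            if profile.at[idx, "condition"] == calibrator:
                profile.at[idx, "fold_change"] = 1.0  # exact by definition
                ddcq_reps = profile.at[idx, "_dcq_reps"] - cal_dcq
            else:
                ddcq = profile.at[idx, "delta_cq"] - cal_dcq
                profile.at[idx, "fold_change"] = 2.0 ** (-ddcq)
                ddcq_reps = profile.at[idx, "_dcq_reps"] - cal_dcq
            folds = 2.0 ** (-np.asarray(ddcq_reps, dtype=float))
            profile.at[idx, "sd_fold"] = (
                float(np.std(folds, ddof=1)) if len(folds) > 1 else 0.0
            )
    return profile.drop(columns=["_dcq_reps"]).reset_index(drop=True)


def call_stress_responsive(
    folds: "pd.Series | dict[str, float] | list[float]",
    threshold: float = 2.0,
    mode: str = "pairwise",
) -> dict:
    """Responsiveness call over a time-point fold-change profile.

    ``pairwise`` mode (default): responsive iff the maximal ratio between any
    two time points exceeds the threshold. ``baseline`` mode compares every
    time point against the first only.
    """
    if isinstance(folds, dict):
        values = list(folds.values())
    elif isinstance(folds, pd.Series):
        values = folds.tolist()
    else:
        values = list(folds)
    if len(values) < 2:
        raise ValueError("need at least two time points")
    if any(v is None or v <= 0 or np.isnan(v) for v in values):
        raise ValueError("fold changes must be positive")
    if mode == "pairwise":
        ratio = max(values) / min(values)
    elif mode == "baseline":
        base = values[0]
        ratio = max(max(v / base for v in values), max(base / v for v in values))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return {"responsive": ratio > threshold, "max_ratio": float(ratio)}


def crosstalk(calls_by_stressor: dict[str, "set[str] | list[str]"]) -> set[str]:
    """Assays responsive under at least two stressors (set intersection)."""
    if len(calls_by_stressor) < 2:
        raise ValueError("crosstalk requires calls from >= 2 stressors")
    sets = [set(v) for v in calls_by_stressor.values()]
    shared: set[str] = set()
    for i, a in enumerate(sets):
        for b in sets[i + 1 :]:
            shared |= a & b
    return shared
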