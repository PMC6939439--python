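"""Benchmark-cohort machinery: entry-selection filters and resolution-binned
summary statistics with SEM confidence bands.

Entries are pandas DataFrame rows with at least: id, resolution (A), r_work
(%), r_free (%), completeness (%), twinned (bool), plus any metric columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FILTER_THRESHOLDS", "filter_entries", "binned_stats", "BinnedSeries"]

# selection thresholds for the paired-refinement cohort
FILTER_THRESHOLDS = {
    "completeness_min": 90.0,   # %
    "r_free_max": 35.0,         # %
    "r_work_max": 30.0,         # %
    "r_delta_min": 1.5,         # % (r_free - r_work)
    "resolution_max": 3.65,     # A
}

_REQUIRED = ["resolution", "r_work", "r_free", "completeness", "twinned"]


def filter_entries(records: pd.DataFrame, return_rejects: bool = False):
    """Apply the cohort selection filters.

    Keeps untwinned entries with completeness >= 90%, R_free <= 35%,
    R_work <= 30%, R_delta = R_free - R_work >= 1.5% and resolution
    <= 3.65 A.  Records with missing fields are rejected with a reason code.
    Idempotent: filtering a filtered frame changes nothing.
    """
    t = FILTER_THRESHOLDS
    keep_idx = []
    reasons = {}
    for idx, row in records.iterrows():
        reason = None
        missing = [c for c in _REQUIRED if c not in row or pd.isna(row[c])]
        if missing:
            reason = f"missing:{','.join(missing)}"
        elif bool(row["twinned"]):
            reason = "twinned"
        elif row["completeness"] < t["completeness_min"]:
            reason = "completeness"
        elif row["r_free"] > t["r_free_max"]:
            reason = "r_free"
        elif row["r_work"] > t["r_work_max"]:
            reason = "r_work"
        elif (row["r_free"] - row["r_work"]) < t["r_delta_min"]:
            reason = "r_delta"
        elif row["resolution"] > t["resolution_max"]:
            reason = "resolution"
        if reason is None:
            keep_idx.append(idx)
        else:
            reasons[idx] = reason
    kept = records.loc[keep_idx]
    if return_rejects:
        return kept, reasons
    return kept


@dataclass
class BinnedSeries:
    """Per-resolution-bin summary; bins with n < 10 are dropped."""

    bin_center: np.ndarray
    n: np.ndarray
    mean: np.ndarray
    sem: np.ndarray

    @property
    def ci95(self) -> np.ndarray:
        return 1.96 * self.sem

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_center": self.bin_center,
                "n": self.n,
                "mean": self.mean,
                "sem": self.sem,
                "ci95": self.ci95,
            }
        )


def binned_stats(
    records: pd.DataFrame, metric: str, bin_width: float = 0.1, min_count: int = 10
) -> BinnedSeries:
    """Mean, SEM (sample sd / sqrt(n)) and 95% CI per resolution bin.

    Bins are half-open [x, x + width) anchored at the data minimum rounded
    down to the bin width; bins with fewer than ``min_count`` entries are
    eliminated.
    """
    if len(records) == 0:
        raise ValueError("no records")
    if metric not in records.columns:
        raise KeyError(f"metric {metric!r} not in records")
    res = records["resolution"].to_numpy(float)
    vals = records[metric].to_numpy(float)
    lo = np.floor(res.min() / bin_width) * bin_width
    idx = np.floor((res - lo) / bin_width).astype(int)
    centers, ns, means, sems = [], [], [], []
    for b in sorted(set(idx)):
        v = vals[idx == b]
        if len(v) < min_count:
            continue
        centers.append(lo + (b + 0.5) * bin_width)
        ns.append(len(v))
        means.append(float(np.mean(v)))
        sems.append(float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0)
    return BinnedSeries(
        bin_center=np.array(centers),
        n=np.array(ns, int),
        mean=np.array(means),
        sem=np.array(sems),
    )
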