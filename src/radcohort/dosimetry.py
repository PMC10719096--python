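"""Per-exam dose ensembles -> per-person exposure metrics.

Each CT examination carries a Monte-Carlo ensemble of plausible absorbed
doses to the active bone marrow (ABM, mGy).  This module summarizes the
ensembles (mean or median), builds per-person cumulative lagged dose
trajectories, assigns dose categories, decomposes cumulative dose into
age-at-exposure / time-since-exposure windows, and selects percentile-
truncated sub-cohorts.

Boundary convention: an exam received at age ``a`` contributes to the
cumulative dose at attained age ``t`` with lag ``l`` iff ``a <= t - l``
(an event exactly ``l`` years after an exam counts that exam's dose).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_CUTPOINTS",
    "DoseHistory",
    "build_dose_histories",
    "categorize_dose",
    "cumulative_dose_at",
    "decompose_dose_windows",
    "summarize_doses_long",
    "summarize_ensemble",
    "truncate_at_percentile",
]

#: cumulative ABM dose cutpoints (mGy) delimiting the study's six categories
#: [0,5), [5,10), [10,15), [15,25), [25,50), [50, max]
DEFAULT_CUTPOINTS = (5.0, 10.0, 15.0, 25.0, 50.0)


def summarize_ensemble(realizations, method: str = "mean") -> float:
    """Summarize one exam's dose-realization ensemble to a single mGy value."""
    arr = np.asarray(realizations, dtype=float)
    if arr.size == 0:
        raise ValueError("empty dose ensemble")
    if method == "mean":
        return float(arr.mean())
    if method == "median":
        return float(np.median(arr))
    raise ValueError(f"unknown summary method {method!r}")


def summarize_doses_long(doses_long: pd.DataFrame) -> pd.DataFrame:
    """Summarize a long-format realization table to per-exam mean and median.

    Input columns: exam_id, realization_index, abm_dose_mGy.
    """
    g = doses_long.groupby("exam_id")["abm_dose_mGy"]
    out = pd.DataFrame({"abm_dose_mean": g.mean(),
                        "abm_dose_median": g.median()}).reset_index()
    return out


@dataclass
class DoseHistory:
    """Per-person step function: age of exam -> dose increment (mGy).

    ``metric`` names the exposure metric carried in ``doses``:
    ``abm_dose_mean``, ``abm_dose_median`` or ``exam_count`` (dose 1 per
    exam).  Ages are sorted; cumulative dose is the prefix sum.
    """

    person_id: str
    ages: np.ndarray          # sorted exam ages, years
    doses: np.ndarray         # dose increments, mGy (or 1.0 for exam_count)
    metric: str = "abm_dose_mean"

    def __post_init__(self) -> None:
        order = np.argsort(self.ages, kind="stable")
        self.ages = np.asarray(self.ages, float)[order]
        self.doses = np.asarray(self.doses, float)[order]
        if (self.doses < 0).any():
            raise ValueError("negative dose in history")
        self.cum = np.cumsum(self.doses)


def cumulative_dose_at(history: DoseHistory, age: float, lag: float) -> float:
    """Cumulative lagged dose Z(age): sum over exams with age_at_exam <= age - lag."""
    if lag < 0:
        raise ValueError("lag must be >= 0")
    k = int(np.searchsorted(history.ages, age - lag, side="right"))
    return float(history.cum[k - 1]) if k else 0.0


def categorize_dose(z, cutpoints=DEFAULT_CUTPOINTS):
    """Half-open dose category index: bin k means cutpoints[k-1] <= Z < cutpoints[k].

    The last bin is closed above at the cohort maximum.  Accepts scalars or
    arrays; raises on negative dose.
    """
    arr = np.asarray(z, dtype=float)
    if (arr < 0).any():
        raise ValueError("negative cumulative dose")
    cut = np.asarray(cutpoints, float)
    if not np.all(np.diff(cut) > 0):
        raise ValueError("cutpoints must be strictly increasing")
    idx = np.searchsorted(cut, arr, side="right")
    return idx if arr.ndim else int(idx)


def decompose_dose_windows(history: DoseHistory, age: float, lag: float,
                           windows, by: str = "age_at_exposure") -> np.ndarray:
    """Split Z(age) into exposure windows; components sum to the total exactly.

    ``windows`` is a sequence of (low, high) half-open intervals [low, high)
    partitioning the axis:  exam age for ``by='age_at_exposure'``, or
    ``age - age_at_exam`` (time since exposure, floored at the lag) for
    ``by='time_since_exposure'``.
    """
    wins = [(float(a), float(b)) for a, b in windows]
    wins_sorted = sorted(wins)
    for (a1, b1), (a2, _b2) in zip(wins_sorted, wins_sorted[1:]):
        if a2 < b1:
            raise ValueError("overlapping windows")
    k = int(np.searchsorted(history.ages, age - lag, side="right"))
    ages = history.ages[:k]
    doses = history.doses[:k]
    axis = ages if by == "age_at_exposure" else age - ages
    if by not in ("age_at_exposure", "time_since_exposure"):
        raise ValueError(f"unknown decomposition axis {by!r}")
    out = np.zeros(len(wins))
    for m, (lo, hi) in enumerate(wins):
        out[m] = doses[(axis >= lo) & (axis < hi)].sum()
    total = doses.sum()
    if abs(out.sum() - total) > 1e-9 * max(total, 1.0):
        raise ValueError("windows do not partition the exposure axis")
    return out


def truncate_at_percentile(cohort_z_end: pd.Series, p: float) -> pd.Index:
    """Persons whose end-of-follow-up cumulative dose is <= the p-th percentile.

    Ties at the threshold are retained, which makes the operation idempotent.
    """
    if not 0 < p <= 100:
        raise ValueError("p must be in (0, 100]")
    if p == 100:
        return cohort_z_end.index
    thr = float(np.percentile(cohort_z_end.to_numpy(float), p))
    return cohort_z_end.index[cohort_z_end.to_numpy(float) <= thr]


# ---------------------------------------------------------------------------
# Bulk construction

def build_dose_histories(exams: pd.DataFrame, dose_summary: pd.DataFrame | None,
                         metric: str = "abm_dose_mean") -> dict[str, DoseHistory]:
    """Dict person_id -> DoseHistory for the chosen exposure metric."""
    if metric == "exam_count":
        dose = np.ones(len(exams))
    else:
        if dose_summary is None or metric not in dose_summary.columns:
            raise ValueError(f"dose summary with column {metric!r} required")
        dose = (exams[["exam_id"]]
                .merge(dose_summary[["exam_id", metric]], on="exam_id",
                       how="left")[metric].to_numpy(float))
        if np.isnan(dose).any():
            raise ValueError("exam without summarized dose")
    out: dict[str, DoseHistory] = {}
    pid = exams["person_id"].to_numpy()
    age = exams["age_at_exam"].to_numpy(float)
    order = np.lexsort((age, pid))
    pid, age, dose = pid[order], age[order], dose[order]
    bounds = np.flatnonzero(np.r_[True, pid[1:] != pid[:-1], True])
    for i, j in zip(bounds[:-1], bounds[1:]):
        out[pid[i]] = DoseHistory(pid[i], age[i:j], dose[i:j], metric)
    return out
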