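"""Postnatal time-course analysis: miRNA-target correlation and change-point location.

Time courses are expression trajectories over an ordered set of postnatal
timepoints (P10, P15, P20, P23, P31, adult by default) with replicate
animals per timepoint.  Correlations between a miRNA and a candidate target
use the Pearson test (two-sided p from the t distribution with n-2 df),
either on per-timepoint means (default: group-level trajectories) or on
matched replicates.  A Spearman alternative is exposed for rank-based use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_TIMEPOINTS = ("P10", "P15", "P20", "P23", "P31", "adult")


class InsufficientDataError(ValueError):
    pass


class UndefinedCorrelationError(ValueError):
    pass


@dataclass
class TimeCourse:
    """One feature's replicate measurements over ordered timepoints."""

    feature_id: str
    timepoints: tuple[str, ...]
    values: dict[str, np.ndarray]  # timepoint -> replicate values

    def __post_init__(self) -> None:
        if len(self.timepoints) < 3:
            raise ValueError("a time course needs >= 3 timepoints")
        for tp in self.timepoints:
            v = np.asarray(self.values.get(tp, []), dtype=float)
            if v.size < 1:
                raise ValueError(f"timepoint {tp!r} has no replicates")
            self.values[tp] = v

    def means(self) -> np.ndarray:
        return np.array([self.values[tp].mean() for tp in self.timepoints])


def timecourses_to_frame(tcs: Sequence[TimeCourse]) -> pd.DataFrame:
    """Long-format TSV schema: feature_id, timepoint, replicate, value."""
    rows = []
    for tc in tcs:
        for tp in tc.timepoints:
            for i, v in enumerate(tc.values[tp], start=1):
                rows.append((tc.feature_id, tp, i, v))
    return pd.DataFrame(rows, columns=["feature_id", "timepoint", "replicate", "value"])


def frame_to_timecourses(
    frame: pd.DataFrame, timepoints: Optional[Sequence[str]] = None
) -> list[TimeCourse]:
    if timepoints is None:
        timepoints = list(dict.fromkeys(frame["timepoint"]))
    out = []
    for fid, sub in frame.groupby("feature_id", sort=False):
        vals = {
            tp: sub.loc[sub["timepoint"] == tp, "value"].to_numpy(dtype=float)
            for tp in timepoints
        }
        out.append(TimeCourse(fid, tuple(timepoints), vals))
    return out


@dataclass
class CorrelationResult:
    mirna_id: str
    mrna_id: str
    r: float
    pvalue: float
    n: int


def correlate_pairs(
    mirna_tc: TimeCourse,
    mrna_tc: TimeCourse,
    pairing: str = "per-timepoint-mean",
    method: str = "pearson",
) -> CorrelationResult:
    """Correlate a miRNA trajectory with a candidate-target trajectory.

    ``pairing='per-timepoint-mean'`` correlates the per-timepoint group
    means (the group-level trajectory comparison); ``pairing='per-animal'``
    pairs replicates positionally within each shared timepoint and requires
    equal replicate counts.  ``method`` is ``pearson`` (default) or
    ``spearman``.
    """
    shared = [tp for tp in mirna_tc.timepoints if tp in mrna_tc.timepoints]
    if pairing == "per-timepoint-mean":
        x = np.array([mirna_tc.values[tp].mean() for tp in shared])
        y = np.array([mrna_tc.values[tp].mean() for tp in shared])
    elif pairing == "per-animal":
        xs, ys = [], []
        for tp in shared:
            a, b = mirna_tc.values[tp], mrna_tc.values[tp]
            if len(a) != len(b):
                raise InsufficientDataError(
                    f"per-animal pairing needs matched replicates at {tp!r}"
                )
            xs.append(a)
            ys.append(b)
        x, y = np.concatenate(xs), np.concatenate(ys)
    else:
        raise ValueError(f"unknown pairing {pairing!r}")
    n = len(x)
    if n < 3:
        raise InsufficientDataError(f"need >= 3 paired observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in one of the series")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(
        mirna_id=mirna_tc.feature_id,
        mrna_id=mrna_tc.feature_id,
        r=float(res.statistic if hasattr(res, "statistic") else res[0]),
        pvalue=float(res.pvalue if hasattr(res, "pvalue") else res[1]),
        n=n,
    )


def earliest_change_timepoint(
    tc: TimeCourse,
    reference_timepoint: str = "P10",
    alpha: float = 0.05,
) -> Optional[str]:
    """Earliest timepoint significantly different from the reference.

    Each non-reference timepoint is compared to the reference with a Welch
    two-sample t-test; the alpha level is Bonferroni-divided by the number
    of comparisons actually performed (a pragmatic stand-in for a Dunnett
    many-to-one procedure).  Timepoints with fewer than two replicates are
    excluded from testing.  Returns the earliest significant label, or
    ``None`` if no timepoint passes.
    """
    if reference_timepoint not in tc.timepoints:
        raise ValueError(f"reference {reference_timepoint!r} not in time course")
    ref = tc.values[reference_timepoint]
    if len(ref) < 2:
        raise InsufficientDataError("reference timepoint needs >= 2 replicates")
    candidates = [
        tp for tp in tc.timepoints
        if tp != reference_timepoint and len(tc.values[tp]) >= 2
    ]
    if not candidates:
        return None
    threshold = alpha / len(candidates)
    for tp in candidates:
        p = stats.ttest_ind(tc.values[tp], ref, equal_var=False).pvalue
        if np.isfinite(p) and p <= threshold:
            return tp
    return None
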