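"""Reduce raw learning/relearning times to savings and aggregate statistics.

A relearning experiment yields, per list, the time S1 spent learning it to
criterion and the time S2 spent relearning it after the retention interval.
Savings is Q = (S1 - S2)/S1: 1 means perfect retention, 0 none, and negative
values occur when relearning takes longer than learning.

Besides per-interval aggregation this module implements the corrections used
with such data: a linear drift of learning time across the experimental
calendar (proactive interference / fatigue), a time-of-day normalization of
learning times, first-point normalization of savings curves, and a one-way
ANOVA computed from per-group summary statistics (n, mean, SD) as printed in
repetition-count tables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .fitting import SavingsCurve
from .models import DAY_SECONDS

logger = logging.getLogger("forgetfit.reduction")

__all__ = [
    "LearningRecord",
    "RepetitionSummary",
    "DriftFit",
    "AnovaResult",
    "savings",
    "aggregate_savings",
    "drift_fit",
    "drift_corrected_savings",
    "timeofday_correction",
    "normalize_curve",
    "anova_from_summary",
    "TIME_OF_DAY_FACTORS",
]

#: Multiplicative factors normalizing learning times to the morning session A:
#: 5% is subtracted for midday (B) and 13% for evening (C) sessions.
TIME_OF_DAY_FACTORS = {"A": 1.0, "B": 0.95, "C": 0.87}


@dataclass(frozen=True)
class LearningRecord:
    """One list's learning/relearning times (seconds) and metadata."""

    list_id: str
    interval_seconds: float
    s1: float
    s2: float
    day: float | None = None
    session: str | None = None
    reps_learning: float | None = None
    reps_relearning: float | None = None

    def __post_init__(self) -> None:
        if not self.s1 > 0:
            raise ValueError(f"S1 must be > 0, got {self.s1} (list {self.list_id})")
        if self.s2 < 0:
            raise ValueError(f"S2 must be >= 0, got {self.s2} (list {self.list_id})")
        if not self.interval_seconds > 0:
            raise ValueError("interval_seconds must be > 0")

    @property
    def q(self) -> float:
        return savings(self.s1, self.s2)


@dataclass(frozen=True)
class RepetitionSummary:
    """Per-interval repetition-count summary: n, mean, SD for (re)learning."""

    interval_seconds: float
    n_learning: int
    mean_learning: float
    sd_learning: float
    n_relearning: int
    mean_relearning: float
    sd_relearning: float


def savings(s1, s2):
    """Savings Q = (S1 - S2)/S1. Scale-invariant; negative values are legal."""
    s1a = np.asarray(s1, dtype=float)
    s2a = np.asarray(s2, dtype=float)
    if np.any(s1a <= 0):
        raise ValueError("S1 must be > 0")
    q = (s1a - s2a) / s1a
    return q if q.shape else float(q)


def aggregate_savings(
    records: Iterable[LearningRecord], subject: str = "aggregate", method: str = "pooled"
) -> SavingsCurve:
    """Per-interval average savings, as a SavingsCurve.

    Two aggregation conventions exist in the savings literature and they do
    not agree beyond two decimals on real data:

    ``"pooled"`` (default)
        Savings of the per-interval average times,
        (mean S1 - mean S2)/mean S1.  This is the convention behind the
        published per-interval average rows (which print the average S1, S2
        and Q of each interval consistently).
    ``"per_list"``
        Unweighted mean of the per-list Q values.

    Per-interval SD of the per-list Q values and list counts are attached to
    the curve under either convention.
    """
    if method not in ("pooled", "per_list"):
        raise ValueError("method must be 'pooled' or 'per_list'")
    records = list(records)
    if not records:
        raise ValueError("no records to aggregate")
    groups: dict[float, list[LearningRecord]] = {}
    for r in records:
        groups.setdefault(r.interval_seconds, []).append(r)
    t_sorted = sorted(groups)
    means, sds, ns = [], [], []
    for t in t_sorted:
        recs = groups[t]
        if not recs:  # defensive; empty groups cannot arise from records
            warnings.warn(f"interval {t} s has no records; excluded", RuntimeWarning)
            continue
        qs = np.asarray([r.q for r in recs])
        if method == "pooled":
            s1 = np.mean([r.s1 for r in recs])
            s2 = np.mean([r.s2 for r in recs])
            means.append(savings(s1, s2))
        else:
            means.append(float(qs.mean()))
        sds.append(float(qs.std(ddof=1)) if qs.size > 1 else 0.0)
        ns.append(int(qs.size))
    return SavingsCurve(
        subject=subject,
        t_seconds=tuple(t_sorted),
        savings=tuple(means),
        sd=tuple(sds),
        n_lists=tuple(ns),
    )


@dataclass(frozen=True)
class DriftFit:
    """OLS of learning time on calendar day: S1 = intercept + slope * day."""

    slope: float  # seconds of learning time per day
    intercept: float
    r_squared: float
    n: int


def drift_fit(records: Iterable[LearningRecord]) -> DriftFit:
    """Ordinary least squares of per-list learning time S1 on calendar day."""
    recs = [r for r in records if r.day is not None]
    if len(recs) < 3:
        raise ValueError("drift_fit needs at least 3 records with a calendar day")
    days = np.asarray([r.day for r in recs], dtype=float)
    s1 = np.asarray([r.s1 for r in recs], dtype=float)
    if np.all(days == days[0]):
        raise ValueError("drift_fit requires at least two distinct days")
    res = stats.linregress(days, s1)
    return DriftFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=len(recs),
    )


def drift_corrected_savings(record: LearningRecord, slope: float) -> float:
    """Savings recomputed against the learning time expected at relearning day.

    The original learning time is projected forward over the retention
    interval, S1* = S1 + slope * (interval in days), and savings is taken
    relative to S1*: Q' = (S1* - S2)/S1*.  This asks "how much time was saved
    relative to what learning would have cost on the relearning day", removing
    the drift's deflation of long-interval savings.  One of several plausible
    corrections; see the methods note.
    """
    if slope < 0:
        raise ValueError("slope must be >= 0")
    s1_star = record.s1 + slope * (record.interval_seconds / DAY_SECONDS)
    if s1_star <= 0:
        raise ValueError("corrected learning time must be positive")
    return float((s1_star - record.s2) / s1_star)


def timeofday_correction(s: float, session: str) -> float:
    """Normalize a learning time to the morning session (A -> 1, B -> 0.95, C -> 0.87)."""
    try:
        factor = TIME_OF_DAY_FACTORS[session]
    except KeyError:
        raise ValueError(
            f"unknown session {session!r}; expected one of {sorted(TIME_OF_DAY_FACTORS)}"
        ) from None
    return s * factor


def normalize_curve(curve: SavingsCurve) -> SavingsCurve:
    """Rescale a savings curve so its first point equals 1.0."""
    first = curve.savings[0]
    if first == 0:
        raise ValueError("cannot normalize: first savings value is zero")
    return SavingsCurve(
        subject=curve.subject,
        t_seconds=curve.t_seconds,
        savings=tuple(q / first for q in curve.savings),
        sd=tuple(s / abs(first) for s in curve.sd) if curve.sd else None,
        n_lists=curve.n_lists,
    )


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


def anova_from_summary(groups: Sequence[tuple[int, float, float]]) -> AnovaResult:
    """One-way independent ANOVA from per-group (n, mean, SD) summaries.

    SS_between = sum n_i (m_i - grand mean)^2 with the grand mean weighted by
    n_i; SS_within = sum (n_i - 1) s_i^2; df = (g - 1, N - g).  Zero
    within-group variance yields an infinite-F sentinel with p = 0.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    n = np.asarray([g[0] for g in groups], dtype=float)
    m = np.asarray([g[1] for g in groups], dtype=float)
    s = np.asarray([g[2] for g in groups], dtype=float)
    if np.any(n < 2):
        raise ValueError("each group needs n >= 2")
    if np.any(s < 0):
        raise ValueError("SDs must be non-negative")
    N = float(n.sum())
    g = len(groups)
    grand = float(np.sum(n * m) / N)
    ss_between = float(np.sum(n * (m - grand) ** 2))
    ss_within = float(np.sum((n - 1) * s**2))
    df_b, df_w = g - 1, int(N) - g
    ms_between = ss_between / df_b
    if ss_within == 0:
        warnings.warn("zero within-group variance; F is infinite", RuntimeWarning)
        return AnovaResult(float("inf"), df_b, df_w, 0.0 if ss_between > 0 else 1.0)
    ms_within = ss_within / df_w
    F = ms_between / ms_within
    p = float(stats.f.sf(F, df_b, df_w))
    return AnovaResult(float(F), df_b, df_w, p)
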