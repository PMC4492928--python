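"""Serial-position analysis of relearning recall.

Each relearned row of 13 nonsense syllables yields, per position, a binary
correct/incorrect score at the first relearning attempt (scored leniently:
a correct syllable counts for its intended position even if produced
elsewhere — that scoring happens upstream, before records reach this module).
Aggregating over rows gives proportion-correct curves per serial position and
retention interval; regressing the mean proportion of position groups on the
retention interval (in days, untransformed scores) quantifies how much each
part of the list is forgotten over time.  The canonical grouping separates
primacy (1-2), middle (3-8, 9-10) and recency (11-13) positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import DAY_SECONDS

logger = logging.getLogger("forgetfit.serialpos")

__all__ = [
    "RecallRecord",
    "SerialPositionTable",
    "DEFAULT_POSITION_GROUPS",
    "position_curves",
    "group_slopes",
]

N_POSITIONS = 13

#: The canonical partition of the 13 serial positions, plus "all".
DEFAULT_POSITION_GROUPS: dict[str, tuple[int, ...]] = {
    "1-2": (1, 2),
    "3-8": (3, 4, 5, 6, 7, 8),
    "9-10": (9, 10),
    "11-13": (11, 12, 13),
}


@dataclass(frozen=True)
class RecallRecord:
    """One syllable-position observation at first relearning."""

    interval_seconds: float
    row_id: str
    position: int
    correct: bool

    def __post_init__(self) -> None:
        if not 1 <= self.position <= N_POSITIONS:
            raise ValueError(f"position must be in 1..{N_POSITIONS}, got {self.position}")


@dataclass(frozen=True)
class SerialPositionTable:
    """Per-(interval, position) trial counts, correct counts and proportions."""

    n_trials: pd.DataFrame  # index: interval_seconds; columns: positions 1..13
    n_correct: pd.DataFrame

    @property
    def proportion(self) -> pd.DataFrame:
        """Proportion correct; NaN where a cell has no trials."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.n_correct / self.n_trials.where(self.n_trials > 0)

    @property
    def intervals(self) -> np.ndarray:
        return self.n_trials.index.to_numpy(dtype=float)

    def to_long(self) -> pd.DataFrame:
        """Long-format table: interval_seconds, position, n_trials, n_correct, proportion."""
        prop = self.proportion
        rows = []
        for t in self.n_trials.index:
            for pos in self.n_trials.columns:
                rows.append(
                    {
                        "interval_seconds": float(t),
                        "position": int(pos),
                        "n_trials": int(self.n_trials.loc[t, pos]),
                        "n_correct": int(self.n_correct.loc[t, pos]),
                        "proportion": float(prop.loc[t, pos]),
                    }
                )
        return pd.DataFrame(rows)


def position_curves(records: Iterable[RecallRecord] | pd.DataFrame) -> SerialPositionTable:
    """Tabulate proportion correct per serial position and retention interval.

    Accepts RecallRecord iterables or a DataFrame with columns
    ``interval_seconds, row_id, position, correct``.  Cells without trials are
    reported as missing (NaN proportion), not as zero.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        required = {"interval_seconds", "position", "correct"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"recall table is missing columns: {sorted(missing)}")
    else:
        df = pd.DataFrame(
            {
                "interval_seconds": [r.interval_seconds for r in records],
                "position": [r.position for r in records],
                "correct": [int(r.correct) for r in records],
            }
        )
    if df.empty:
        raise ValueError("no recall records")
    bad = df[(df["position"] < 1) | (df["position"] > N_POSITIONS)]
    if not bad.empty:
        raise ValueError(f"positions outside 1..{N_POSITIONS}: {sorted(bad['position'].unique())}")
    intervals = sorted(df["interval_seconds"].unique())
    cols = list(range(1, N_POSITIONS + 1))
    trials = pd.DataFrame(0, index=intervals, columns=cols)
    correct = pd.DataFrame(0, index=intervals, columns=cols)
    grouped = df.groupby(["interval_seconds", "position"])["correct"]
    for (t, pos), series in grouped:
        trials.loc[t, pos] = len(series)
        correct.loc[t, pos] = int(series.astype(int).sum())
    return SerialPositionTable(n_trials=trials, n_correct=correct)


def group_slopes(
    table: SerialPositionTable,
    groups: Mapping[str, Sequence[int]] | None = None,
) -> dict[str, float]:
    """OLS slope of group-mean proportion correct versus retention time in days.

    For each position group the proportions are averaged across the group's
    positions per interval, then regressed on the interval expressed in days
    (untransformed scores).  An ``"all"`` entry for the mean over all 13
    positions is always included.  Cells with no trials are excluded pairwise.
    """
    if groups is None:
        groups = DEFAULT_POSITION_GROUPS
    prop = table.proportion
    if len(prop.index) < 2:
        raise ValueError("group_slopes needs at least two retention intervals")
    days = prop.index.to_numpy(dtype=float) / DAY_SECONDS
    out: dict[str, float] = {}
    all_groups = dict(groups)
    all_groups["all"] = tuple(range(1, N_POSITIONS + 1))
    for name, positions in all_groups.items():
        y = prop[list(positions)].mean(axis=1, skipna=True).to_numpy()
        mask = np.isfinite(y)
        if mask.sum() < 2:
            out[name] = float("nan")
            continue
        res = stats.linregress(days[mask], y[mask])
        out[name] = float(res.slope)
    return out
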