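"""CSV readers and writers for the package's three record schemas.

Savings curves:     ``subject,t_seconds,savings`` (one row per point)
Learning records:   ``list_id,interval_seconds,S1_seconds,S2_seconds[,day][,session]``
Recall records:     ``interval_seconds,row_id,position,correct`` (correct is 0/1)

All files are UTF-8 with '.' decimal separators and a header row.  Malformed
input raises :class:`MalformedCSVError` carrying the offending line number.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import pandas as pd

from .fitting import SavingsCurve
from .reduction import LearningRecord

logger = logging.getLogger("forgetfit.io")

__all__ = [
    "MalformedCSVError",
    "read_savings_csv",
    "write_savings_csv",
    "read_learning_csv",
    "write_learning_csv",
    "read_recall_csv",
    "write_recall_csv",
]


class MalformedCSVError(ValueError):
    """A CSV file that does not match the expected schema."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"{message}" + (f" (line {line})" if line is not None else ""))


def _read(path, required: set[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise MalformedCSVError(f"cannot parse {path}: {exc}") from exc
    missing = required - set(df.columns)
    if missing:
        raise MalformedCSVError(f"{path}: missing columns {sorted(missing)}", line=1)
    return df

def _numeric(df: pd.DataFrame, path, col: str) -> pd.Series:
    coerced = pd.to_numeric(df[col], errors="coerce")
    bad = coerced.isna() & df[col].notna()
    if bad.any():
        # +2: header line plus 1-based indexing
        raise MalformedCSVError(
            f"{path}: non-numeric value {df[col][bad].iloc[0]!r} in column {col!r}",
            line=int(bad.idxmax()) + 2,
        )
    if coerced.isna().any():
        raise MalformedCSVError(
            f"{path}: empty value in column {col!r}", line=int(coerced.isna().idxmax()) + 2
        )
    return coerced


def read_savings_csv(path) -> list[SavingsCurve]:
    """Read savings curves, one per distinct subject, sorted by interval."""
    df = _read(path, {"subject", "t_seconds", "savings"})
    for col in ("t_seconds", "savings"):
        df[col] = _numeric(df, path, col)
    curves = []
    for subject, g in df.groupby("subject", sort=False):
        g = g.sort_values("t_seconds")
        try:
            curves.append(
                SavingsCurve(
                    subject=str(subject),
                    t_seconds=tuple(g["t_seconds"]),
                    savings=tuple(g["savings"]),
                )
            )
        except ValueError as exc:
            raise MalformedCSVError(f"{path}: invalid curve for {subject!r}: {exc}") from exc
    return curves


def write_savings_csv(path, curves: Iterable[SavingsCurve]) -> None:
    rows = [
        {"subject": c.subject, "t_seconds": t, "savings": q}
        for c in curves
        for t, q in zip(c.t_seconds, c.savings)
    ]
    pd.DataFrame(rows, columns=["subject", "t_seconds", "savings"]).to_csv(path, index=False)


def read_learning_csv(path) -> list[LearningRecord]:
    df = _read(path, {"list_id", "interval_seconds", "S1_seconds", "S2_seconds"})
    for col in ("interval_seconds", "S1_seconds", "S2_seconds"):
        df[col] = _numeric(df, path, col)
    if "day" in df.columns:
        df["day"] = pd.to_numeric(df["day"], errors="coerce")
    records = []
    for idx, row in df.iterrows():
        day = None
        if "day" in df.columns and pd.notna(row["day"]):
            day = float(row["day"])
        session = None
        if "session" in df.columns and pd.notna(row.get("session")):
            session = str(row["session"])
        try:
            records.append(
                LearningRecord(
                    list_id=str(row["list_id"]),
                    interval_seconds=float(row["interval_seconds"]),
                    s1=float(row["S1_seconds"]),
                    s2=float(row["S2_seconds"]),
                    day=day,
                    session=session,
                )
            )
        except ValueError as exc:
            raise MalformedCSVError(f"{path}: {exc}", line=int(idx) + 2) from exc
    return records


def write_learning_csv(path, records: Iterable[LearningRecord]) -> None:
    records = list(records)
    rows = []
    has_day = any(r.day is not None for r in records)
    has_session = any(r.session is not None for r in records)
    for r in records:
        row = {
            "list_id": r.list_id,
            "interval_seconds": r.interval_seconds,
            "S1_seconds": r.s1,
            "S2_seconds": r.s2,
        }
        if has_day:
            row["day"] = r.day
        if has_session:
            row["session"] = r.session
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_recall_csv(path) -> pd.DataFrame:
    df = _read(path, {"interval_seconds", "row_id", "position", "correct"})
    for col in ("interval_seconds", "position", "correct"):
        df[col] = _numeric(df, path, col)
    if not df["correct"].isin((0, 1)).all():
        bad = ~df["correct"].isin((0, 1))
        raise MalformedCSVError(
            f"{path}: 'correct' must be 0 or 1", line=int(bad.idxmax()) + 2
        )
    df["position"] = df["position"].astype(int)
    df["correct"] = df["correct"].astype(int)
    return df


def write_recall_csv(path, records: pd.DataFrame) -> None:
    cols = ["interval_seconds", "row_id", "position", "correct"]
    records[cols].to_csv(path, index=False)
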