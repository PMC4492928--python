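"""Bundled reference data: the printed tables of the savings experiments.

Three fixtures are available through :func:`load_fixture`:

``table1``
    Per-interval repetition-count summaries (n, mean, SD) for learning and
    relearning, 7 retention intervals.
``table2``
    The replication subject's raw per-list learning/relearning times in
    seconds with savings, 69 lists (only 9 for the 9-hour interval).
``table3``
    The four canonical savings curves — Ebbinghaus (1880), the two subjects
    of the German replication (Mack, Seitz), and the present replication
    subject (Dros) — at 7 retention intervals each.

Interval conventions: Ebbinghaus' own short intervals are stated as 19 min,
63 min and 8.75 h, while the replications used 20 min, 1 h and 9 h.  The
published model fits to all four curves are, however, reproduced exactly on
the uniform replication grid (see the methods note), so ``table3`` defaults
to that grid and exposes the stated per-subject convention via
``intervals="stated"``.
"""

from __future__ import annotations

from types import MappingProxyType

from .fitting import SavingsCurve
from .models import EBBINGHAUS_INTERVALS_S, REPLICATION_INTERVALS_S
from .reduction import LearningRecord, RepetitionSummary

__all__ = ["load_fixture", "load_table1", "load_table2", "load_table3", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("table1", "table2", "table3")

_INTERVAL_LABELS = ("20min", "1hour", "9hours", "1day", "2days", "6days", "31days")

# interval label -> (n, learning mean, SD, n, relearning mean, SD)
_TABLE1 = {
    "20min": (10, 30.77, 2.90, 10, 16.26, 2.27),
    "1hour": (10, 30.64, 2.28, 10, 19.22, 1.56),
    "9hours": (9, 31.07, 2.08, 9, 22.48, 2.67),
    "1day": (10, 31.22, 2.34, 10, 21.33, 2.11),
    "2days": (10, 31.42, 2.49, 10, 24.19, 2.30),
    "6days": (10, 31.21, 3.19, 10, 25.97, 3.37),
    "31days": (10, 29.44, 2.26, 10, 28.23, 3.48),
}

# interval label -> [(S1, S2) per list]; times in seconds
_TABLE2 = {
    "20min": [(1405, 670), (1840, 1210), (1830, 1100), (2180, 960), (1800, 840),
              (1815, 1345), (2040, 1110), (1725, 865), (1935, 1320), (1830, 1235)],
    "1hour": [(1690, 1280), (1790, 1330), (2070, 1235), (1875, 1130), (1775, 1245),
              (1765, 1170), (1680, 1125), (1905, 1250), (1805, 1155), (2065, 1325)],
    "9hours": [(1815, 1240), (1780, 1350), (1935, 1350), (1525, 975), (1770, 1275),
               (1815, 1335), (1635, 1220), (1845, 1380), (1950, 1585)],
    "1day": [(1670, 1105), (1840, 1325), (1930, 1205), (1740, 1365), (1875, 1410),
             (1710, 1215), (1905, 1325), (2095, 1235), (1860, 1290), (1980, 1275)],
    "2days": [(1710, 1195), (1635, 1340), (1950, 1580), (1935, 1440), (1830, 1500),
              (2130, 1485), (1890, 1440), (2085, 1460), (1740, 1335), (1695, 1375)],
    "6days": [(1780, 1370), (1605, 1560), (1870, 1545), (2020, 1805), (2090, 1785),
              (1740, 1585), (1710, 1350), (2025, 1665), (2100, 1415), (1890, 1275)],
    "31days": [(1480, 1380), (1680, 1450), (1770, 1530), (1440, 1510), (1650, 1760),
               (1890, 1785), (1815, 1745), (1910, 1505), (1490, 1260), (1710, 1395)],
}

# Note: the printed per-interval Average savings row is (0.421, 0.335, 0.271,
# 0.315, 0.239, "0", 0.090); the 6-day cell is a typographical error in the
# source table — recomputing from the per-list values above gives 0.181.

# subject -> savings at the 7 intervals, short to long
_TABLE3 = {
    "Ebbinghaus": (0.582, 0.442, 0.358, 0.337, 0.278, 0.254, 0.211),
    "Mack": (0.544, 0.432, 0.285, 0.316, 0.365, 0.309, 0.258),
    "Seitz": (0.442, 0.325, 0.270, 0.270, 0.286, 0.205, 0.201),
    "Dros": (0.472, 0.373, 0.276, 0.317, 0.230, 0.168, 0.041),
}

TABLE3_SUBJECTS = tuple(_TABLE3)


def load_table1() -> tuple[RepetitionSummary, ...]:
    """Repetition-count summaries per retention interval."""
    return tuple(
        RepetitionSummary(t, *_TABLE1[label])
        for t, label in zip(REPLICATION_INTERVALS_S, _INTERVAL_LABELS)
    )


def load_table2() -> tuple[LearningRecord, ...]:
    """Raw per-list learning/relearning times (69 lists)."""
    records = []
    for t, label in zip(REPLICATION_INTERVALS_S, _INTERVAL_LABELS):
        for i, (s1, s2) in enumerate(_TABLE2[label]):
            records.append(
                LearningRecord(list_id=f"{label}-{i + 1}", interval_seconds=t, s1=s1, s2=s2)
            )
    return tuple(records)


def load_table3(intervals: str = "fitted") -> MappingProxyType:
    """The four canonical savings curves, as subject -> SavingsCurve.

    ``intervals="fitted"`` (default) places every curve on the uniform
    replication grid (20 min, 1 h, 9 h, 1/2/6/31 d) — the grid on which the
    published model fits are reproduced.  ``intervals="stated"`` uses the
    per-subject convention instead: Ebbinghaus at 19 min, 63 min, 8.75 h.
    """
    if intervals not in ("fitted", "stated"):
        raise ValueError("intervals must be 'fitted' or 'stated'")
    out = {}
    for subject, q in _TABLE3.items():
        if intervals == "stated" and subject == "Ebbinghaus":
            grid = EBBINGHAUS_INTERVALS_S
        else:
            grid = REPLICATION_INTERVALS_S
        out[subject] = SavingsCurve(subject=subject, t_seconds=grid, savings=q)
    return MappingProxyType(out)


def load_fixture(name: str, **kwargs):
    """Load a bundled fixture by name ('table1', 'table2' or 'table3')."""
    loaders = {"table1": load_table1, "table2": load_table2, "table3": load_table3}
    try:
        loader = loaders[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}") from None
    return loader(**kwargs)
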