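"""Synthetic savings-experiment generator.

Emulates the design of a single-subject relearning study: per retention
interval a number of 13-syllable lists is learned (time S1) and relearned
(time S2) after the interval, with savings declining under a chosen true
retention law.  Defaults mirror the replication study's conditions: 7
intervals from 20 minutes to 31 days, 10 lists per interval, learning times
around 1840 s (SD 150 s), a 75-day experimental calendar, and additive
Gaussian observation noise on savings.  An optional linear drift in learning
time across calendar days reproduces the proactive-interference/fatigue
confound, and ``massed_longest`` places all longest-interval lists at the
start of the calendar as in the original design.

A second generator produces per-position recall records with flat primacy
(positions 1-2) and recency (11-13) groups and linearly time-decaying middle
positions, for exercising the serial-position analysis.

All randomness flows from the config seed; identical configs give identical
output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence
import warnings

import numpy as np
import pandas as pd

from .models import DAY_SECONDS, MODELS, REPLICATION_INTERVALS_S
from .reduction import LearningRecord
from .serialpos import DEFAULT_POSITION_GROUPS, N_POSITIONS

logger = logging.getLogger("forgetfit.simulate")

__all__ = ["SimulationConfig", "SerialProfileConfig", "simulate_experiment", "simulate_serial"]

MIN_S1 = 300.0  # truncation floor for learning time, seconds
MIN_S2 = 60.0  # truncation floor for relearning time, seconds


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of a synthetic savings experiment.

    ``true_model``/``true_params`` define the underlying retention law
    Q_true(t).  Observed savings are Q_true(t) + N(0, noise_sd); S1 is drawn
    from N(s1_mean + drift_slope * day, s1_sd) truncated at 300 s and S2 is
    derived as S1 * (1 - Q_obs) truncated at 60 s.  Calendar days are
    assigned uniformly over ``experiment_days`` unless ``massed_longest``
    confines the longest interval's lists to the first ten days.
    """

    true_model: str = "mcm"
    true_params: tuple[float, ...] = (0.563, 0.000353, 0.000188, 1.00e-6)
    intervals: tuple[float, ...] = REPLICATION_INTERVALS_S
    lists_per_interval: int = 10
    s1_mean: float = 1840.0
    s1_sd: float = 150.0
    noise_sd: float = 0.03
    drift_slope: float = 0.0  # seconds of learning time per calendar day
    experiment_days: int = 75
    massed_longest: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_model not in MODELS:
            raise ValueError(f"unknown model {self.true_model!r}")
        if self.lists_per_interval < 1:
            raise ValueError("lists_per_interval must be >= 1")
        if min(self.s1_sd, self.noise_sd) < 0:
            raise ValueError("standard deviations must be >= 0")


def simulate_experiment(config: SimulationConfig) -> list[LearningRecord]:
    """Generate per-list learning records under a known retention law."""
    rng = np.random.default_rng(config.seed)
    spec = MODELS[config.true_model]
    records: list[LearningRecord] = []
    longest = max(config.intervals)
    for t in config.intervals:
        if t / DAY_SECONDS > config.experiment_days:
            warnings.warn(
                f"interval {t / DAY_SECONDS:.1f} d exceeds the {config.experiment_days}-day "
                "experiment; generated anyway (relearning falls outside the calendar)",
                RuntimeWarning,
                stacklevel=2,
            )
        q_true = float(spec.evaluate(t, config.true_params))
        for i in range(config.lists_per_interval):
            if config.massed_longest and t == longest:
                day = float(rng.integers(0, min(10, config.experiment_days)))
            else:
                day = float(rng.integers(0, config.experiment_days))
            s1 = max(MIN_S1, rng.normal(config.s1_mean + config.drift_slope * day, config.s1_sd))
            q_obs = q_true + rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else q_true
            s2 = max(MIN_S2, s1 * (1.0 - q_obs))
            records.append(
                LearningRecord(
                    list_id=f"{int(t)}s-{i + 1}",
                    interval_seconds=float(t),
                    s1=float(s1),
                    s2=float(s2),
                    day=day,
                )
            )
    return records


@dataclass(frozen=True)
class SerialProfileConfig:
    """Per-position-group recall profile for the serial-position generator.

    ``baselines`` give the proportion correct at t = 0 per group and
    ``decays`` the linear decline per day; the per-cell success probability is
    clamp(baseline - decay * t_days, 0, 1) and correct counts are Binomial.
    Defaults: easy, stable primacy/recency edges (no decay) and harder,
    decaying middle positions.
    """

    baselines: dict[str, float] = field(
        default_factory=lambda: {"1-2": 0.9, "3-8": 0.5, "9-10": 0.6, "11-13": 0.9}
    )
    decays: dict[str, float] = field(
        default_factory=lambda: {"1-2": 0.0, "3-8": 0.01, "9-10": 0.01, "11-13": 0.0}
    )
    trials_per_cell: int = 80
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.baselines) != set(self.decays):
            raise ValueError("baselines and decays must cover the same groups")
        if any(not 0 <= b <= 1 for b in self.baselines.values()):
            raise ValueError("baselines must be in [0, 1]")
        if any(d < 0 for d in self.decays.values()):
            raise ValueError("decays must be >= 0")
        if self.trials_per_cell < 1:
            raise ValueError("trials_per_cell must be >= 1")

    def groups(self) -> dict[str, tuple[int, ...]]:
        return {g: DEFAULT_POSITION_GROUPS[g] for g in self.baselines}


def simulate_serial(
    config: SerialProfileConfig, intervals: Sequence[float] = REPLICATION_INTERVALS_S
) -> pd.DataFrame:
    """Generate per-trial recall records (long format) under a known profile.

    Returns a DataFrame with columns ``interval_seconds, row_id, position,
    correct`` suitable for :func:`forgetfit.serialpos.position_curves`.
    """
    rng = np.random.default_rng(config.seed)
    pos_to_group: dict[int, str] = {}
    for g, positions in config.groups().items():
        for p in positions:
            pos_to_group[p] = g
    if set(pos_to_group) != set(range(1, N_POSITIONS + 1)):
        raise ValueError("profile groups must cover positions 1..13")
    rows = []
    for t in intervals:
        t_days = t / DAY_SECONDS
        for pos in range(1, N_POSITIONS + 1):
            g = pos_to_group[pos]
            p = float(np.clip(config.baselines[g] - config.decays[g] * t_days, 0.0, 1.0))
            correct = rng.binomial(1, p, size=config.trials_per_cell)
            for i, c in enumerate(correct):
                rows.append(
                    {
                        "interval_seconds": float(t),
                        "row_id": f"{int(t)}s-r{i + 1}",
                        "position": pos,
                        "correct": int(c),
                    }
                )
    return pd.DataFrame(rows)
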