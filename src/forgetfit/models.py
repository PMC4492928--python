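"""Closed-form retention (forgetting) models for savings data.

Savings Q(t) is the relative amount of relearning effort saved after a
retention interval t: Q = (S1 - S2)/S1 with S1 the original learning time and
S2 the relearning time.  This module evaluates the candidate retention laws
used to describe how Q declines with t:

``eb1880``
    Ebbinghaus' 1880 double-power law, Q(t) = 1 - [1 - (2/t)^a1]^mu1, t in
    minutes.  Undefined for t <= 2 min.
``eb1885``
    Ebbinghaus' 1885 logarithmic law, Q(t) = mu1 / ((log10 t)^a1 + mu1), t in
    minutes.  Q(1) = 1 by construction.
``power``
    A two-parameter power law, Q(t) = mu1 * (1 + t)^(-a1), t in seconds.
``power_boost``
    The power law plus a constant upward "boost" applied at retention
    intervals of one day and longer, modelling the jump in savings commonly
    attributed to post-learning sleep.
``summed_exp``
    Sum of two exponentials, Q(t) = mu1*exp(-a1*t) + mu2*exp(-a2*t).
``mcm``
    The Memory Chain Model: an exponentially decaying fast store (rate a1,
    initial strength mu1) whose contents are copied at rate mu2 into a slower
    store (rate a2).  Algebraically a reparameterized summed exponential.
``single_exp``
    Q(t) = mu1 * exp(-a1 * t).

All decay-rate models take t in seconds; the two historical Ebbinghaus laws
take t in minutes, matching the units their parameters are conventionally
reported in.  :func:`evaluate` is the unit-safe entry point: it always takes
seconds and converts internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "DomainError",
    "DegenerateParameterizationError",
    "RetentionInterval",
    "ModelSpec",
    "ParamVector",
    "MODELS",
    "MODEL_NAMES",
    "DAY_SECONDS",
    "EBBINGHAUS_INTERVALS_S",
    "REPLICATION_INTERVALS_S",
    "eval_eb1880",
    "eval_eb1885",
    "eval_power",
    "eval_power_printed",
    "eval_power_boost",
    "eval_summed_exp",
    "eval_mcm",
    "eval_single_exp",
    "mcm_to_summed",
    "summed_to_mcm",
    "evaluate",
    "validate_params",
]

DAY_SECONDS = 86400.0

#: Retention intervals as stated for Ebbinghaus' own data: 19 min, 63 min,
#: 8.75 h (525 min), then 1, 2, 6, 31 days.
EBBINGHAUS_INTERVALS_S = (1140.0, 3780.0, 31500.0, 86400.0, 172800.0, 518400.0, 2678400.0)

#: Retention intervals of the replication studies: 20 min, 1 h, 9 h,
#: then 1, 2, 6, 31 days.
REPLICATION_INTERVALS_S = (1200.0, 3600.0, 32400.0, 86400.0, 172800.0, 518400.0, 2678400.0)


class DomainError(ValueError):
    """Time value outside a model's domain of definition."""


class DegenerateParameterizationError(ValueError):
    """Parameterization is singular (e.g. equal decay rates in the MCM map)."""


@dataclass(frozen=True)
class RetentionInterval:
    """Elapsed time between the end of learning and the start of relearning."""

    t_seconds: float

    def __post_init__(self) -> None:
        if not self.t_seconds > 0:
            raise ValueError(f"retention interval must be positive, got {self.t_seconds}")

    @classmethod
    def from_minutes(cls, minutes: float) -> "RetentionInterval":
        return cls(minutes * 60.0)

    @classmethod
    def from_hours(cls, hours: float) -> "RetentionInterval":
        return cls(hours * 3600.0)

    @classmethod
    def from_days(cls, days: float) -> "RetentionInterval":
        return cls(days * DAY_SECONDS)

    @property
    def t_minutes(self) -> float:
        return self.t_seconds / 60.0

    @property
    def t_days(self) -> float:
        return self.t_seconds / DAY_SECONDS


# ---------------------------------------------------------------------------
# Model evaluators (native time units)
# ---------------------------------------------------------------------------


def _as_array(t) -> np.ndarray:
    return np.asarray(t, dtype=float)


def eval_eb1880(t_minutes, mu1: float, a1: float):
    """Ebbinghaus' 1880 law Q(t) = 1 - [1 - (2/t)^a1]^mu1, t in minutes.

    Undefined for t < 2 min, where the inner bracket becomes negative; at
    exactly t = 2 the bracket is zero and Q = 1.
    """
    t = _as_array(t_minutes)
    if np.any(t < 2.0):
        raise DomainError("eb1880 is undefined for t < 2 minutes (singularity at t = 2)")
    q = 1.0 - (1.0 - (2.0 / t) ** a1) ** mu1
    return q if q.shape else float(q)


def eval_eb1885(t_minutes, mu1: float, a1: float):
    """Ebbinghaus' 1885 law Q(t) = mu1 / ((log10 t)^a1 + mu1), t in minutes."""
    t = _as_array(t_minutes)
    if np.any(t < 1.0):
        raise DomainError("eb1885 is undefined for t < 1 minute (negative log10)")
    q = mu1 / (np.log10(t) ** a1 + mu1)
    return q if q.shape else float(q)


def eval_power(t_seconds, mu1: float, a1: float):
    """Power law Q(t) = mu1 * (1 + t)^(-a1), t in seconds.

    The +1 offset keeps Q(0) = mu1 finite; at the multi-minute-and-longer
    intervals of savings experiments it is numerically indistinguishable from
    mu1 * t^(-a1).
    """
    t = _as_array(t_seconds)
    q = mu1 * (1.0 + t) ** (-a1)
    return q if q.shape else float(q)


def eval_power_printed(t_seconds, mu1: float, a1: float):
    """Alternative power form Q(t) = (1 + mu1*t)^(-a1).

    This is the form sometimes written in the forgetting literature, with the
    rate inside the base.  It is NOT the parameterization under which the
    published parameter tables for these savings curves were obtained (its SSD
    at those parameter values is an order of magnitude too large); it is kept
    only as a clearly labelled alternative.  Prefer :func:`eval_power`.
    """
    t = _as_array(t_seconds)
    q = (1.0 + mu1 * t) ** (-a1)
    return q if q.shape else float(q)


def eval_power_boost(t_seconds, mu1: float, a1: float, boost: float):
    """Power law plus a constant boost for t >= 1 day (half-open at 86400 s)."""
    t = _as_array(t_seconds)
    q = mu1 * (1.0 + t) ** (-a1) + boost * (t >= DAY_SECONDS)
    return q if q.shape else float(q)


def eval_summed_exp(t_seconds, mu1: float, a1: float, mu2: float, a2: float):
    """Sum of two exponentials Q(t) = mu1*exp(-a1*t) + mu2*exp(-a2*t)."""
    t = _as_array(t_seconds)
    q = mu1 * np.exp(-a1 * t) + mu2 * np.exp(-a2 * t)
    return q if q.shape else float(q)


#: Relative |a1 - a2| below which eval_mcm switches to its analytic limit,
#: avoiding catastrophic cancellation in (exp(-a2 t) - exp(-a1 t))/(a1 - a2).
MCM_DEGENERATE_RTOL = 1e-12


def eval_mcm(t_seconds, mu1: float, a1: float, mu2: float, a2: float):
    """Memory Chain Model retention function.

    Q(t) = mu1*exp(-a1*t) + mu1*mu2*(exp(-a2*t) - exp(-a1*t))/(a1 - a2)

    mu1: initial strength in the fast store; a1: its decay rate; mu2: rate of
    consolidation into the slow store; a2: the slow store's decay rate.  When
    a1 and a2 coincide to within ``MCM_DEGENERATE_RTOL`` the analytic limit
    mu1*exp(-a1*t)*(1 + mu2*t) is used.
    """
    t = _as_array(t_seconds)
    if abs(a1 - a2) < MCM_DEGENERATE_RTOL * max(abs(a1), abs(a2)):
        q = mu1 * np.exp(-a1 * t) * (1.0 + mu2 * t)
    else:
        q = mu1 * np.exp(-a1 * t) + mu1 * mu2 * (np.exp(-a2 * t) - np.exp(-a1 * t)) / (a1 - a2)
    return q if q.shape else float(q)


def eval_single_exp(t_seconds, mu1: float, a1: float):
    """Single exponential Q(t) = mu1 * exp(-a1 * t)."""
    t = _as_array(t_seconds)
    q = mu1 * np.exp(-a1 * t)
    return q if q.shape else float(q)


# ---------------------------------------------------------------------------
# MCM <-> summed-exponential reparameterization
# ---------------------------------------------------------------------------


def mcm_to_summed(mu1: float, a1: float, mu2: float, a2: float) -> tuple[float, float]:
    """Map MCM parameters to the amplitudes of the equivalent summed exponential.

    Returns (beta1, beta2) such that eval_summed_exp(t, beta1, a1, beta2, a2)
    equals eval_mcm(t, mu1, a1, mu2, a2) at every t.  Decay rates carry over
    unchanged.
    """
    if a1 == a2:
        raise DegenerateParameterizationError("mcm_to_summed requires a1 != a2")
    beta2 = mu1 * mu2 / (a1 - a2)
    beta1 = mu1 - beta2
    return beta1, beta2


def summed_to_mcm(beta1: float, a1: float, beta2: float, a2: float) -> tuple[float, float]:
    """Inverse of :func:`mcm_to_summed`: returns (mu1, mu2), rates unchanged."""
    if a1 == a2:
        raise DegenerateParameterizationError("summed_to_mcm requires a1 != a2")
    mu1 = beta1 + beta2
    if mu1 == 0:
        raise DegenerateParameterizationError("summed_to_mcm requires beta1 + beta2 != 0")
    mu2 = (a1 - a2) * beta2 / mu1
    return mu1, mu2


# ---------------------------------------------------------------------------
# Model registry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """A retention law: its parameter names, time unit, and fit bounds."""

    name: str
    param_names: tuple[str, ...]
    time_unit: str  # "seconds" or "minutes"
    bounds: tuple[tuple[float, float], ...]
    func: Callable = field(repr=False)

    @property
    def k(self) -> int:
        """Number of free parameters."""
        return len(self.param_names)

    def __post_init__(self) -> None:
        if len(self.bounds) != len(self.param_names):
            raise ValueError("bounds must match param_names")
        if self.time_unit not in ("seconds", "minutes"):
            raise ValueError(f"unknown time unit {self.time_unit!r}")

    def evaluate(self, t_seconds, params: Sequence[float] | Mapping[str, float]):
        """Evaluate Q at t given in seconds (unit conversion handled here)."""
        values = _param_values(self, params)
        t = np.asarray(t_seconds, dtype=float)
        if self.time_unit == "minutes":
            t = t / 60.0
        return self.func(t, *values)


def _param_values(spec: ModelSpec, params) -> tuple[float, ...]:
    if isinstance(params, Mapping):
        missing = [p for p in spec.param_names if p not in params]
        if missing:
            raise KeyError(f"missing parameters for {spec.name}: {missing}")
        return tuple(float(params[p]) for p in spec.param_names)
    values = tuple(float(v) for v in params)
    if len(values) != spec.k:
        raise ValueError(f"{spec.name} expects {spec.k} parameters, got {len(values)}")
    return values


@dataclass(frozen=True)
class ParamVector:
    """Validated parameter values for one model, keyed by its param_names."""

    model: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        validate_params(self.model, self.values)

    @property
    def names(self) -> tuple[str, ...]:
        return MODELS[self.model].param_names

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))

    def __getitem__(self, name: str) -> float:
        return self.as_dict()[name]


_RATE_BOUNDS = (1e-10, 1.0)
_AMP_BOUNDS = (1e-3, 10.0)

MODELS: dict[str, ModelSpec] = {
    "eb1880": ModelSpec("eb1880", ("mu1", "a1"), "minutes", ((1e-3, 20.0), (1e-3, 1.0)), eval_eb1880),
    "eb1885": ModelSpec("eb1885", ("mu1", "a1"), "minutes", ((1e-3, 50.0), (1e-2, 10.0)), eval_eb1885),
    "power": ModelSpec("power", ("mu1", "a1"), "seconds", (_AMP_BOUNDS, _RATE_BOUNDS), eval_power),
    "power_boost": ModelSpec(
        "power_boost", ("mu1", "a1", "boost"), "seconds", (_AMP_BOUNDS, _RATE_BOUNDS, (0.0, 0.5)), eval_power_boost
    ),
    "summed_exp": ModelSpec(
        "summed_exp", ("mu1", "a1", "mu2", "a2"), "seconds",
        (_AMP_BOUNDS, _RATE_BOUNDS, _AMP_BOUNDS, _RATE_BOUNDS), eval_summed_exp,
    ),
    "mcm": ModelSpec(
        "mcm", ("mu1", "a1", "mu2", "a2"), "seconds",
        (_AMP_BOUNDS, _RATE_BOUNDS, (1e-10, 1.0), _RATE_BOUNDS), eval_mcm,
    ),
    "single_exp": ModelSpec("single_exp", ("mu1", "a1"), "seconds", (_AMP_BOUNDS, _RATE_BOUNDS), eval_single_exp),
}

MODEL_NAMES = tuple(MODELS)


def validate_params(model: str, values: Sequence[float]) -> None:
    """Check the parameter-space invariants for a model; raise ValueError if violated."""
    spec = MODELS[model]
    vals = dict(zip(spec.param_names, values))
    if len(values) != spec.k:
        raise ValueError(f"{model} expects {spec.k} parameters, got {len(values)}")
    if not all(np.isfinite(v) for v in values):
        raise ValueError(f"{model} parameters must be finite: {values}")
    if vals["mu1"] <= 0:
        raise ValueError("mu1 must be > 0")
    if vals["a1"] < 0 or (model != "single_exp" and vals["a1"] <= 0):
        raise ValueError("a1 must be positive")
    if model in ("summed_exp", "mcm"):
        if vals["a2"] <= 0:
            raise ValueError("a2 must be > 0")
        if vals["mu2"] < 0:
            raise ValueError("mu2 must be >= 0")
    if model == "power_boost" and vals["boost"] < 0:
        raise ValueError("boost must be >= 0")


def evaluate(model: str, t_seconds, params) -> np.ndarray | float:
    """Evaluate a registered model at t (seconds); converts units internally."""
    return MODELS[model].evaluate(t_seconds, params)
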