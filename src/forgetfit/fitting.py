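"""Nonlinear least-squares fitting of retention models to savings curves.

The objective everywhere is the unweighted sum of squared differences (SSD)
between observed savings and the model prediction.  Goodness of fit is
summarized by three statistics as used in the savings literature:

* ``SSD``   — sum of squared residuals,
* ``R2u``   — uncentered variance explained, 1 - SSD / sum(Q_i^2),
* ``AIC``   — Gaussian-likelihood Akaike criterion,
  n*ln(2*pi*SSD/n) + n + 2*(k+1), counting the residual variance as one
  extra fitted parameter.  Differences larger than 2 are conventionally
  read as a meaningful difference in fit.

Generic models are fitted by seeded multi-start bounded least squares.  The
two summed-exponential families (``summed_exp`` and the Memory Chain Model,
``mcm``) are fitted by variable projection: for fixed decay rates the
amplitudes solve a non-negative linear least-squares problem, so the search
is over the two rates only, which makes the notoriously multi-modal
sum-of-exponentials problem reliable.  Because the MCM is an exact
reparameterization of the summed exponential, its fit is obtained from the
same optimum through the exact inverse parameter map — which is why the two
always report identical SSDs.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares, minimize, nnls

from .models import (
    MODELS,
    ModelSpec,
    summed_to_mcm,
)

logger = logging.getLogger("forgetfit.fitting")

__all__ = [
    "SavingsCurve",
    "FitResult",
    "ComparisonTable",
    "FitError",
    "UnderdeterminedError",
    "ssd",
    "r2_uncentered",
    "aic",
    "fit_model",
    "compare_models",
    "MEANINGFUL_DAIC",
]

#: AIC difference conventionally read as a meaningful difference in fit.
MEANINGFUL_DAIC = 2.0


class FitError(RuntimeError):
    """No optimization start converged."""


class UnderdeterminedError(ValueError):
    """Fewer data points than free parameters."""


@dataclass(frozen=True)
class SavingsCurve:
    """One subject's savings observations: (retention interval, savings) pairs.

    ``savings`` are dimensionless proportions; negative observed savings are
    legal (relearning can take longer than learning).  Optional per-point
    standard deviations and list counts travel along for aggregated curves.
    """

    subject: str
    t_seconds: tuple[float, ...]
    savings: tuple[float, ...]
    sd: tuple[float, ...] | None = None
    n_lists: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.t_seconds, dtype=float)
        q = np.asarray(self.savings, dtype=float)
        if t.size != q.size:
            raise ValueError("t_seconds and savings must have equal length")
        if t.size < 2:
            raise ValueError("a savings curve needs at least 2 points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("retention intervals must be strictly increasing")
        object.__setattr__(self, "t_seconds", tuple(float(x) for x in t))
        object.__setattr__(self, "savings", tuple(float(x) for x in q))

    @property
    def n(self) -> int:
        return len(self.t_seconds)

    @property
    def t(self) -> np.ndarray:
        return np.asarray(self.t_seconds)

    @property
    def q(self) -> np.ndarray:
        return np.asarray(self.savings)


@dataclass(frozen=True)
class FitResult:
    """A fitted model with its parameters and goodness-of-fit statistics."""

    model: ModelSpec
    params: dict[str, float]
    ssd: float
    r2: float
    aic: float
    n: int
    k: int
    n_starts: int
    seed: int
    converged: bool
    subject: str = ""

    @property
    def param_values(self) -> tuple[float, ...]:
        return tuple(self.params[p] for p in self.model.param_names)

    def predict(self, t_seconds):
        return self.model.evaluate(t_seconds, self.params)

    def to_dict(self) -> dict:
        return {
            "model": self.model.name,
            "subject": self.subject,
            "params": self.params,
            "SSD": self.ssd,
            "R2u": self.r2,
            "AIC": self.aic,
            "n": self.n,
            "k": self.k,
            "n_starts": self.n_starts,
            "seed": self.seed,
            "converged": self.converged,
        }


# ---------------------------------------------------------------------------
# Goodness-of-fit statistics
# ---------------------------------------------------------------------------


def ssd(curve: SavingsCurve, model: str | ModelSpec, params) -> float:
    """Sum of squared differences between the curve and the model prediction."""
    spec = MODELS[model] if isinstance(model, str) else model
    pred = np.asarray(spec.evaluate(curve.t, params))
    return float(np.sum((curve.q - pred) ** 2))


def r2_uncentered(curve: SavingsCurve, ssd_value: float) -> float:
    """Uncentered variance explained, 1 - SSD / sum(Q_i^2)."""
    total = float(np.sum(curve.q**2))
    if total == 0:
        raise ValueError("uncentered R^2 is undefined for an all-zero savings vector")
    return 1.0 - ssd_value / total


def aic(ssd_value: float, n: int, k: int) -> float:
    """Gaussian-likelihood AIC from a residual sum of squares.

    AIC = n*ln(2*pi*SSD/n) + n + 2*(k+1); the +1 counts the residual
    variance as a fitted parameter.  A perfect fit (SSD = 0) has no finite
    likelihood; -inf is returned with a warning.
    """
    if n <= 0 or k < 1:
        raise ValueError("aic requires n > 0 and k >= 1")
    if ssd_value < 0:
        raise ValueError("SSD must be non-negative")
    if ssd_value == 0:
        warnings.warn("SSD is exactly 0; AIC is -inf", RuntimeWarning, stacklevel=2)
        return float("-inf")
    return n * np.log(2.0 * np.pi * ssd_value / n) + n + 2.0 * (k + 1)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _log_uniform_starts(rng: np.random.Generator, bounds, n_starts: int) -> np.ndarray:
    """Log-uniform start values within bounds (floored at 1e-6 for log sampling)."""
    lo = np.maximum([b[0] for b in bounds], 1e-6)
    hi = np.asarray([b[1] for b in bounds], dtype=float)
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=(n_starts, len(bounds))))


def _residual_fn(spec: ModelSpec, curve: SavingsCurve):
    t = curve.t / 60.0 if spec.time_unit == "minutes" else curve.t
    q = curve.q

    def resid(p):
        with np.errstate(all="ignore"):
            r = spec.func(t, *p) - q
        return np.where(np.isfinite(r), r, 1e6)

    return resid


def _pick_best(candidates: list[tuple[float, tuple[float, ...]]]):
    """Lowest SSD; ties (within 1e-12) broken by lexicographically smallest params."""
    best_ssd = min(c[0] for c in candidates)
    tied = [c for c in candidates if c[0] <= best_ssd + 1e-12]
    return min(tied, key=lambda c: c[1])


def _fit_generic(spec: ModelSpec, curve: SavingsCurve, n_starts: int, seed: int, bounds):
    rng = np.random.default_rng(seed)
    starts = _log_uniform_starts(rng, bounds, n_starts)
    lo = [b[0] for b in bounds]
    hi = [b[1] for b in bounds]
    resid = _residual_fn(spec, curve)
    candidates: list[tuple[float, tuple[float, ...]]] = []
    for x0 in starts:
        try:
            res = least_squares(resid, x0, bounds=(lo, hi), method="trf")
        except Exception:  # singular Jacobian, domain failures etc.
            continue
        if res.success:
            candidates.append((float(2.0 * res.cost), tuple(float(v) for v in res.x)))
    if not candidates:
        raise FitError(
            f"no start converged for model {spec.name!r} on subject {curve.subject!r} "
            f"({n_starts} starts tried, seed {seed})"
        )
    return _pick_best(candidates), len(candidates)


def _fit_sum_of_exponentials(curve: SavingsCurve, n_starts: int, seed: int, rate_bounds):
    """Variable projection: search the two decay rates, solve amplitudes by NNLS."""
    t, q = curve.t, curve.q
    lo, hi = np.log(rate_bounds[0]), np.log(rate_bounds[1])

    def proj_ssd(log_rates):
        A = np.exp(-np.exp(log_rates)[None, :] * t[:, None])
        amps, rnorm = nnls(A, q)
        return rnorm**2, amps

    rng = np.random.default_rng(seed)
    candidates = []
    for _ in range(n_starts):
        x0 = rng.uniform(lo, hi, size=2)
        res = minimize(lambda lr: proj_ssd(lr)[0], x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 400})
        s, amps = proj_ssd(res.x)
        candidates.append((float(s), tuple(np.exp(res.x)), tuple(amps)))
    best = min(candidates, key=lambda c: c[0])
    # polish in the full 4-parameter space
    _, (ra, rb), (ba, bb) = best
    x0 = np.array([max(ba, 1e-8), ra, max(bb, 1e-8), rb])
    lo4 = [1e-10, rate_bounds[0], 1e-10, rate_bounds[0]]
    hi4 = [10.0, rate_bounds[1], 10.0, rate_bounds[1]]

    def resid(p):
        return p[0] * np.exp(-p[1] * t) + p[2] * np.exp(-p[3] * t) - q

    res = least_squares(resid, np.clip(x0, lo4, hi4), bounds=(lo4, hi4), method="trf",
                        xtol=1e-15, ftol=1e-15, gtol=1e-15)
    b1, a1, b2, a2 = (float(v) for v in res.x)
    if a1 < a2:  # convention: store 1 decays faster
        b1, a1, b2, a2 = b2, a2, b1, a1
    s = float(np.sum(resid([b1, a1, b2, a2]) ** 2))
    if s > best[0] + 1e-15:  # polish made it worse (rare); keep varpro optimum
        (s0, (ra, rb), (ba, bb)) = best
        b1, a1, b2, a2 = ba, ra, bb, rb
        if a1 < a2:
            b1, a1, b2, a2 = b2, a2, b1, a1
        s = s0
    return (b1, a1, b2, a2), s, n_starts


def fit_model(
    curve: SavingsCurve,
    model: str | ModelSpec,
    n_starts: int = 50,
    seed: int = 0,
    bounds: Sequence[tuple[float, float]] | None = None,
) -> FitResult:
    """Fit a retention model to a savings curve by multi-start least squares.

    Parameters
    ----------
    curve
        The observations; retention intervals in seconds (unit conversion for
        minutes-based models happens internally).
    model
        Registered model name or a :class:`ModelSpec`.
    n_starts
        Number of random starting points (log-uniform within bounds).
    seed
        Seed for the start sampler; the result is deterministic given it.
    bounds
        Optional per-parameter (lower, upper) overrides.

    Raises
    ------
    UnderdeterminedError
        If the curve has fewer points than the model has parameters.
    FitError
        If no start converges.
    """
    spec = MODELS[model] if isinstance(model, str) else model
    if curve.n < spec.k:
        raise UnderdeterminedError(
            f"{spec.name} has {spec.k} parameters but curve {curve.subject!r} has only {curve.n} points"
        )
    use_bounds = tuple(bounds) if bounds is not None else spec.bounds

    if spec.name in ("summed_exp", "mcm"):
        rate_bounds = use_bounds[1]
        values4, ssd_value, n_conv = _fit_sum_of_exponentials(curve, n_starts, seed, rate_bounds)
        if spec.name == "mcm":
            b1, a1, b2, a2 = values4
            mu1, mu2 = summed_to_mcm(b1, a1, b2, a2)
            values = (mu1, a1, mu2, a2)
        else:
            values = values4
        converged = True
    else:
        (ssd_value, values), n_conv = _fit_generic(spec, curve, n_starts, seed, use_bounds)
        converged = n_conv > 0

    params = dict(zip(spec.param_names, values))
    r2 = r2_uncentered(curve, ssd_value)
    aic_value = aic(ssd_value, curve.n, spec.k) if ssd_value > 0 else float("-inf")
    logger.debug("fit %s on %s: SSD=%.6g params=%s", spec.name, curve.subject, ssd_value, params)
    return FitResult(
        model=spec, params=params, ssd=ssd_value, r2=r2, aic=aic_value,
        n=curve.n, k=spec.k, n_starts=n_starts, seed=seed, converged=converged,
        subject=curve.subject,
    )


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------


@dataclass
class ComparisonTable:
    """Per-model, per-subject fits plus cross-subject averages and dAIC flags."""

    results: dict[str, dict[str, FitResult | str]] = field(default_factory=dict)
    subjects: tuple[str, ...] = ()
    models: tuple[str, ...] = ()

    def fits(self, model: str) -> list[FitResult]:
        return [r for r in self.results[model].values() if isinstance(r, FitResult)]

    def average(self, model: str, stat: str) -> float:
        vals = [getattr(r, stat) for r in self.fits(model)]
        return float(np.mean(vals)) if vals else float("nan")

    def average_aic(self) -> dict[str, float]:
        return {m: self.average(m, "aic") for m in self.models}

    def delta_aic(self) -> dict[str, float]:
        """Average AIC of each model minus the best (lowest) average AIC."""
        avg = self.average_aic()
        best = min(v for v in avg.values() if np.isfinite(v))
        return {m: v - best for m, v in avg.items()}

    def meaningful(self) -> dict[str, bool]:
        """True for models whose average AIC is > 2 worse than the best model's."""
        return {m: d > MEANINGFUL_DAIC for m, d in self.delta_aic().items()}

    def to_tsv(self) -> str:
        """Model-block table: one block per model, one column per subject + average."""
        lines = ["\t".join(["model", "stat", *self.subjects, "average"])]
        for m in self.models:
            spec = MODELS[m]
            rows: list[tuple[str, list]] = [(p, []) for p in spec.param_names]
            rows += [("SSD", []), ("R2u", []), ("AIC", [])]
            for s in self.subjects:
                r = self.results[m].get(s)
                if isinstance(r, FitResult):
                    for p, cells in rows[: spec.k]:
                        cells.append(f"{r.params[p]:.4g}")
                    rows[-3][1].append(f"{r.ssd:.3g}")
                    rows[-2][1].append(f"{r.r2:.3f}")
                    rows[-1][1].append(f"{r.aic:.1f}")
                else:
                    for _, cells in rows:
                        cells.append("fit-failed")
            avg_map = {"SSD": "ssd", "R2u": "r2", "AIC": "aic"}
            for name, cells in rows:
                avg_cell = ""
                if name in avg_map:
                    avg_cell = f"{self.average(m, avg_map[name]):.4g}"
                lines.append("\t".join([m, name, *cells, avg_cell]))
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        out: dict = {}
        for m in self.models:
            out[m] = {}
            for s in self.subjects:
                r = self.results[m].get(s)
                if isinstance(r, FitResult):
                    out[m][s] = {"params": r.params, "SSD": r.ssd, "R2u": r.r2, "AIC": r.aic}
                else:
                    out[m][s] = {"error": str(r)}
            out[m]["average"] = {
                "SSD": self.average(m, "ssd"),
                "R2u": self.average(m, "r2"),
                "AIC": self.average(m, "aic"),
            }
        out["delta_AIC"] = self.delta_aic()
        return json.dumps(out, indent=2)


def compare_models(
    curves: Iterable[SavingsCurve],
    model_list: Sequence[str],
    n_starts: int = 50,
    seed: int = 0,
) -> ComparisonTable:
    """Fit each model to each curve and tabulate SSD/R2u/AIC with averages.

    Individual fit failures are recorded per cell (as the error message) and
    do not abort the table.
    """
    curves = list(curves)
    if not curves:
        raise ValueError("compare_models needs at least one curve")
    if len(model_list) < 1:
        raise ValueError("compare_models needs at least one model")
    table = ComparisonTable(
        subjects=tuple(c.subject for c in curves), models=tuple(model_list)
    )
    for m in model_list:
        table.results[m] = {}
        for c in curves:
            try:
                table.results[m][c.subject] = fit_model(c, m, n_starts=n_starts, seed=seed)
            except Exception as exc:  # reported per cell, not fatal
                logger.warning("fit of %s on %s failed: %s", m, c.subject, exc)
                table.results[m][c.subject] = str(exc)
    return table
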