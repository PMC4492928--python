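"""Retention-model evaluation: frozen values, domains, and algebraic identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from forgetfit.models import (
    MODELS,
    DomainError,
    DegenerateParameterizationError,
    RetentionInterval,
    eval_eb1880,
    eval_eb1885,
    eval_mcm,
    eval_power,
    eval_power_boost,
    eval_power_printed,
    eval_single_exp,
    eval_summed_exp,
    evaluate,
    mcm_to_summed,
    summed_to_mcm,
    validate_params,
)


@pytest.mark.parametrize(
    "func, args, expected, tol",
    [
        # eb1880 (t in minutes): exact at the t=2 singularity, frozen elsewhere
        (eval_eb1880, (2.0, 0.7, 0.3), 1.0, 1e-12),
        (eval_eb1880, (525.0, 0.523, 0.101), 0.35665, 5e-5),
        (eval_eb1880, (44640.0, 0.523, 0.101), 0.21059, 5e-5),
        # eb1885 (t in minutes): Q(1) = 1 exactly
        (eval_eb1885, (1.0, 1.84, 1.25), 1.0, 0.0),
        (eval_eb1885, (19.0, 1.8, 1.21), 0.57206, 5e-5),
        (eval_eb1885, (1440.0, 1.8, 1.21), 0.30922, 5e-5),
        # power (t in seconds)
        (eval_power, (0.0, 1.4, 0.13), 1.4, 0.0),
        (eval_power, (518400.0, 1.4, 0.13), 0.25310, 5e-5),
        (eval_power, (32400.0, 0.965, 0.0926), 0.36885, 5e-5),
        # boost variant
        (eval_power_boost, (518400.0, 1.65, 0.152, 0.0303), 0.25358, 5e-5),
        # summed exponential
        (eval_summed_exp, (0.0, 0.383, 3.19e-4, 0.321, 1.79e-7), 0.704, 1e-12),
        (eval_summed_exp, (1140.0, 0.383, 3.19e-4, 0.321, 1.79e-7), 0.58714, 5e-5),
        (eval_summed_exp, (2678400.0, 0.383, 3.19e-4, 0.321, 1.79e-7), 0.19878, 5e-5),
        # MCM
        (eval_mcm, (0.0, 0.704, 3.19e-4, 1.45e-4, 1.79e-7), 0.704, 1e-12),
        (eval_mcm, (1140.0, 0.704, 3.19e-4, 1.45e-4, 1.79e-7), 0.58692, 5e-5),
        # single exponential: half-life identity
        (eval_single_exp, (np.log(2) / 1e-4, 0.6, 1e-4), 0.3, 1e-12),
        (eval_single_exp, (0.0, 0.6, 1e-4), 0.6, 0.0),
    ],
)
def test_frozen_evaluations(func, args, expected, tol):
    assert func(*args) == pytest.approx(expected, abs=max(tol, 1e-15))


def test_single_exp_zero_rate_is_constant():
    t = np.linspace(0, 3e6, 50)
    assert np.all(eval_single_exp(t, 0.42, 0.0) == 0.42)


def test_power_boost_step_at_one_day():
    below = eval_power_boost(86399.0, 1.65, 0.152, 0.131)
    at = eval_power_boost(86400.0, 1.65, 0.152, 0.131)
    plain = eval_power(86400.0, 1.65, 0.152)
    assert at - eval_power(86400.0, 1.65, 0.152) == pytest.approx(0.131, abs=1e-12)
    assert below == pytest.approx(eval_power(86399.0, 1.65, 0.152), abs=1e-12)
    assert at > below
    # zero boost degenerates to the plain power law everywhere
    t = np.geomspace(1.0, 3e6, 100)
    np.testing.assert_allclose(
        eval_power_boost(t, 1.4, 0.13, 0.0), eval_power(t, 1.4, 0.13), rtol=0, atol=0
    )


def test_eb1880_domain_and_limits():
    with pytest.raises(DomainError):
        eval_eb1880(1.9, 0.5, 0.1)
    with pytest.raises(DomainError):
        eval_eb1885(0.5, 1.8, 1.2)
    # Q -> 1 as t -> 2+ and -> 0 as t -> infinity
    assert eval_eb1880(2.0 + 1e-9, 0.523, 0.101) == pytest.approx(1.0, abs=1e-3)
    assert eval_eb1880(1e30, 0.523, 0.101) < 0.01


def test_printed_power_form_is_not_the_canonical_one():
    # the rate-inside-base form gives a very different value at table-scale t
    assert eval_power_printed(518400.0, 1.4, 0.13) != pytest.approx(
        eval_power(518400.0, 1.4, 0.13), rel=0.2
    )


@pytest.mark.parametrize("model", list(MODELS))
def test_models_non_increasing_in_t(model):
    """Valid parameters give non-increasing retention on a 100-point grid."""
    rng = np.random.default_rng(42)
    spec = MODELS[model]
    t = np.geomspace(3.0, 5e4, 100) if spec.time_unit == "minutes" else np.geomspace(1.0, 3e6, 100)
    for _ in range(20):
        if model in ("summed_exp", "mcm"):
            a1 = 10 ** rng.uniform(-5, -3)
            # MCM savings is monotone only while consolidation (mu2) is slower
            # than the fast store's decay (a1); draw within that regime
            mu2 = rng.uniform(0.01, 1) if model == "summed_exp" else a1 * rng.uniform(0.01, 0.9)
            params = (rng.uniform(0.1, 2), a1, mu2, 10 ** rng.uniform(-8, -6))
        elif model == "power_boost":
            params = (rng.uniform(0.5, 3), rng.uniform(0.05, 0.3), rng.uniform(0, 0.3))
        elif model == "eb1885":
            params = (rng.uniform(0.5, 3), rng.uniform(0.5, 2))
        elif model == "eb1880":
            params = (rng.uniform(0.2, 1), rng.uniform(0.03, 0.3))
        else:
            params = (rng.uniform(0.5, 3), 10 ** rng.uniform(-6, -4))
        q = np.asarray(spec.func(t, *params))
        if model == "power_boost":
            # monotone except the single upward step at t = 1 day
            step = np.searchsorted(t, 86400.0)
            assert np.all(np.diff(q[:step]) <= 1e-15)
            assert np.all(np.diff(q[step:]) <= 1e-15)
        else:
            assert np.all(np.diff(q) <= 1e-15)


def test_mcm_to_summed_matches_published_reparameterization():
    b1, b2 = mcm_to_summed(0.704, 0.000319, 0.000145, 1.79e-7)
    assert b1 == pytest.approx(0.3838, abs=5e-4)
    assert b2 == pytest.approx(0.3202, abs=5e-4)
    # no consolidation -> pure single exponential
    b1, b2 = mcm_to_summed(0.5, 1e-3, 0.0, 1e-7)
    assert (b1, b2) == (0.5, 0.0)
    with pytest.raises(DegenerateParameterizationError):
        mcm_to_summed(0.5, 1e-3, 1e-4, 1e-3)


@settings(max_examples=200, derandomize=True)
@given(
    mu1=st.floats(0.05, 3.0),
    la1=st.floats(-5.0, -2.5),
    mu2=st.floats(1e-6, 1e-3),
    la2=st.floats(-8.5, -6.0),
    lt=st.floats(0.0, 6.5),
)
def test_mcm_equals_summed_exp_under_reparameterization(mu1, la1, mu2, la2, lt):
    """eval_mcm == eval_summed_exp after the exact parameter map, at random t.

    Rates are drawn on well-separated log-decades (fast store vs slow store),
    the regime the model describes and where both algebraic forms are
    numerically stable.
    """
    a1, a2, t = 10.0**la1, 10.0**la2, 10.0**lt
    b1, b2 = mcm_to_summed(mu1, a1, mu2, a2)
    lhs = eval_mcm(t, mu1, a1, mu2, a2)
    rhs = eval_summed_exp(t, b1, a1, b2, a2)
    assert lhs == pytest.approx(rhs, rel=1e-12, abs=1e-15)
    # and the inverse map round-trips
    m1, m2 = summed_to_mcm(b1, a1, b2, a2)
    assert m1 == pytest.approx(mu1, rel=1e-12)
    assert m2 == pytest.approx(mu2, rel=1e-9, abs=1e-15)


def test_mcm_limit_branch_agrees_with_two_branch_formula():
    # at 10x the degenerate threshold the general formula is still accurate
    a1 = 1e-3
    a2 = a1 * (1 - 1e-11)  # |a1 - a2| = 10 * threshold * a1
    t = np.array([0.0, 10.0, 1e3, 1e5])
    general = 0.5 * np.exp(-a1 * t) + 0.5 * 2e-4 * (np.exp(-a2 * t) - np.exp(-a1 * t)) / (a1 - a2)
    ours = eval_mcm(t, 0.5, a1, 2e-4, a2)
    np.testing.assert_allclose(ours, general, rtol=1e-8)
    # closed-form limit value
    assert eval_mcm(1000.0, 0.5, 1e-3, 1e-4, 1e-3) == pytest.approx(0.5 * np.exp(-1) * 1.1, rel=1e-12)


def test_evaluate_converts_minutes_models_from_seconds():
    # 525 min passed as seconds must hit the minutes evaluator at t = 525
    assert evaluate("eb1880", 525 * 60.0, (0.523, 0.101)) == pytest.approx(0.35665, abs=5e-5)
    assert evaluate("eb1885", 60.0, (1.84, 1.25)) == 1.0


def test_param_validation_rejects_invalid_vectors():
    with pytest.raises(ValueError):
        validate_params("power", (-1.0, 0.1))
    with pytest.raises(ValueError):
        validate_params("summed_exp", (0.5, 1e-3, -0.1, 1e-6))
    with pytest.raises(ValueError):
        validate_params("power_boost", (0.5, 0.1, -0.01))
    validate_params("mcm", (0.5, 1e-3, 1e-4, 1e-6))  # valid


def test_retention_interval_constructors():
    assert RetentionInterval.from_minutes(20).t_seconds == 1200
    assert RetentionInterval.from_hours(9).t_seconds == 32400
    assert RetentionInterval.from_days(31).t_seconds == 2678400
    assert RetentionInterval.from_days(31).t_days == 31
    with pytest.raises(ValueError):
        RetentionInterval(0.0)
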