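"""Behavioral learning metrics: session means, power-law fits,
baseline adjustment, online-learning slopes, retention, percent change."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from npcpipe.behavior import (
    TrialSeries,
    baseline_adjust,
    fit_power_curve,
    online_learning_slopes,
    percent_change_behavior,
    retention_scores,
    session_means,
)

from conftest import make_trials


# ---------------------------------------------------------------- TrialSeries
def test_trialseries_missing_column():
    with pytest.raises(ValueError, match="missing columns"):
        TrialSeries(pd.DataFrame({"subject": ["a"], "session": [1], "trial": [1]}))


def test_trialseries_out_of_range_bal():
    df = pd.DataFrame(
        {"subject": ["a"], "session": [1], "trial": [1], "bal": [31.0]}
    )
    with pytest.raises(ValueError, match=r"\[0, 30\]"):
        TrialSeries(df)


def test_trialseries_incomplete_grid():
    df = pd.DataFrame(
        {
            "subject": ["a", "a", "b"],
            "session": [1, 1, 1],
            "trial": [1, 2, 1],
            "bal": [5.0, 6.0, 7.0],
        }
    )
    with pytest.raises(ValueError, match="incomplete"):
        TrialSeries(df)


# -------------------------------------------------------------- session_means
def test_session_means_constant(constant_trials):
    means = session_means(constant_trials)
    assert (means.to_numpy() == 10.0).all()


def test_session_means_arithmetic():
    # trials 1..15 s in one session -> mean 8
    series = make_trials({"a": {1: list(range(1, 16)), 2: list(range(1, 16))}})
    assert session_means(series).loc["a", 1] == 8.0


def test_session_means_brute_force(rng):
    vals = rng.uniform(0, 30, size=(3, 4, 6))  # subjects x sessions x trials
    series = make_trials(
        {
            f"s{i}": {j + 1: list(vals[i, j]) for j in range(4)}
            for i in range(3)
        }
    )
    means = session_means(series)
    for i in range(3):
        for j in range(4):
            assert means.loc[f"s{i}", j + 1] == pytest.approx(vals[i, j].mean())


# ------------------------------------------------------------ fit_power_curve
def _power_means(subjects_ab, sessions=6):
    s = np.arange(1, sessions + 1)
    return pd.DataFrame(
        {i + 1: [a * (i + 1) ** b for a, b in subjects_ab] for i in range(sessions)},
        index=[f"s{k}" for k in range(len(subjects_ab))],
    )


def test_power_fit_exact():
    means = _power_means([(5.0, 0.3), (4.0, 0.5), (6.0, 0.1)])
    fit = fit_power_curve(means)
    assert fit.params["a"].to_numpy() == pytest.approx([5, 4, 6], abs=1e-6)
    assert fit.params["b"].to_numpy() == pytest.approx([0.3, 0.5, 0.1], abs=1e-6)
    assert (fit.params["resid_norm"] < 1e-8).all()


def test_power_fit_constant_means_gives_zero_slope():
    means = pd.DataFrame(
        {s: [7.0, 3.0] for s in range(1, 7)}, index=["a", "b"]
    )
    fit = fit_power_curve(means)
    assert fit.params["b"].to_numpy() == pytest.approx([0.0, 0.0], abs=1e-8)


def test_power_fit_monte_carlo_bias(rng):
    # noisy curves: mean bias of the recovered exponent stays small
    s = np.arange(1, 7)
    true_b = 0.35
    est = []
    for _ in range(200):
        y = 5.0 * s**true_b + rng.normal(0, 0.05, size=6)
        means = pd.DataFrame({i + 1: [y[i]] for i in range(6)}, index=["x"])
        est.append(fit_power_curve(means).params["b"].iloc[0])
    assert abs(np.mean(est) - true_b) < 0.02


def test_power_fit_preconditions():
    with pytest.raises(ValueError, match="at least 3 sessions"):
        fit_power_curve(pd.DataFrame({1: [1.0], 2: [2.0]}, index=["a"]))
    bad = _power_means([(5.0, 0.3)])
    bad.iloc[0, 0] = 0.0
    with pytest.raises(ValueError, match="non-positive"):
        fit_power_curve(bad)


# ------------------------------------------------------------ baseline_adjust
def test_baseline_adjust_proportional_is_zero(rng):
    b = rng.normal(10, 2, 20)
    assert baseline_adjust(2 * b, b) == pytest.approx(np.zeros(20), abs=1e-10)


def test_baseline_adjust_orthogonality(rng):
    v = rng.normal(size=50)
    b = rng.normal(size=50)
    r = baseline_adjust(v, b)
    assert abs(r @ (b - b.mean())) < 1e-8
    assert abs(r.mean()) < 1e-12


def test_baseline_adjust_constant_baseline_rejected():
    with pytest.raises(ValueError, match="constant baseline"):
        baseline_adjust(np.arange(5.0), np.full(5, 3.0))


@given(st.integers(min_value=0, max_value=10_000))
def test_baseline_adjust_property(seed):
    rng = np.random.default_rng(seed)
    v = rng.normal(size=12)
    b = rng.normal(size=12)
    r = baseline_adjust(v, b)
    # mean-zero, orthogonal to centered baseline, and idempotent
    assert abs(r.mean()) < 1e-10
    assert abs(r @ (b - b.mean())) < 1e-8
    assert baseline_adjust(r, b) == pytest.approx(r, abs=1e-10)


# ----------------------------------------------------- online_learning_slopes
def test_online_slopes_linear_exact():
    trials = np.arange(1, 16)
    series = make_trials(
        {
            "a": {1: list(0.5 * trials + 3), 2: list(0.5 * trials + 3)},
            "b": {1: list(0.2 * trials + 5), 2: list(0.2 * trials + 5)},
        }
    )
    df = online_learning_slopes(series)
    a1 = df[(df.subject == "a") & (df.session == 1)].iloc[0]
    assert a1["slope"] == pytest.approx(0.5, abs=1e-10)
    assert a1["intercept"] == pytest.approx(3.0, abs=1e-10)


def test_online_slopes_flat_is_zero():
    series = make_trials({"a": {1: [9] * 6}, "b": {1: [4] * 6}})
    df = online_learning_slopes(series)
    assert df["slope"].to_numpy() == pytest.approx([0.0, 0.0], abs=1e-12)


def test_online_slopes_recover_trend(rng):
    trials = np.arange(1, 16)
    data = {}
    for i in range(40):
        noise = rng.normal(0, 0.5, 15)
        data[f"s{i:02d}"] = {1: list(np.clip(5 + 0.2 * trials + noise, 0, 30))}
    df = online_learning_slopes(make_trials(data))
    se = df["slope"].std(ddof=1) / np.sqrt(len(df))
    assert abs(df["slope"].mean() - 0.2) < 3 * se + 1e-9


# ------------------------------------------------------------ retention (Eq.1)
def test_retention_plus_20_percent():
    # final two trials of TS_1 average 10; initial two of TS_2 average 12
    series = make_trials(
        {
            "a": {1: [10, 10, 10, 10], 2: [12, 12, 8, 8]},
            "b": {1: [10, 10, 10, 10], 2: [10, 10, 10, 10]},
        }
    )
    ret = retention_scores(series)
    a = ret[(ret.subject == "a")].iloc[0]
    assert a["retention"] == pytest.approx(20.0)
    b = ret[(ret.subject == "b")].iloc[0]
    assert b["retention"] == pytest.approx(0.0)


def test_retention_hand_oracle_four_sessions():
    series = make_trials(
        {
            "a": {
                1: [5, 6, 7, 8],  # final two mean 7.5
                2: [6, 9, 9, 10],  # initial 7.5, final 9.5
                3: [9.5, 9.5, 11, 12],  # initial 9.5, final 11.5
                4: [23, 23, 25, 25],  # initial 23
            }
        }
    )
    ret = retention_scores(series).set_index("interval")["retention"]
    assert ret["TS_1-TS_2"] == pytest.approx(7.5 * 100 / 7.5 - 100)
    assert ret["TS_2-TS_3"] == pytest.approx(9.5 * 100 / 9.5 - 100)
    assert ret["TS_3-TS_4"] == pytest.approx(23 * 100 / 11.5 - 100)


def test_retention_scale_invariance(rng):
    vals = rng.uniform(3, 10, size=(3, 8))
    base = make_trials({"a": {i + 1: list(vals[i]) for i in range(3)}})
    scaled = make_trials({"a": {i + 1: list(2.5 * vals[i]) for i in range(3)}})
    r1 = retention_scores(base)["retention"].to_numpy()
    r2 = retention_scores(scaled)["retention"].to_numpy()
    assert r1 == pytest.approx(r2, abs=1e-10)


# --------------------------------------------------- percent_change_behavior
def test_percent_change_behavior_doubling():
    means = pd.DataFrame({1: [4.0], 2: [8.0], 3: [4.0]}, index=["a"])
    pc = percent_change_behavior(means)
    assert pc.loc["a", 2] == pytest.approx(100.0)
    assert pc.loc["a", 3] == pytest.approx(0.0)


def test_percent_change_behavior_preconditions():
    means = pd.DataFrame({1: [0.0], 2: [8.0]}, index=["a"])
    with pytest.raises(ValueError, match="non-positive reference"):
        percent_change_behavior(means)
    with pytest.raises(ValueError, match="not present"):
        percent_change_behavior(pd.DataFrame({2: [1.0]}, index=["a"]), 1)
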