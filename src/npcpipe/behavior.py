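"""Behavioral learning metrics for the dynamic balancing task (DBT).

The behavioral outcome per trial is BAL: the time (s) the seesaw platform
was kept within the ±3° horizontal target zone during a 30-s trial.
Subjects train for 6 weekly sessions of 15 trials.  From the trial table
this module derives

* per-session means,
* a two-parameter power-law learning curve ``mean(s) = a * s**b`` fitted
  per subject (``b`` is the learning rate),
* online-learning slopes (within-session linear trends) residualized on
  their intercepts across subjects,
* percent relative retention between consecutive sessions, and
* percentage change of session means from the baseline session.

Baseline adjustment everywhere means "residuals of an OLS regression on
the baseline variable (with intercept)", which removes the well-known
negative coupling between initial performance and subsequent learning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "TrialSeries",
    "LearningCurveFit",
    "session_means",
    "fit_power_curve",
    "baseline_adjust",
    "online_learning_slopes",
    "retention_scores",
    "percent_change_behavior",
]

TRIAL_SECONDS = 30.0


@dataclass
class TrialSeries:
    """Long-format trial table: one row per subject x session x trial."""

    table: pd.DataFrame  # columns: subject, session, trial, bal

    def __post_init__(self) -> None:
        required = {"subject", "session", "trial", "bal"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"trial table missing columns: {sorted(missing)}")
        bal = self.table["bal"].to_numpy(float)
        if np.any(~np.isfinite(bal)) or bal.min() < 0 or bal.max() > TRIAL_SECONDS:
            raise ValueError("BAL values must be finite and within [0, 30] s")
        self._check_complete()

    def _check_complete(self) -> None:
        counts = self.table.groupby(["subject", "session"])["trial"].nunique()
        n_trials = counts.iloc[0]
        sessions = self.table["session"].nunique()
        bad = counts[counts != n_trials]
        if len(bad):
            raise ValueError(f"incomplete trial grid at cells: {list(bad.index)}")
        per_subj = self.table.groupby("subject")["session"].nunique()
        bad_s = per_subj[per_subj != sessions]
        if len(bad_s):
            raise ValueError(f"subjects missing sessions: {list(bad_s.index)}")

    @property
    def subjects(self) -> list:
        return sorted(self.table["subject"].unique())

    @property
    def sessions(self) -> list:
        return sorted(self.table["session"].unique())

    @classmethod
    def from_csv(cls, path) -> "TrialSeries":
        return cls(pd.read_csv(path))


@dataclass
class LearningCurveFit:
    """Per-subject power-law fit plus baseline-adjusted learning rates."""

    params: pd.DataFrame  # index subject; columns a, b, resid_norm
    adjusted_slopes: pd.Series  # b residualized on session-1 mean


def session_means(series: TrialSeries) -> pd.DataFrame:
    """Arithmetic mean BAL per subject and session (subjects x sessions)."""
    wide = series.table.pivot_table(
        index="subject", columns="session", values="bal", aggfunc="mean"
    )
    return wide.sort_index()


def _power(s, a, b):
    return a * np.power(s, b)


def fit_power_curve(means: pd.DataFrame) -> LearningCurveFit:
    """Fit ``mean(s) = a * s**b`` per subject by nonlinear least squares.

    The fit is initialized from the log-log OLS solution, which makes it
    deterministic and exact on noiseless power-law data.  Requires >= 3
    sessions and strictly positive session means.
    """
    if means.shape[1] < 3:
        raise ValueError("power-curve fit needs at least 3 sessions")
    if (means.to_numpy() <= 0).any():
        raise ValueError("power-curve fit undefined for non-positive session means")
    s = np.asarray(means.columns, dtype=float)
    rows = []
    for subj, row in means.iterrows():
        y = row.to_numpy(float)
        # log-log OLS start values
        coef = np.polyfit(np.log(s), np.log(y), 1)
        p0 = (float(np.exp(coef[1])), float(coef[0]))
        try:
            popt, _ = curve_fit(_power, s, y, p0=p0, maxfev=10000)
        except RuntimeError:
            popt = p0
        a, b = float(popt[0]), float(popt[1])
        resid = y - _power(s, a, b)
        rows.append((subj, a, b, float(np.linalg.norm(resid))))
    params = pd.DataFrame(rows, columns=["subject", "a", "b", "resid_norm"]).set_index(
        "subject"
    )
    baseline = means.iloc[:, 0].loc[params.index].to_numpy(float)
    try:
        adj = baseline_adjust(params["b"].to_numpy(float), baseline)
    except ValueError as e:
        import warnings

        warnings.warn(f"baseline adjustment unavailable ({e}); b_adj set to NaN")
        adj = np.full(len(params), np.nan)
    return LearningCurveFit(
        params=params, adjusted_slopes=pd.Series(adj, index=params.index, name="b_adj")
    )


def baseline_adjust(values: np.ndarray, baseline: np.ndarray) -> np.ndarray:
    """Residuals of OLS of ``values`` on ``baseline`` (with intercept).

    Output is mean-zero and orthogonal to the baseline; a constant
    baseline makes the regression degenerate and is rejected.
    """
    v = np.asarray(values, dtype=float)
    b = np.asarray(baseline, dtype=float)
    if v.shape != b.shape or v.ndim != 1:
        raise ValueError("values and baseline must be equal-length vectors")
    if v.size < 3:
        raise ValueError("need at least 3 observations")
    bc = b - b.mean()
    ss = bc @ bc
    if ss <= v.size * np.finfo(float).eps * max(1.0, float(np.abs(b).max()) ** 2):
        raise ValueError("constant baseline: regression degenerate")
    vc = v - v.mean()
    slope = (bc @ vc) / ss
    return vc - slope * bc


def online_learning_slopes(series: TrialSeries) -> pd.DataFrame:
    """Within-session linear trends of BAL over trials.

    Per subject and session an OLS line ``bal ~ trial`` is fitted; the
    session's slopes are then residualized on the intercepts across
    subjects (initial performance typically anticorrelates with the rate
    of improvement).  Returns a long frame with columns ``subject,
    session, slope, intercept, slope_adj``.
    """
    recs = []
    for (subj, sess), g in series.table.groupby(["subject", "session"]):
        t = g["trial"].to_numpy(float)
        if t.size < 3:
            raise ValueError("online-learning slopes need >= 3 trials per session")
        y = g["bal"].to_numpy(float)
        slope, intercept = np.polyfit(t, y, 1)
        recs.append((subj, sess, float(slope), float(intercept)))
    df = pd.DataFrame(recs, columns=["subject", "session", "slope", "intercept"])
    out = []
    for sess, g in df.groupby("session"):
        try:
            adj = baseline_adjust(g["slope"].to_numpy(), g["intercept"].to_numpy())
        except ValueError as e:
            import warnings

            warnings.warn(
                f"session {sess}: baseline adjustment unavailable ({e}); "
                "slope_adj set to NaN"
            )
            adj = np.full(len(g), np.nan)
        gg = g.copy()
        gg["slope_adj"] = adj
        out.append(gg)
    return pd.concat(out).sort_values(["subject", "session"]).reset_index(drop=True)


def retention_scores(series: TrialSeries) -> pd.DataFrame:
    """Percent relative retention between consecutive training sessions.

    Initial performance of session ``i`` is the mean of its first two
    trials; final performance of session ``i-1`` the mean of its last two.
    The score is ``initial(TS_i) * 100 / final(TS_{i-1}) - 100``, so 0
    means perfect retention across the between-session break.
    """
    sessions = series.sessions
    if len(sessions) < 2:
        raise ValueError("retention needs at least 2 sessions")
    tab = series.table.sort_values(["subject", "session", "trial"])
    init = (
        tab.groupby(["subject", "session"])
        .apply(lambda g: g["bal"].iloc[:2].mean(), include_groups=False)
        .unstack("session")
    )
    fin = (
        tab.groupby(["subject", "session"])
        .apply(lambda g: g["bal"].iloc[-2:].mean(), include_groups=False)
        .unstack("session")
    )
    recs = []
    for prev, nxt in zip(sessions[:-1], sessions[1:]):
        f = fin[prev]
        if (f <= 0).any():
            raise ValueError(f"zero final performance in session {prev}")
        score = init[nxt] * 100.0 / f - 100.0
        for subj, val in score.items():
            recs.append((subj, f"TS_{prev}-TS_{nxt}", float(val)))
    return pd.DataFrame(recs, columns=["subject", "interval", "retention"])


def percent_change_behavior(
    means: pd.DataFrame, reference_session: int = 1
) -> pd.DataFrame:
    """Percentage change of session means relative to a reference session.

    Returns subjects x later-sessions, values ``100*(m_k - m_ref)/m_ref``.
    """
    if reference_session not in means.columns:
        raise ValueError(f"reference session {reference_session} not present")
    ref = means[reference_session]
    if (ref <= 0).any():
        raise ValueError("non-positive reference session mean")
    later = [c for c in means.columns if c != reference_session]
    out = means[later].sub(ref, axis=0).div(ref, axis=0) * 100.0
    return out
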