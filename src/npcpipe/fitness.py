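"""Graded-exercise-test (GXT) indices of cardiovascular fitness.

A cycle-ergometer GXT (WHO scheme: start 25 W, +25 W every 2 min) yields
per-stage workload, heart rate and capillary lactate.  Derived indices:

* PWC120 / PWC170 -- body-mass-normalized workload (W/kg) at fixed heart
  rates of 120 / 170 bpm, by piecewise-linear interpolation of the
  workload-heart-rate pairs.
* P3 -- workload (W/kg) at a fixed lactate of 3 mmol/l from a degree-3
  polynomial fit of the lactate-workload curve.
* IAT -- individual anaerobic threshold, the workload at which the fitted
  lactate exceeds its fitted minimum by 1.5 mmol/l ("1.5 mmol method").

A one-sample t-test compares training lactate (as % of each subject's IAT
lactate) against 100 to verify that the intervention strained the
anaerobic-lactic system.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = ["GxtRecord", "pwc", "lactate_curve_indices", "lactate_vs_iat_test"]


@dataclass
class GxtRecord:
    workload: np.ndarray  # W, strictly increasing per stage
    heart_rate: np.ndarray  # bpm
    lactate: np.ndarray  # mmol/l
    body_mass: float  # kg

    def __post_init__(self) -> None:
        self.workload = np.asarray(self.workload, float)
        self.heart_rate = np.asarray(self.heart_rate, float)
        self.lactate = np.asarray(self.lactate, float)
        if not (len(self.workload) == len(self.heart_rate) == len(self.lactate)):
            raise ValueError("stage arrays must be equal length")
        if np.any(np.diff(self.workload) <= 0):
            raise ValueError("workloads must be strictly increasing")
        if len(self.workload) < 2:
            raise ValueError("need at least 2 stages")
        if self.body_mass <= 0:
            raise ValueError("body mass must be positive")


def pwc(record: GxtRecord, target_hr: float) -> float:
    """Workload (W/kg) at ``target_hr`` by linear interpolation; no
    extrapolation outside the observed heart-rate range."""
    hr = record.heart_rate
    if not (hr.min() <= target_hr <= hr.max()):
        raise ValueError(
            f"target heart rate {target_hr} outside observed range "
            f"[{hr.min()}, {hr.max()}]"
        )
    if np.any(np.diff(hr) < 0):
        warnings.warn("heart rate not monotone over stages; using first crossing")
        for i in range(len(hr) - 1):
            lo, hi = sorted((hr[i], hr[i + 1]))
            if lo <= target_hr <= hi:
                w = np.interp(
                    target_hr, [hr[i], hr[i + 1]][:: 1 if hr[i] <= hr[i + 1] else -1],
                    [record.workload[i], record.workload[i + 1]][
                        :: 1 if hr[i] <= hr[i + 1] else -1
                    ],
                )
                return float(w) / record.body_mass
    w = np.interp(target_hr, hr, record.workload)
    return float(w) / record.body_mass


def lactate_curve_indices(
    record: GxtRecord,
    target_lactate: float = 3.0,
    iat_delta: float = 1.5,
    iat_baseline: str = "fitted_minimum",
) -> dict:
    """Cubic lactate-curve indices: P3, IAT and the lactate at IAT.

    The lactate-workload pairs are fitted with a degree-3 polynomial.
    ``P3`` is the smallest in-range workload where the fitted curve equals
    ``target_lactate``; ``IAT`` the smallest in-range workload where it
    equals baseline + ``iat_delta``, the baseline being the fitted curve's
    in-range minimum (``iat_baseline="fitted_minimum"``, default) or the
    first stage's fitted value (``"first_stage"``).  Workloads are
    body-mass normalized (W/kg).
    """
    if len(record.workload) < 4:
        raise ValueError("cubic lactate fit needs at least 4 stages")
    w, lac = record.workload, record.lactate
    coef = np.polyfit(w, lac, 3)
    poly = np.poly1d(coef)

    lo, hi = float(w.min()), float(w.max())
    grid = np.linspace(lo, hi, 2001)
    vals = poly(grid)

    if iat_baseline == "fitted_minimum":
        base = float(vals.min())
    elif iat_baseline == "first_stage":
        base = float(poly(lo))
    else:
        raise ValueError("iat_baseline must be 'fitted_minimum' or 'first_stage'")

    def first_crossing(level: float) -> float:
        f = vals - level
        sign_change = np.nonzero(np.diff(np.signbit(f)) | (f[:-1] == 0))[0]
        if f[0] == 0:
            return lo
        if len(sign_change) == 0:
            raise ValueError(
                f"fitted lactate curve never crosses {level:.3g} mmol/l in range"
            )
        i = sign_change[0]
        return float(optimize.brentq(lambda x: poly(x) - level, grid[i], grid[i + 1]))

    p3_w = first_crossing(target_lactate)
    # the IAT crossing is searched to the right of the minimum
    if iat_baseline == "fitted_minimum":
        imin = int(np.argmin(vals))
        vals_iat = vals[imin:]
        grid_iat = grid[imin:]
    else:
        vals_iat, grid_iat = vals, grid
    f = vals_iat - (base + iat_delta)
    sign_change = np.nonzero(np.diff(np.signbit(f)) | (f[:-1] == 0))[0]
    if f[0] >= 0:
        iat_w = float(grid_iat[0])
    elif len(sign_change) == 0:
        raise ValueError("fitted curve never reaches baseline + delta in range")
    else:
        i = sign_change[0]
        iat_w = float(
            optimize.brentq(
                lambda x: poly(x) - (base + iat_delta), grid_iat[i], grid_iat[i + 1]
            )
        )

    return {
        "p3": p3_w / record.body_mass,
        "iat": iat_w / record.body_mass,
        "iat_lactate": float(poly(iat_w)),
        "fit_coefficients": coef.tolist(),
        "iat_baseline": iat_baseline,
        "fit_residual_norm": float(np.linalg.norm(poly(w) - lac)),
    }


def lactate_vs_iat_test(
    session_lactate_pct: np.ndarray, mu0: float = 100.0
) -> dict:
    """One-sample t-test of per-subject training lactate (% of IAT) vs 100.

    ``session_lactate_pct`` holds each subject's mean training lactate
    already normalized to that subject's IAT lactate (in percent).
    Returns mean difference from ``mu0``, 95% CI, t and two-sided p.
    """
    x = np.asarray(session_lactate_pct, float)
    if x.size < 2:
        raise ValueError("need at least 2 subjects")
    if np.allclose(x.std(ddof=1), 0):
        if np.allclose(x.mean(), mu0):
            return {
                "mean_diff": 0.0,
                "ci": (0.0, 0.0),
                "t": np.nan,
                "p": np.nan,
                "df": x.size - 1,
                "degenerate": True,
            }
        raise ValueError("zero variance: t statistic undefined")
    res = stats.ttest_1samp(x, mu0)
    diff = float(x.mean() - mu0)
    se = float(x.std(ddof=1) / np.sqrt(x.size))
    tcrit = stats.t.ppf(0.975, x.size - 1)
    return {
        "mean_diff": diff,
        "ci": (diff - tcrit * se, diff + tcrit * se),
        "t": float(res.statistic),
        "p": float(res.pvalue),
        "df": x.size - 1,
        "degenerate": False,
    }
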