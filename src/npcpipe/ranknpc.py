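"""ROI/behavior-level NPC: rank-based permutation tests per interval,
closed-testing FWE adjustment, Fisher chi-square global p, Cliff's delta.

Each interval (e.g. baseline->MRI_2 ... baseline->MRI_5 percentage change
of an ROI average, or a session-wise behavioral score) contributes one
two-sample comparison of the treatment vs. control arms.  Comparisons
use a studentized Wilcoxon statistic: a Welch-type t computed on the
pooled mid-ranks, which keeps the permutation test valid under unequal
variances.  The k partial tests are evaluated under synchronized label
permutations; every intersection hypothesis is tested by Fisher
combination of the subset's per-permutation p-values (closed testing),
and the global null by the full-set intersection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import comb
from scipy.stats import norm, rankdata

__all__ = [
    "IntervalBattery",
    "RankNpcResult",
    "studentized_wilcoxon",
    "studentized_wilcoxon_perm",
    "battery_perm_pstreams",
    "closed_testing_adjust",
    "fisher_global",
    "cliffs_delta",
    "interval_battery_analysis",
]


def studentized_wilcoxon(x: np.ndarray, y: np.ndarray) -> float:
    """Welch-type t on pooled mid-ranks: positive when x ranks above y.

    Returns 0 (with a warning) when all pooled values are tied, where the
    statistic is undefined.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("need at least 2 observations per group")
    r = rankdata(np.concatenate([x, y]))
    rx, ry = r[:nx], r[nx:]
    vx, vy = rx.var(ddof=1), ry.var(ddof=1)
    se = np.sqrt(vx / nx + vy / ny)
    if se == 0:
        warnings.warn("all pooled values tied: studentized Wilcoxon undefined")
        return 0.0
    return float((rx.mean() - ry.mean()) / se)


def _welch_rank_stats(ranks: np.ndarray, idx: np.ndarray, nx: int) -> np.ndarray:
    """Vectorized statistic for label permutations.

    ``ranks``: pooled mid-ranks (fixed under relabeling).  ``idx``: (B, N)
    permutation index matrix; the first nx positions of each row are the
    x group.  Returns (B,) statistics.
    """
    rx = ranks[idx[:, :nx]]
    ry = ranks[idx[:, nx:]]
    ny = idx.shape[1] - nx
    vx = rx.var(axis=1, ddof=1)
    vy = ry.var(axis=1, ddof=1)
    se = np.sqrt(vx / nx + vy / ny)
    diff = rx.mean(axis=1) - ry.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = diff / se
    return np.where(se > 0, w, 0.0)


def _label_perms(
    N: int, nx: int, n_perm: int, seed: int, exhaustive: bool
) -> np.ndarray:
    """(B+1, N) index matrix; row 0 is the identity assignment."""
    if exhaustive:
        total = comb(N, nx, exact=True)
        if total > 200_000:
            raise ValueError(f"exhaustive enumeration infeasible: {total} assignments")
        rows = np.empty((total, N), dtype=np.int64)
        all_idx = np.arange(N)
        for b, xs in enumerate(combinations(range(N), nx)):
            xs = np.array(xs)
            rows[b, :nx] = xs
            rows[b, nx:] = np.setdiff1d(all_idx, xs, assume_unique=True)
        # move the identity assignment (0..nx-1) to the front
        ident = np.arange(N)
        pos = int(np.nonzero((rows == ident).all(axis=1))[0][0])
        rows[[0, pos]] = rows[[pos, 0]]
        return rows
    rng = np.random.default_rng(seed)
    idx = np.argsort(rng.random((n_perm + 1, N)), axis=1)
    idx[0] = np.arange(N)
    return idx


def studentized_wilcoxon_perm(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 1000,
    alternative: str = "greater",
    seed: int = 0,
    exhaustive: bool = False,
) -> tuple[float, float]:
    """One-sided permutation test on the studentized Wilcoxon statistic.

    ``alternative="greater"`` tests whether x tends to exceed y (and
    "less" the reverse).  With ``exhaustive=True`` all label assignments
    are enumerated and p = #{W_b >= W_obs} / total; otherwise ``n_perm``
    random relabelings give the (1+b)/(1+B) estimate.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    nx, N = x.size, x.size + y.size
    sign = 1.0 if alternative == "greater" else -1.0
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    ranks = rankdata(np.concatenate([x, y]))
    if np.all(ranks == ranks[0]):
        warnings.warn("all pooled values tied: p = 1")
        return 0.0, 1.0
    idx = _label_perms(N, nx, n_perm, seed, exhaustive)
    stats = sign * _welch_rank_stats(ranks, idx, nx)
    obs = stats[0]
    if exhaustive:
        p = float((stats >= obs).mean())
    else:
        p = float((1.0 + (stats[1:] >= obs).sum()) / (1.0 + n_perm))
    return float(obs), p


@dataclass
class IntervalBattery:
    """k interval-wise two-sample comparisons sharing the same subjects.

    ``treatment`` and ``control``: (k, n_t) and (k, n_c) arrays of
    per-interval values.  ``direction``: "greater" if the alternative is
    treatment > control (e.g. FA change), "less" for the reverse (radial
    diffusivity, ALFF).
    """

    treatment: np.ndarray
    control: np.ndarray
    labels: list[str] = field(default_factory=list)
    direction: str = "greater"

    def __post_init__(self) -> None:
        self.treatment = np.atleast_2d(np.asarray(self.treatment, float))
        self.control = np.atleast_2d(np.asarray(self.control, float))
        if self.treatment.shape[0] != self.control.shape[0]:
            raise ValueError("treatment/control interval counts differ")
        if self.treatment.shape[1] < 2 or self.control.shape[1] < 2:
            raise ValueError("need at least 2 subjects per arm")
        if not self.labels:
            self.labels = [f"interval_{i+1}" for i in range(self.k)]

    @property
    def k(self) -> int:
        return self.treatment.shape[0]


def battery_perm_pstreams(
    battery: IntervalBattery, n_perm: int = 1000, seed: int = 0
) -> np.ndarray:
    """Synchronized per-permutation partial p-values, shape (B+1, k).

    One label-permutation matrix drives all k intervals.  For each
    interval, every permutation's statistic is ranked within that
    interval's own full permutation distribution, giving p in [1/(B+1),
    1]; row 0 holds the observed (raw) partial p-values.
    """
    nt = battery.treatment.shape[1]
    N = nt + battery.control.shape[1]
    sign = 1.0 if battery.direction == "greater" else -1.0
    idx = _label_perms(N, nt, n_perm, seed, exhaustive=False)
    B1 = idx.shape[0]
    p = np.empty((B1, battery.k))
    for i in range(battery.k):
        pooled = np.concatenate([battery.treatment[i], battery.control[i]])
        ranks = rankdata(pooled)
        stats = sign * _welch_rank_stats(ranks, idx, nt)
        r = rankdata(stats, method="min")
        p[:, i] = (B1 - r + 1.0) / B1
    return p


def _subset_pvalues(pstreams: np.ndarray) -> dict[frozenset, float]:
    """Closed-family intersection p-values from synchronized p-streams."""
    B1, k = pstreams.shape
    if k > 6:
        raise ValueError(
            "closed testing enumerates 2^k intersections; k > 6 unsupported "
            "(consider a max-statistic correction instead)"
        )
    logs = np.log(pstreams)
    out: dict[frozenset, float] = {}
    for r in range(1, k + 1):
        for S in combinations(range(k), r):
            T = -2.0 * logs[:, S].sum(axis=1)
            out[frozenset(S)] = float((T >= T[0]).mean())
    return out


def closed_testing_adjust(
    battery: IntervalBattery, n_perm: int = 1000, seed: int = 0
) -> dict:
    """FWE-adjusted partial p-values by the closed testing procedure.

    The adjusted p for interval i is the maximum intersection p over all
    subsets containing i; an elementary hypothesis is rejected at alpha
    only if every intersection containing it is.  Returns raw p,
    adjusted p and the global (full-intersection Fisher) p.
    """
    pstreams = battery_perm_pstreams(battery, n_perm=n_perm, seed=seed)
    subsets = _subset_pvalues(pstreams)
    k = battery.k
    raw = pstreams[0].copy()
    adjusted = np.array(
        [max(pv for S, pv in subsets.items() if i in S) for i in range(k)]
    )
    global_p = subsets[frozenset(range(k))]
    return {
        "raw_p": raw,
        "adjusted_p": adjusted,
        "global_p": global_p,
        "labels": list(battery.labels),
    }


def fisher_global(pstreams: np.ndarray) -> tuple[float, float]:
    """Global p by Fisher chi-square combination of synchronized partials.

    ``pstreams`` is the (B+1, k) matrix from
    :func:`battery_perm_pstreams` (row 0 observed).  The observed
    ``T = -2 * sum(log p)`` is referred to its own synchronized
    permutation distribution.
    """
    T = -2.0 * np.log(pstreams).sum(axis=1)
    return float(T[0]), float((T >= T[0]).mean())


_MAGNITUDE_THRESHOLDS = ((0.147, "negligible"), (0.33, "small"), (0.474, "medium"))


def cliffs_delta(x: np.ndarray, y: np.ndarray) -> dict:
    """Cliff's delta with a consistent-variance 95% CI and magnitude label.

    ``d = [#(x_i > y_j) - #(x_i < y_j)] / (n_x * n_y)`` -- the difference
    of the probabilities of superiority, in [-1, 1].  The CI uses Cliff's
    consistent variance estimate with the asymmetric transformation,
    clamped to [-1, 1].  Magnitudes: |d| < 0.147 negligible, < 0.33
    small, < 0.474 medium, otherwise large.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("need at least 2 observations per group")
    dij = np.sign(x[:, None] - y[None, :])
    d = float(dij.mean())
    di = dij.mean(axis=1)
    dj = dij.mean(axis=0)
    num = (
        ny**2 * np.sum((di - d) ** 2)
        + nx**2 * np.sum((dj - d) ** 2)
        - np.sum((dij - d) ** 2)
    )
    var_d = max(num / (nx * ny * (nx - 1) * (ny - 1)), 0.0)
    s = np.sqrt(var_d)
    z = norm.ppf(0.975)
    if s == 0:
        lo = hi = d
    else:
        denom = 1 - d**2 + z**2 * var_d
        half = z * s * np.sqrt((1 - d**2) ** 2 + z**2 * var_d)
        lo = (d - d**3 - half) / denom
        hi = (d - d**3 + half) / denom
    lo, hi = float(np.clip(lo, -1, 1)), float(np.clip(hi, -1, 1))
    magnitude = "large"
    for thr, name in _MAGNITUDE_THRESHOLDS:
        if abs(d) < thr:
            magnitude = name
            break
    return {"d": d, "ci": (lo, hi), "magnitude": magnitude, "se": float(s)}


@dataclass
class RankNpcResult:
    table: pd.DataFrame  # per interval: statistic, raw/adjusted p, Cliff d
    global_statistic: float
    global_p: float


def interval_battery_analysis(
    battery: IntervalBattery, n_perm: int = 1000, seed: int = 0
) -> RankNpcResult:
    """Complete interval battery: partial tests, closed testing, global p,
    Cliff's delta per interval."""
    pstreams = battery_perm_pstreams(battery, n_perm=n_perm, seed=seed)
    subsets = _subset_pvalues(pstreams)
    k = battery.k
    adjusted = [max(pv for S, pv in subsets.items() if i in S) for i in range(k)]
    Tg, pg = fisher_global(pstreams)
    rows = []
    for i in range(k):
        stat = studentized_wilcoxon(battery.treatment[i], battery.control[i])
        cd = cliffs_delta(battery.treatment[i], battery.control[i])
        rows.append(
            {
                "interval": battery.labels[i],
                "statistic": stat,
                "raw_p": float(pstreams[0, i]),
                "adjusted_p": float(adjusted[i]),
                "cliffs_d": cd["d"],
                "d_ci_low": cd["ci"][0],
                "d_ci_high": cd["ci"][1],
                "magnitude": cd["magnitude"],
            }
        )
    return RankNpcResult(
        table=pd.DataFrame(rows), global_statistic=Tg, global_p=pg
    )
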