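"""Parallel multiple-mediator model with percentile-bootstrap inference.

Quantifies how much of the treatment effect on the outcome (here: the
baseline-adjusted learning rate) is transmitted through one or more
mediators (averaged residualized brain change in significant clusters).
With binary treatment X (control = 0, treatment = 1), mediators M_j and
covariates C:

    M_j = i_j + a_j X + f_j' C + e          (one fit per mediator)
    Y   = i_y + c' X + sum_j b_j M_j + g' C + e

The specific indirect effect through M_j is ``a_j * b_j``; the total
indirect effect is their sum, and the OLS decomposition
``c = c' + sum_j a_j b_j`` holds exactly, where c is the X coefficient
of Y ~ X + C.  Inference on indirect effects uses case-resampling
bootstrap with percentile confidence intervals; no distributional
assumptions are imposed.  Mediators (and optionally Y) are standardized
before entry, so indirect effects are in SD units of the outcome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

__all__ = ["MediationData", "MediationResult", "fit_mediation", "bootstrap_indirect"]


@dataclass
class MediationData:
    x: np.ndarray  # binary treatment, control=0 / treatment=1
    mediators: np.ndarray  # (n, k)
    y: np.ndarray
    covariates: np.ndarray | None = None  # (n, q), e.g. age, sex
    mediator_names: list[str] | None = None
    standardize: bool = True

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, float)
        self.mediators = np.atleast_2d(np.asarray(self.mediators, float))
        if self.mediators.shape[0] != self.x.size:
            self.mediators = self.mediators.T
        self.y = np.asarray(self.y, float)
        n = self.x.size
        if self.mediators.shape[0] != n or self.y.size != n:
            raise ValueError("x, mediators and y must have equal length")
        if self.covariates is not None:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, float))
            if self.covariates.shape[0] != n:
                self.covariates = self.covariates.T
            if self.covariates.shape[0] != n:
                raise ValueError("covariate length mismatch")
        if not np.all(np.isin(self.x, (0.0, 1.0))):
            raise ValueError("treatment must be binary coded 0/1")
        if not (
            np.all(np.isfinite(self.mediators))
            and np.all(np.isfinite(self.y))
            and (self.covariates is None or np.all(np.isfinite(self.covariates)))
        ):
            raise ValueError("missing or non-finite values are not allowed")
        if self.mediator_names is None:
            self.mediator_names = [f"M{j+1}" for j in range(self.n_mediators)]

    @property
    def n_mediators(self) -> int:
        return self.mediators.shape[1]


def _zscore(a: np.ndarray, axis=0) -> np.ndarray:
    sd = a.std(axis=axis, ddof=1)
    return (a - a.mean(axis=axis)) / sd


def _design(cols: list[np.ndarray]) -> np.ndarray:
    return np.column_stack([np.ones(cols[0].size)] + cols)


def _collinearity_check(M: np.ndarray) -> dict:
    """Condition number and pairwise correlations of the mediator block."""
    k = M.shape[1]
    Z = _zscore(M)
    cond = float(np.linalg.cond(Z)) if k > 1 else 1.0
    corr = np.corrcoef(Z, rowvar=False) if k > 1 else np.ones((1, 1))
    if k > 1 and np.any(np.abs(corr[~np.eye(k, dtype=bool)]) > 1 - 1e-10):
        raise ValueError(
            f"mediators are collinear (condition number {cond:.3g}); "
            "drop or combine redundant mediators"
        )
    return {"condition_number": cond, "pairwise_correlation": corr.tolist()}


def _point_estimates(x, M, y, C) -> dict:
    """OLS point estimates of all mediation paths (plain linear algebra;
    used by both the observed fit and the bootstrap loop)."""
    cov_cols = [] if C is None else [C[:, q] for q in range(C.shape[1])]
    a = np.empty(M.shape[1])
    Xa = _design([x] + cov_cols)
    pinv_a = np.linalg.pinv(Xa)
    for j in range(M.shape[1]):
        a[j] = (pinv_a @ M[:, j])[1]
    Xy = _design([x] + [M[:, j] for j in range(M.shape[1])] + cov_cols)
    beta_y = np.linalg.pinv(Xy) @ y
    c_prime = beta_y[1]
    b = beta_y[2 : 2 + M.shape[1]]
    Xc = _design([x] + cov_cols)
    c_total = (np.linalg.pinv(Xc) @ y)[1]
    return {
        "a": a,
        "b": b,
        "c_prime": float(c_prime),
        "c_total": float(c_total),
        "specific_indirect": a * b,
        "total_indirect": float((a * b).sum()),
    }


def fit_mediation(data: MediationData, hc: str = "HC3") -> dict:
    """Point estimates plus heteroscedasticity-consistent standard errors.

    Returns path coefficients (a_j, b_j, c', c), indirect effects, the
    HC standard errors of the regression coefficients (``hc`` one of
    HC0..HC3) and a mediator collinearity report.
    """
    x = data.x
    M = _zscore(data.mediators) if data.standardize else data.mediators.copy()
    y = _zscore(data.y) if data.standardize else data.y.copy()
    C = data.covariates
    diag = _collinearity_check(data.mediators)

    est = _point_estimates(x, M, y, C)

    cov_cols = [] if C is None else [C[:, q] for q in range(C.shape[1])]
    Xy = _design([x] + [M[:, j] for j in range(M.shape[1])] + cov_cols)
    if np.linalg.matrix_rank(Xy) < Xy.shape[1]:
        raise ValueError(
            "outcome design rank deficient; mediator collinearity report: "
            f"{diag}"
        )
    fit_y = sm.OLS(y, Xy).fit(cov_type=hc)
    a_se = []
    Xa = _design([x] + cov_cols)
    for j in range(M.shape[1]):
        fa = sm.OLS(M[:, j], Xa).fit(cov_type=hc)
        a_se.append(float(fa.bse[1]))
    est.update(
        {
            "a_se": np.array(a_se),
            "b_se": fit_y.bse[2 : 2 + M.shape[1]],
            "c_prime_se": float(fit_y.bse[1]),
            "hc_type": hc,
            "collinearity": diag,
            "mediator_names": list(data.mediator_names),
        }
    )
    return est


def _batched_lstsq(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Solve OLS for a batch of designs: X (b, n, p), Y (b, n, m) -> (b, p, m).

    Uses normal equations with a ridge of machine-epsilon scale for
    near-degenerate resamples (possible under case resampling)."""
    XtX = np.einsum("bnp,bnq->bpq", X, X)
    XtY = np.einsum("bnp,bnm->bpm", X, Y)
    p = X.shape[2]
    tr = np.einsum("bpp->b", XtX)
    XtX = XtX + (1e-10 * tr / p)[:, None, None] * np.eye(p)
    return np.linalg.solve(XtX, XtY)


def _batched_specific_indirect(x, M, y, C) -> np.ndarray:
    """Vectorized specific indirect effects a_j*b_j over resamples.

    x: (b, n); M: (b, n, k); y: (b, n); C: (b, n, q) or None.
    """
    b_, n, k = M.shape
    ones = np.ones((b_, n, 1))
    cov = () if C is None else (C,)
    Xa = np.concatenate([ones, x[:, :, None], *cov], axis=2)
    a = _batched_lstsq(Xa, M)[:, 1, :]  # (b, k)
    Xy = np.concatenate([ones, x[:, :, None], M, *cov], axis=2)
    beta_y = _batched_lstsq(Xy, y[:, :, None])[:, :, 0]
    b_coef = beta_y[:, 2 : 2 + k]
    return a * b_coef


@dataclass
class MediationResult:
    paths: dict
    specific_indirect: np.ndarray
    specific_ci: np.ndarray  # (k, 2)
    specific_se: np.ndarray
    total_indirect: float
    total_ci: tuple[float, float]
    total_se: float
    n_boot: int
    seed: int
    n_redrawn: int
    mediator_names: list[str]


def bootstrap_indirect(
    data: MediationData,
    n_boot: int = 50_000,
    seed: int = 0,
    ci_level: float = 0.95,
    hc: str = "HC3",
) -> MediationResult:
    """Percentile-bootstrap CIs for total and specific indirect effects.

    Case resampling: subjects are drawn with replacement, all models are
    re-fit per resample, and the 2.5/97.5 percentiles of the bootstrap
    distributions give the CIs; SE is the bootstrap SD.  Resamples with a
    single treatment group cannot identify the paths and are redrawn
    (count reported).  A significant indirect effect is one whose CI
    excludes zero.
    """
    if n_boot < 1000:
        raise ValueError("n_boot must be at least 1000")
    est = fit_mediation(data, hc=hc)
    x = data.x
    M = _zscore(data.mediators) if data.standardize else data.mediators.copy()
    y = _zscore(data.y) if data.standardize else data.y.copy()
    C = data.covariates
    n, k = M.shape

    rng = np.random.default_rng(seed)
    spec = np.empty((n_boot, k))
    n_redrawn = 0
    for bstart in range(0, n_boot, 4096):
        bs = min(4096, n_boot - bstart)
        idx = rng.integers(0, n, size=(bs, n))
        # redraw degenerate (single-group) resamples
        bad = np.nonzero(x[idx].min(axis=1) == x[idx].max(axis=1))[0]
        while bad.size:
            n_redrawn += bad.size
            idx[bad] = rng.integers(0, n, size=(bad.size, n))
            bad = bad[x[idx[bad]].min(axis=1) == x[idx[bad]].max(axis=1)]
        spec[bstart : bstart + bs] = _batched_specific_indirect(
            x[idx], M[idx], y[idx], None if C is None else C[idx]
        )
    total = spec.sum(axis=1)

    lo_q, hi_q = 100 * (1 - ci_level) / 2, 100 * (1 + ci_level) / 2
    spec_ci = np.percentile(spec, [lo_q, hi_q], axis=0).T
    tot_ci = tuple(np.percentile(total, [lo_q, hi_q]))
    return MediationResult(
        paths=est,
        specific_indirect=est["specific_indirect"],
        specific_ci=spec_ci,
        specific_se=spec.std(axis=0, ddof=1),
        total_indirect=est["total_indirect"],
        total_ci=(float(tot_ci[0]), float(tot_ci[1])),
        total_se=float(total.std(ddof=1)),
        n_boot=n_boot,
        seed=seed,
        n_redrawn=n_redrawn,
        mediator_names=list(data.mediator_names),
    )
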