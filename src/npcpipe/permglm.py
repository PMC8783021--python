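"""Voxelwise partial-test GLMs and their synchronized permutation nulls.

The joint brain-behavior hypothesis is split into six partial tests per
imaging modality: for each of three learning intervals, (i) an
ANCOVA-type model regressing residualized change on group (age and sex as
nuisance) and (ii) a regression of change on concurrent behavioral change
(age, sex and group as nuisance).  All partial tests are one-sided in the
direction the theory predicts.

Null distributions are generated by Freedman-Lane permutation: the data
are reduced to nuisance-only residuals, those residuals are sign-flipped
(or the rows shuffled), the nuisance fit is added back, and the full
model is re-fit.  A single :class:`PermutationScheme` instance drives
every submodel, so the permutation sequence is *synchronized* -- the
prerequisite for combining the partial tests while preserving their
dependence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np

__all__ = [
    "SubModelSpec",
    "PermutationScheme",
    "build_design",
    "fit_partial_test",
    "permutation_distribution",
    "partial_pvalues",
]


@dataclass
class SubModelSpec:
    """One partial test of the six-submodel battery.

    kind : ``"group_ancova"`` (change ~ group + age + sex) or
        ``"brain_behavior"`` (change ~ behavior + age + sex + group).
    interval : learning interval index 1..3 (baseline to MRI_3/4/5).
    direction : ``"greater"`` or ``"less"`` -- the one-sided alternative
        for the regressor of interest.
    """

    kind: str
    interval: int
    direction: str = "greater"

    def __post_init__(self) -> None:
        if self.kind not in ("group_ancova", "brain_behavior"):
            raise ValueError(f"unknown submodel kind {self.kind!r}")
        if self.direction not in ("greater", "less"):
            raise ValueError("direction must be 'greater' or 'less'")


def build_design(cohort, kind: str, behavior: np.ndarray | None = None):
    """Design matrix and regressor-of-interest column for one submodel.

    ``cohort`` is a DataFrame with columns group (0/1), age, sex (0/1).
    Returns ``(X, coi, names)``.
    """
    n = len(cohort)
    intercept = np.ones(n)
    group = cohort["group"].to_numpy(float)
    age = cohort["age"].to_numpy(float)
    sex = cohort["sex"].to_numpy(float)
    if kind == "group_ancova":
        X = np.column_stack([intercept, group, age, sex])
        names = ["intercept", "group", "age", "sex"]
        coi = 1
    elif kind == "brain_behavior":
        if behavior is None:
            raise ValueError("brain_behavior submodel needs a behavior regressor")
        X = np.column_stack([intercept, np.asarray(behavior, float), age, sex, group])
        names = ["intercept", "behavior", "age", "sex", "group"]
        coi = 1
    else:
        raise ValueError(kind)
    _check_rank(X, names)
    return X, coi, names


def _check_rank(X: np.ndarray, names) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the offending pair(s) for the error message
        bad = []
        for i, j in combinations(range(X.shape[1]), 2):
            xi, xj = X[:, i], X[:, j]
            denom = np.linalg.norm(xi) * np.linalg.norm(xj)
            if denom > 0 and abs(xi @ xj) / denom > 1 - 1e-10:
                bad.append((names[i], names[j]))
        raise ValueError(f"design matrix rank deficient; collinear columns: {bad}")


@dataclass
class PermutationScheme:
    """Shared permutation source for synchronized submodel testing.

    ``n_perm`` counts random permutations beyond the identity; the
    identity is always iteration 0, so ``n_perm + 1`` statistics are
    produced per submodel.  ``method`` is ``"sign_flip"`` (within-subject
    sign flipping of nuisance residuals) or ``"label_shuffle"`` (row
    permutation).  The draw matrix is generated once and cached, so every
    submodel fed the same scheme instance consumes the identical
    sequence.
    """

    n_perm: int = 1000
    seed: int = 0
    method: str = "sign_flip"
    synchronized: bool = True
    exhaustive: bool = False
    _draws: np.ndarray | None = field(default=None, repr=False, compare=False)
    _n_subjects: int | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.method not in ("sign_flip", "label_shuffle"):
            raise ValueError("method must be 'sign_flip' or 'label_shuffle'")
        if not self.exhaustive and self.n_perm < 100:
            import warnings

            warnings.warn("n_perm < 100: permutation tails will be unstable")

    def draws(self, n_subjects: int) -> np.ndarray:
        """(B+1, n) matrix of signs or permutation indices, identity first."""
        if self._draws is not None:
            if self._n_subjects != n_subjects:
                raise ValueError("scheme already bound to a different subject count")
            return self._draws
        rng = np.random.default_rng(self.seed)
        if self.exhaustive:
            if self.method == "sign_flip":
                all_signs = np.array(
                    list(product([1, -1], repeat=n_subjects)), dtype=np.int8
                )
                # identity (all +1) is the first tuple produced by product
                mat = all_signs
            else:
                raise ValueError(
                    "exhaustive enumeration is only provided for sign_flip; "
                    "use ranknpc for exhaustive label tests"
                )
        elif self.method == "sign_flip":
            mat = rng.choice([-1, 1], size=(self.n_perm + 1, n_subjects)).astype(
                np.int8
            )
            mat[0] = 1
        else:
            mat = np.empty((self.n_perm + 1, n_subjects), dtype=np.int64)
            mat[0] = np.arange(n_subjects)
            for b in range(1, self.n_perm + 1):
                mat[b] = rng.permutation(n_subjects)
        self._draws = mat
        self._n_subjects = n_subjects
        return mat

    @property
    def draw_log(self) -> dict:
        return {
            "n_perm": self.n_perm,
            "seed": self.seed,
            "method": self.method,
            "exhaustive": self.exhaustive,
            "bound_subjects": self._n_subjects,
            "draw_checksum": (
                None
                if self._draws is None
                else int(np.abs(self._draws.astype(np.int64)).sum())
            ),
        }


def _oriented_t(Y: np.ndarray, X: np.ndarray, coi: int, direction: str) -> np.ndarray:
    """Per-voxel OLS t for column ``coi``; sign-oriented so larger = more
    evidence in the hypothesized direction.  Y is (n, V) or (B, n, V)."""
    n, p = X.shape
    pinv = np.linalg.pinv(X)
    xtx_inv_cc = float(np.linalg.inv(X.T @ X)[coi, coi])
    squeeze = Y.ndim == 2
    if squeeze:
        Y = Y[None]
    beta_c = np.einsum("j,bjv->bv", pinv[coi], Y)
    # residual sum of squares via QR projection: ||Y||^2 - ||Q'Y||^2
    Q = np.linalg.qr(X)[0]
    QtY = np.einsum("jp,bjv->bpv", Q, Y)
    ss_tot = np.einsum("bjv,bjv->bv", Y, Y)
    ss_fit = np.einsum("bpv,bpv->bv", QtY, QtY)
    sigma2 = np.maximum(ss_tot - ss_fit, 0.0) / (n - p)
    se = np.sqrt(np.maximum(sigma2 * xtx_inv_cc, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta_c / se
    t = np.where(se > 0, t, 0.0)
    if direction == "less":
        t = -t
    return t[0] if squeeze else t


def fit_partial_test(
    Y: np.ndarray, X: np.ndarray, coi: int, direction: str = "greater"
) -> np.ndarray:
    """Observed oriented t-map for one submodel.  ``Y`` is (n, V)."""
    if Y.shape[0] != X.shape[0]:
        raise ValueError("subjects misaligned between data and design")
    _check_rank(X, [f"col{i}" for i in range(X.shape[1])])
    return _oriented_t(np.asarray(Y, float), X, coi, direction)


def permutation_distribution(
    Y: np.ndarray,
    X: np.ndarray,
    coi: int,
    scheme: PermutationScheme,
    direction: str = "greater",
    batch_size: int = 128,
) -> np.ndarray:
    """Freedman-Lane permutation t-maps, identity first: shape (B+1, V).

    Nuisance-only residuals of Y are sign-flipped (or shuffled), the
    nuisance fit added back, and the full-model t recomputed per
    permutation.
    """
    Y = np.asarray(Y, float)
    n, V = Y.shape
    draws = scheme.draws(n)
    Z = np.delete(X, coi, axis=1)
    pinvZ = np.linalg.pinv(Z)
    fitZ = Z @ (pinvZ @ Y)
    RzY = Y - fitZ

    B1 = draws.shape[0]
    out = np.empty((B1, V))
    if scheme.method == "sign_flip":
        out[:] = _signflip_t(fitZ, RzY, draws, X, coi, direction)
    else:
        for start in range(0, B1, batch_size):
            d = draws[start : start + batch_size]
            Ystar = fitZ[None] + RzY[d]
            out[start : start + d.shape[0]] = _oriented_t(Ystar, X, coi, direction)
    # the identity iteration must reproduce the observed statistic exactly
    out[0] = _oriented_t(Y, X, coi, direction)
    return out


def _signflip_t(
    fitZ: np.ndarray, R: np.ndarray, signs: np.ndarray, X: np.ndarray,
    coi: int, direction: str,
) -> np.ndarray:
    """All sign-flip t-maps at once without materializing permuted data.

    With Y*_b = F + s_b ∘ R (F the nuisance fit, R its residuals, s_b the
    sign vector), every ingredient of the t statistic is linear or
    quadratic in s_b with (s_b)^2 = 1, so the whole distribution reduces
    to a handful of (B, n) x (n, V) matrix products.
    """
    n, p = X.shape
    pinv_c = np.linalg.pinv(X)[coi]
    xtx_inv_cc = float(np.linalg.inv(X.T @ X)[coi, coi])
    Q = np.linalg.qr(X)[0]
    s = signs.astype(float)

    beta_c = (pinv_c @ fitZ)[None, :] + (s * pinv_c[None, :]) @ R
    QtF = Q.T @ fitZ  # (p, V)
    ss_fit = np.zeros((s.shape[0], R.shape[1]))
    for j in range(p):
        ss_fit += (QtF[j][None, :] + (s * Q[:, j][None, :]) @ R) ** 2
    ss_tot = (
        np.einsum("jv,jv->v", fitZ, fitZ)[None, :]
        + np.einsum("jv,jv->v", R, R)[None, :]
        + 2.0 * (s @ (fitZ * R))
    )
    sigma2 = np.maximum(ss_tot - ss_fit, 0.0) / (n - p)
    se = np.sqrt(np.maximum(sigma2 * xtx_inv_cc, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta_c / se
    t = np.where(se > 0, t, 0.0)
    return -t if direction == "less" else t


def partial_pvalues(observed: np.ndarray, permuted: np.ndarray) -> np.ndarray:
    """One-sided permutation p: ``(1 + #{t_b >= t_obs}) / (1 + B)``.

    ``permuted`` holds the B non-identity permutation statistics (rows).
    Ties count against the observed statistic (>= comparison), keeping
    the estimate conservative and bounded away from zero.
    """
    observed = np.asarray(observed, float)
    permuted = np.asarray(permuted, float)
    if permuted.shape[0] < 1:
        raise ValueError("need at least one permutation beyond the identity")
    count = (permuted >= observed[None]).sum(axis=0)
    return (1.0 + count) / (1.0 + permuted.shape[0])
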