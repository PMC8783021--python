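"""Voxelwise nonparametric combination (NPC), TFCE and FWE control.

The union-intersection logic: each voxel carries six partial t statistics
(from :mod:`npcpipe.permglm`) whose synchronized permutation
distributions are available.  Within each permutation, every partial t is
converted to a p-value by ranking it inside its own submodel's full
permutation distribution at that voxel; the six p-values are combined
with Fisher's function ``T = -2 * sum(log p)``.  Because the partial
tests share one permutation sequence, the permutation distribution of T
preserves their dependence.

Cluster-level inference: each permutation's combined map is enhanced with
threshold-free cluster enhancement (TFCE) and family-wise error is
controlled by the max-statistic over the mask; clusters of FWE-corrected
p <= alpha are reported with extent and peak location.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import rankdata

__all__ = [
    "TfceParams",
    "NpcResult",
    "fisher_combine",
    "npc_joint",
    "tfce",
    "fwe_correct",
    "cluster_report",
    "npc_analysis",
]

_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class TfceParams:
    """TFCE integration parameters (volumetric defaults E=0.5, H=2)."""

    E: float = 0.5
    H: float = 2.0
    dh: float | None = None  # None -> max / n_steps per map
    connectivity: int = 26
    n_steps: int = 100  # threshold count used when dh is None

    def __post_init__(self) -> None:
        if self.E <= 0 or self.H <= 0 or (self.dh is not None and self.dh <= 0):
            raise ValueError("E, H and dh must be positive")
        if self.connectivity not in _STRUCTS:
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.n_steps < 1:
            raise ValueError("n_steps must be at least 1")


@dataclass
class NpcResult:
    combined: np.ndarray  # observed Fisher T map (grid)
    enhanced: np.ndarray  # observed TFCE map (grid)
    p_fwe: np.ndarray  # FWE-corrected p map (grid, 1 outside mask)
    clusters: pd.DataFrame
    mask: np.ndarray
    n_perm: int
    alpha: float = 0.05


def fisher_combine(p: np.ndarray, axis: int = 0) -> np.ndarray:
    """Fisher's combining function ``T = -2 * sum_k log(p_k)``."""
    p = np.asarray(p, float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return -2.0 * np.log(p).sum(axis=axis)


def npc_joint(partial_tmaps: list[np.ndarray]) -> np.ndarray:
    """Combine synchronized partial t-map stacks into Fisher T per permutation.

    Each element of ``partial_tmaps`` is a (B, V) stack (identity first)
    from one submodel, all driven by the same permutation scheme.  For
    each submodel the within-permutation p at a voxel is the fraction of
    the submodel's own B statistics that are >= the current one (ranked
    against the full distribution, so values lie in [1/B, 1]).  Returns a
    (B, V) stack of combined statistics; row 0 is the observed map.
    """
    if len(partial_tmaps) == 0:
        raise ValueError("no partial tests to combine")
    shapes = {t.shape for t in partial_tmaps}
    if len(shapes) != 1:
        raise ValueError("partial t-map stacks are not synchronized (shape mismatch)")
    B = partial_tmaps[0].shape[0]
    T = np.zeros_like(partial_tmaps[0], dtype=float)
    for t in partial_tmaps:
        # rank 'min' gives 1 + #{strictly less}; #{>=} = B - rank + 1
        r = rankdata(t, axis=0, method="min")
        p = (B - r + 1.0) / B
        T -= 2.0 * np.log(p)
    return T


def tfce(stat_map: np.ndarray, params: TfceParams | None = None,
         mask: np.ndarray | None = None) -> np.ndarray:
    """Threshold-free cluster enhancement of a 3D statistic map.

    Discrete integral over thresholds h = dh, 2dh, ... <= max: each voxel
    accumulates ``extent(component containing it)**E * h**H * dh`` where
    extent is the size of the connected supra-threshold component.
    Non-positive input values receive 0.
    """
    params = params or TfceParams()
    m = np.asarray(stat_map, float)
    if mask is not None:
        m = np.where(mask, m, 0.0)
    if not np.all(np.isfinite(m)):
        raise ValueError("non-finite values in statistic map")
    out = np.zeros_like(m)
    vmax = m.max()
    if vmax <= 0:
        return out
    dh = params.dh if params.dh is not None else vmax / params.n_steps
    struct = _STRUCTS[params.connectivity]
    # integer stepping avoids float-accumulation drift dropping the last step
    n_steps = int(np.floor(vmax / dh + 1e-9))
    if n_steps == 0:
        return out
    # supra-threshold sets are nested, so we can shrink to the bounding box
    # of the current set before labelling -- at high thresholds this is tiny
    supra0 = m >= dh
    if not supra0.any():
        return out
    box = tuple(slice(lo, hi + 1) for lo, hi in _bbox(supra0))
    sub = np.ascontiguousarray(m[box])
    acc = np.zeros_like(sub)
    labels = np.empty(sub.shape, dtype=np.int32)
    for k in range(1, n_steps + 1):
        h = k * dh
        supra = sub >= h
        n = ndimage.label(supra, structure=struct, output=labels)
        if n == 0:
            break
        sizes = np.bincount(labels.ravel())
        contrib = sizes.astype(float) ** params.E * (h**params.H * dh)
        contrib[0] = 0.0
        acc += contrib[labels]
        # shrink only when the supra set became markedly smaller
        n_supra = sub.size - sizes[0]
        if n_supra < sub.size // 2 and k < n_steps:
            out[box] += acc
            inner = tuple(slice(lo, hi + 1) for lo, hi in _bbox(supra))
            box = tuple(
                slice(b.start + i.start, b.start + i.stop)
                for b, i in zip(box, inner)
            )
            sub = np.ascontiguousarray(sub[inner])
            acc = np.zeros_like(sub)
            labels = np.empty(sub.shape, dtype=np.int32)
    out[box] += acc
    return out


def _bbox(binary: np.ndarray):
    """Per-axis (lo, hi) index bounds of the True region (assumed non-empty)."""
    bounds = []
    for ax in range(binary.ndim):
        other = tuple(a for a in range(binary.ndim) if a != ax)
        proj = binary.any(axis=other)
        nz = np.flatnonzero(proj)
        bounds.append((int(nz[0]), int(nz[-1])))
    return bounds


def fwe_correct(
    enhanced_observed: np.ndarray,
    perm_max: np.ndarray,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Max-statistic FWE-corrected p-map.

    ``perm_max`` holds, per permutation (identity included as its first
    entry), the maximum enhanced statistic over the mask.  The corrected
    p at a voxel is the fraction of permutations whose max is >= the
    voxel's observed enhanced value; with the identity included this is
    the (1 + b) / (1 + B) estimator and can never be zero.
    """
    perm_max = np.sort(np.asarray(perm_max, float))
    B = perm_max.size
    obs = np.asarray(enhanced_observed, float)
    # count of perm_max >= value  ==  B - #(perm_max < value)
    counts = B - np.searchsorted(perm_max, obs, side="left")
    p = counts / B
    p = np.asarray(p, float)
    if mask is not None:
        p = np.where(mask, p, 1.0)
    return p


def cluster_report(
    p_map: np.ndarray,
    alpha: float = 0.05,
    connectivity: int = 26,
    voxel_size: float = 2.0,
) -> pd.DataFrame:
    """Connected components of {p <= alpha}: extent, min p, peak location.

    Clusters are sorted by extent (largest first).  Peak = voxel with the
    smallest corrected p (first in scan order on ties); coordinates are
    reported both as voxel indices and in mm (index * voxel size).
    """
    sig = np.asarray(p_map) <= alpha
    labels, n = ndimage.label(sig, structure=_STRUCTS[connectivity])
    rows = []
    for idx in range(1, n + 1):
        where = labels == idx
        extent = int(where.sum())
        pvals = np.where(where, p_map, np.inf)
        peak_flat = int(np.argmin(pvals))
        peak = np.unravel_index(peak_flat, p_map.shape)
        rows.append(
            {
                "extent": extent,
                "max_stat_p": float(p_map[peak]),
                "peak_x": int(peak[0]),
                "peak_y": int(peak[1]),
                "peak_z": int(peak[2]),
                "peak_x_mm": peak[0] * voxel_size,
                "peak_y_mm": peak[1] * voxel_size,
                "peak_z_mm": peak[2] * voxel_size,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "extent",
            "max_stat_p",
            "peak_x",
            "peak_y",
            "peak_z",
            "peak_x_mm",
            "peak_y_mm",
            "peak_z_mm",
        ],
    )
    df = df.sort_values("extent", ascending=False).reset_index(drop=True)
    df.insert(0, "cluster_index", np.arange(1, len(df) + 1))
    return df


def npc_analysis(
    partial_tmaps: list[np.ndarray],
    mask: np.ndarray,
    tfce_params: TfceParams | None = None,
    alpha: float = 0.05,
    voxel_size: float = 2.0,
) -> NpcResult:
    """Full voxel-level NPC: combine, enhance, FWE-correct, report.

    ``partial_tmaps``: synchronized (B, V) stacks over in-mask voxels.
    TFCE of every permutation's combined map feeds the max-statistic
    null; the observed (identity) map is corrected against it.
    """
    tfce_params = tfce_params or TfceParams()
    T = npc_joint(partial_tmaps)
    B, V = T.shape
    if V != int(mask.sum()):
        raise ValueError("t-map voxel count does not match mask")
    grid = np.zeros(mask.shape)

    # a common dh across permutations keeps the max-statistic comparable
    dh = tfce_params.dh
    if dh is None:
        dh = max(T.max() / tfce_params.n_steps, np.finfo(float).tiny)
        tfce_params = TfceParams(
            E=tfce_params.E, H=tfce_params.H, dh=dh,
            connectivity=tfce_params.connectivity, n_steps=tfce_params.n_steps,
        )

    perm_max = np.empty(B)
    enhanced_obs = None
    for b in range(B):
        grid[:] = 0.0
        grid[mask] = T[b]
        enh = tfce(grid, tfce_params)
        perm_max[b] = enh[mask].max() if V else 0.0
        if b == 0:
            enhanced_obs = enh.copy()

    p_fwe = fwe_correct(enhanced_obs, perm_max)
    p_fwe = np.where(mask, p_fwe, 1.0)
    clusters = cluster_report(
        p_fwe, alpha=alpha, connectivity=tfce_params.connectivity,
        voxel_size=voxel_size,
    )
    combined_grid = np.zeros(mask.shape)
    combined_grid[mask] = T[0]
    return NpcResult(
        combined=combined_grid,
        enhanced=enhanced_obs,
        p_fwe=p_fwe,
        clusters=clusters,
        mask=mask,
        n_perm=B - 1,
        alpha=alpha,
    )
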