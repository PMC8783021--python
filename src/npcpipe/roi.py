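"""ROI construction, feature extraction, ALFF and repeated-measures
correlation -- the bridge between voxel-level results and ROI analyses.

Follow-up analyses average modality values (i) inside significant
clusters and (ii) inside 10-mm spheres around cluster peaks restricted
to gray matter (probability >= 0.2).  Resting-state amplitude of
low-frequency fluctuations (ALFF, 0.01-0.08 Hz) is computed from the
single-sided amplitude spectrum.  Structure-function coupling across
intervals is quantified with the repeated-measures correlation: the
common within-unit association from an ANCOVA with unit as factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .change import ImageStack

__all__ = [
    "RoiMask",
    "RmcorrResult",
    "sphere_roi",
    "extract_roi_mean",
    "mean_over_intervals",
    "alff",
    "rmcorr",
]


@dataclass
class RoiMask:
    mask: np.ndarray  # boolean grid
    provenance: str  # "cluster" or "sphere"
    peak_mm: tuple[float, float, float] | None = None
    radius_mm: float | None = None
    gm_threshold: float | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, bool)
        if not self.mask.any():
            raise ValueError("ROI mask is empty")


def sphere_roi(
    peak_mm: tuple[float, float, float],
    gm_prob: np.ndarray,
    radius_mm: float = 10.0,
    gm_threshold: float = 0.2,
    voxel_size: float = 2.0,
) -> RoiMask:
    """Sphere of ``radius_mm`` around a peak, intersected with gray matter.

    A voxel belongs to the ROI when its center lies within the Euclidean
    radius of the peak (mm coordinate = index * voxel size) AND its gray
    matter probability is >= ``gm_threshold``.  Raises if the
    intersection is empty.
    """
    if radius_mm <= 0:
        raise ValueError("radius must be positive")
    gm_prob = np.asarray(gm_prob, float)
    peak = np.asarray(peak_mm, float)
    shape = gm_prob.shape
    extents = (np.array(shape) - 1) * voxel_size
    if np.any(peak < 0) or np.any(peak > extents):
        raise ValueError("peak coordinate outside the grid")
    grids = np.meshgrid(
        *[np.arange(s) * voxel_size for s in shape], indexing="ij"
    )
    dist2 = sum((g - c) ** 2 for g, c in zip(grids, peak))
    mask = (dist2 <= radius_mm**2) & (gm_prob >= gm_threshold)
    if not mask.any():
        raise ValueError(
            "sphere/gray-matter intersection is empty "
            f"(peak {tuple(peak)}, radius {radius_mm} mm, GM >= {gm_threshold})"
        )
    return RoiMask(
        mask=mask,
        provenance="sphere",
        peak_mm=tuple(peak),
        radius_mm=radius_mm,
        gm_threshold=gm_threshold,
    )


def extract_roi_mean(stack: ImageStack, roi: RoiMask | np.ndarray) -> np.ndarray:
    """Per-subject arithmetic mean over in-ROI voxels."""
    m = roi.mask if isinstance(roi, RoiMask) else np.asarray(roi, bool)
    if m.shape != stack.grid_shape:
        raise ValueError("ROI grid does not match the image stack")
    inside = m & stack.mask
    if not inside.any():
        raise ValueError("ROI does not intersect the analysis mask")
    return stack.data[:, inside].mean(axis=1)


def mean_over_intervals(values: np.ndarray) -> np.ndarray:
    """Elementwise mean across the interval axis.

    ``values`` is (n_intervals, n_subjects) -- e.g. residualized change
    extracted at each learning interval; the result is one averaged
    change score per subject.
    """
    v = np.atleast_2d(np.asarray(values, float))
    return v.mean(axis=0)


def alff(
    series: np.ndarray, tr_seconds: float, band: tuple[float, float] = (0.01, 0.08)
) -> np.ndarray:
    """Amplitude of low-frequency fluctuations over a closed frequency band.

    The series mean is removed, the single-sided amplitude spectrum
    ``2|F_k|/n`` computed, and the mean amplitude over bins with
    ``band[0] <= f <= band[1]`` returned.  Accepts (..., n_samples)
    arrays and returns one scalar per leading index.
    """
    if tr_seconds <= 0:
        raise ValueError("TR must be positive")
    x = np.asarray(series, float)
    n = x.shape[-1]
    if n < 64:
        raise ValueError("need at least 64 samples for a stable spectrum")
    nyquist = 0.5 / tr_seconds
    if band[1] > nyquist + 1e-12:
        raise ValueError(f"band upper edge {band[1]} Hz above Nyquist {nyquist:.4g}")
    if n * tr_seconds < 2.0 / max(band[0], 1e-12):
        warnings.warn("series shorter than two cycles of the band's lower edge")
    xd = x - x.mean(axis=-1, keepdims=True)
    amp = 2.0 * np.abs(np.fft.rfft(xd, axis=-1)) / n
    freqs = np.fft.rfftfreq(n, d=tr_seconds)
    sel = (freqs >= band[0] - 1e-12) & (freqs <= band[1] + 1e-12)
    if not sel.any():
        raise ValueError("no frequency bins inside the band")
    return amp[..., sel].mean(axis=-1)


@dataclass
class RmcorrResult:
    r: float
    df: int
    p: float
    slope: float
    n_units: int
    n_obs: int


def rmcorr(units: np.ndarray, x: np.ndarray, y: np.ndarray) -> RmcorrResult:
    """Repeated-measures correlation (common within-unit association).

    Equivalent to an ANCOVA of y on x with unit as a factor:
    ``r_rm = sign(slope) * sqrt(SS_x / (SS_x + SS_error))`` with
    ``df = N - n_units - 1``; computationally this is the Pearson
    correlation of the within-unit centered x and y.  Units with
    constant x carry no information about the slope and are dropped
    with a warning.
    """
    units = np.asarray(units)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if not (units.shape == x.shape == y.shape):
        raise ValueError("units, x and y must be equal-length vectors")
    uniq = np.unique(units)
    if uniq.size < 2:
        raise ValueError("need at least 2 units")
    keep = np.ones(x.size, bool)
    for u in uniq:
        sel = units == u
        if sel.sum() < 3:
            raise ValueError(f"unit {u!r} has fewer than 3 observations")
        if np.allclose(x[sel], x[sel][0]):
            warnings.warn(f"unit {u!r} has constant x; dropped")
            keep &= ~sel
    units, x, y = units[keep], x[keep], y[keep]
    uniq = np.unique(units)
    if uniq.size < 2:
        raise ValueError("fewer than 2 usable units after dropping")

    xc = x.copy()
    yc = y.copy()
    for u in uniq:
        sel = units == u
        xc[sel] -= x[sel].mean()
        yc[sel] -= y[sel].mean()
    sxx = xc @ xc
    syy = yc @ yc
    sxy = xc @ yc
    slope = sxy / sxx
    ss_x = sxy**2 / sxx
    ss_err = syy - ss_x
    r = np.sign(slope) * np.sqrt(ss_x / (ss_x + ss_err)) if syy > 0 else 0.0
    df = x.size - uniq.size - 1
    if df <= 0:
        raise ValueError("not enough observations for inference")
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r**2))
        p = 2.0 * stats.t.sf(abs(t), df)
    return RmcorrResult(
        r=float(r), df=int(df), p=float(p), slope=float(slope),
        n_units=int(uniq.size), n_obs=int(x.size),
    )
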