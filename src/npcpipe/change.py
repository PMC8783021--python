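"""Per-voxel change quantities feeding all downstream inference.

Longitudinal voxelwise analyses should not work on raw follow-up images:
regression to the mean couples apparent "change" to the baseline value.
The standard remedy is the residualized change score -- the residual of a
per-voxel regression of follow-up on baseline across subjects -- which is
mean-zero and uncorrelated with baseline by construction.  ROI-level
follow-up analyses instead use simple percentage change from baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["ImageStack", "ChangeMap", "residualized_change", "percent_change"]


@dataclass
class ImageStack:
    """Subjects x 3D-grid values for one modality at one timepoint.

    Parameters
    ----------
    data : ndarray, shape (n_subjects, nx, ny, nz)
    mask : boolean ndarray, shape (nx, ny, nz)
        Analysis mask shared by all subjects.
    modality : str
        e.g. ``"FA"``, ``"RD"`` (radial diffusivity), ``"ALFF"``.
    timepoint : str
        e.g. ``"MRI_1"`` ... ``"MRI_5"``.
    voxel_size : float
        Isotropic voxel edge length in mm (identity orientation).
    """

    data: np.ndarray
    mask: np.ndarray
    modality: str = "FA"
    timepoint: str = "MRI_1"
    voxel_size: float = 2.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise ValueError("data must be (n_subjects, nx, ny, nz)")
        if self.mask.shape != self.data.shape[1:]:
            raise ValueError("mask shape does not match image grid")
        if not np.all(np.isfinite(self.data[:, self.mask])):
            raise ValueError("non-finite values inside the analysis mask")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.data.shape[1:]

    def masked(self) -> np.ndarray:
        """Return (n_subjects, n_in_mask_voxels) view of in-mask data."""
        return self.data[:, self.mask]

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size
        return aff

    def to_nifti(self) -> nib.Nifti1Image:
        # subject axis last, the conventional 4D layout
        return nib.Nifti1Image(np.moveaxis(self.data, 0, -1), self.affine)

    @classmethod
    def from_nifti(cls, path, mask, **kw) -> "ImageStack":
        img = nib.load(str(path))
        data = np.moveaxis(np.asarray(img.dataobj, dtype=float), -1, 0)
        vs = float(img.header.get_zooms()[0])
        return cls(data=data, mask=mask, voxel_size=vs, **kw)


@dataclass
class ChangeMap:
    """Subjects x grid change scores between two timepoints."""

    data: np.ndarray
    mask: np.ndarray
    baseline: str
    followup: str
    kind: str = "residualized"  # or "percent"
    standardized: bool = False
    modality: str = "FA"
    voxel_size: float = 2.0
    flagged_voxels: np.ndarray = field(default_factory=lambda: np.zeros(0, int))

    def masked(self) -> np.ndarray:
        return self.data[:, self.mask]


def residualized_change(
    baseline: ImageStack, followup: ImageStack, standardize: bool = False
) -> ChangeMap:
    """Residualized change: per-voxel OLS of follow-up on baseline.

    For every voxel, follow-up values across subjects are regressed on
    baseline values (with intercept); the residuals are the change scores.
    Voxels with a constant baseline cannot support the regression; there
    the residual degenerates to the deviation from the follow-up mean and
    the voxel is flagged.

    Parameters
    ----------
    standardize : bool
        If True, z-score the residuals across subjects per voxel, so maps
        are in SD units.
    """
    if baseline.grid_shape != followup.grid_shape or not np.array_equal(
        baseline.mask, followup.mask
    ):
        raise ValueError("baseline and follow-up stacks must share geometry and mask")
    if baseline.n_subjects != followup.n_subjects:
        raise ValueError("subject count mismatch")
    n = baseline.n_subjects
    if n < 3:
        raise ValueError("residualized change needs at least 3 subjects")

    b = baseline.masked()
    f = followup.masked()
    bc = b - b.mean(axis=0)
    fc = f - f.mean(axis=0)
    var_b = np.einsum("sv,sv->v", bc, bc)
    degenerate = var_b <= n * np.finfo(float).eps * np.maximum(1.0, np.abs(b).max())
    cov = np.einsum("sv,sv->v", bc, fc)
    slope = np.where(degenerate, 0.0, cov / np.where(degenerate, 1.0, var_b))
    resid = fc - slope * bc

    if standardize:
        sd = resid.std(axis=0, ddof=1)
        resid = np.divide(resid, sd, out=np.zeros_like(resid), where=sd > 0)

    out = np.zeros_like(followup.data)
    out[:, followup.mask] = resid
    return ChangeMap(
        data=out,
        mask=followup.mask.copy(),
        baseline=baseline.timepoint,
        followup=followup.timepoint,
        kind="residualized",
        standardized=standardize,
        modality=followup.modality,
        voxel_size=followup.voxel_size,
        flagged_voxels=np.flatnonzero(degenerate),
    )


def percent_change(baseline: np.ndarray, followup: np.ndarray) -> np.ndarray:
    """100 * (follow-up - baseline) / baseline, elementwise.

    Entries with non-positive baseline are undefined and returned as NaN;
    callers are expected to mask (and log) them.
    """
    b = np.asarray(baseline, dtype=float)
    f = np.asarray(followup, dtype=float)
    bad = b <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        pc = 100.0 * (f - b) / b
    pc = np.where(bad, np.nan, pc)
    return pc
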