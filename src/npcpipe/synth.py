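"""Synthetic two-arm longitudinal studies with known ground truth.

Emulates the design the inference machinery targets: a treatment arm
(cardiovascular exercise, n=15 by default) and an inactive control arm
(n=16) with age/sex covariates; six weekly training sessions of 15
balance trials following a power-law learning curve whose exponent is
shifted in the treatment arm; five-timepoint image stacks (MRI_1
baseline, MRI_2 post-intervention, MRI_3..MRI_5 during learning) for
diffusion-like modalities, containing planted clusters whose change from
baseline differs by group with either an *immediate-persistent* or a
*gradually emerging* trajectory and is optionally correlated with
concurrent behavioral change; and resting time series whose low-frequency
amplitude declines over timepoints in the treatment arm.

Everything is driven by a master seed through a spawned-stream hierarchy,
so adding a component never perturbs the draws of another and identical
specs reproduce bit-identical studies.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .behavior import TrialSeries, percent_change_behavior, session_means
from .change import ImageStack

__all__ = [
    "CohortSpec",
    "ClusterSpec",
    "EffectSpec",
    "SyntheticStudy",
    "simulate_cohort",
    "simulate_learning_curves",
    "simulate_image_stacks",
    "simulate_resting_series",
    "simulate_mediation_dataset",
    "simulate_study",
    "write_study",
]

TIMEPOINTS = ["MRI_1", "MRI_2", "MRI_3", "MRI_4", "MRI_5"]
# learning-phase MRI sessions paired with the training session completed
# just before them (MRI_3 follows TS_2, MRI_4 follows TS_4, MRI_5 follows TS_6)
MRI_TO_SESSION = {"MRI_3": 2, "MRI_4": 4, "MRI_5": 6}
_BASELINE_MEAN = {"FA": 0.45, "RD": 0.70, "ALFF": 1.0}


@dataclass
class CohortSpec:
    n_treatment: int = 15
    n_control: int = 16
    age_range: tuple[float, float] = (18.0, 35.0)
    sex_balance: float = 0.5  # proportion female per arm
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_treatment < 2 or self.n_control < 2:
            raise ValueError("arm sizes n_treatment and n_control must be >= 2")
        if not self.age_range[0] < self.age_range[1]:
            raise ValueError("age_range must satisfy min < max")
        if not 0.0 <= self.sex_balance <= 1.0:
            raise ValueError("sex_balance must lie in [0, 1]")


@dataclass
class ClusterSpec:
    modality: str
    center: tuple[int, int, int]  # voxel indices
    radius: float  # voxels
    trajectory: str = "immediate_persistent"  # or "gradual"
    direction: int = 1  # +1 increase, -1 decrease in treatment arm
    group_effect_size: float = 1.0  # SD units of the change noise
    behavior_coupling: float = 0.0  # correlation with behavioral change

    def __post_init__(self) -> None:
        if self.trajectory not in ("immediate_persistent", "gradual"):
            raise ValueError(
                "trajectory must be 'immediate_persistent' or 'gradual'"
            )
        if self.radius < 1:
            raise ValueError("cluster radius must be >= 1 voxel")
        if abs(self.behavior_coupling) >= 1:
            raise ValueError("|behavior_coupling| must be < 1")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")


@dataclass
class EffectSpec:
    behavior_slope_shift: float = 0.5  # SD units on the learning exponent
    cluster_specs: list[ClusterSpec] = field(default_factory=list)
    mediation_paths: tuple[float, ...] = (0.5, 0.5, 0.4, 0.4, 0.3)  # a1,a2,b1,b2,c'
    noise_sd: dict[str, float] = field(default_factory=dict)
    alff_drop: float = 0.2  # fractional in-band amplitude drop, treatment arm

    def noise_for(self, modality: str) -> float:
        return self.noise_sd.get(modality, 1.0)

    def modalities(self) -> list[str]:
        seen: list[str] = []
        for c in self.cluster_specs:
            if c.modality not in seen:
                seen.append(c.modality)
        return seen


def default_effects() -> EffectSpec:
    """The study conditions the generator mirrors: a gradually-emerging FA
    increase in one region and an immediate-persistent radial-diffusivity
    decrease in another, both ~1 SD and moderately behavior-coupled."""
    return EffectSpec(
        behavior_slope_shift=0.5,
        cluster_specs=[
            ClusterSpec("FA", (3, 3, 3), 2.0, "gradual", +1, 1.0, 0.4),
            ClusterSpec("RD", (8, 8, 8), 2.0, "immediate_persistent", -1, 1.0, -0.4),
        ],
    )


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Cohort table: subject, group (control=0 / treatment=1), age, sex.

    Ages are uniform over the range; female counts per arm match the
    requested balance as closely as integer counts allow (sex coded
    female=1).
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.master_seed).spawn(1)[0])
    rows = []
    sid = 0
    for group, n in ((0, spec.n_control), (1, spec.n_treatment)):
        ages = rng.uniform(*spec.age_range, size=n)
        n_female = int(round(spec.sex_balance * n))
        sexes = np.zeros(n, int)
        sexes[:n_female] = 1
        rng.shuffle(sexes)
        for i in range(n):
            sid += 1
            rows.append((f"sub-{sid:03d}", group, float(ages[i]), int(sexes[i])))
    return pd.DataFrame(rows, columns=["subject", "group", "age", "sex"])


def simulate_learning_curves(
    cohort: pd.DataFrame,
    effect: EffectSpec,
    sessions: int = 6,
    trials: int = 15,
    seed=0,
    a_mean: float = 4.5,
    a_sd: float = 0.8,
    b_mean: float = 0.35,
    b_sd: float = 0.10,
    online_slope: float = 0.08,
    trial_noise_sd: float = 1.5,
) -> TrialSeries:
    """Power-law learning curves with a group-shifted exponent.

    Each subject draws scale a ~ N(a_mean, a_sd) (truncated positive) and
    exponent b ~ N(b_mean + shift*b_sd*group, b_sd); the expected session
    mean is a * s**b.  Trials add a mean-centered within-session linear
    trend (so session means are exact when noise is zero) plus Gaussian
    trial noise, and are clipped to the 0-30 s trial window.
    """
    if sessions < 2 or trials < 2:
        raise ValueError("need at least 2 sessions and 2 trials")
    rng = _rng(seed)
    shift = effect.behavior_slope_shift
    recs = []
    tgrid = np.arange(1, trials + 1)
    tcent = tgrid - tgrid.mean()
    for _, subj in cohort.iterrows():
        a = max(rng.normal(a_mean, a_sd), 0.5)
        b = rng.normal(b_mean + shift * b_sd * subj["group"], b_sd)
        for s in range(1, sessions + 1):
            mu = a * s**b
            noise = (
                rng.normal(0.0, trial_noise_sd, size=trials)
                if trial_noise_sd > 0
                else np.zeros(trials)
            )
            bal = np.clip(mu + online_slope * tcent + noise, 0.0, 30.0)
            for t, v in zip(tgrid, bal):
                recs.append((subj["subject"], s, int(t), float(v)))
    return TrialSeries(
        pd.DataFrame(recs, columns=["subject", "session", "trial", "bal"])
    )


def _smooth_unit_noise(rng, shape, sigma) -> np.ndarray:
    """Gaussian random field with unit marginal variance."""
    w = rng.standard_normal(shape)
    if sigma <= 0:
        return w
    sm = gaussian_filter(w, sigma, mode="constant")
    imp = np.zeros([min(s, int(8 * sigma) * 2 + 1) for s in shape])
    imp[tuple(s // 2 for s in imp.shape)] = 1.0
    k = gaussian_filter(imp, sigma, mode="constant")
    return sm / np.sqrt((k**2).sum())


def _cluster_mask(shape, center, radius) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius**2


def simulate_image_stacks(
    cohort: pd.DataFrame,
    effect: EffectSpec,
    behavior_change: np.ndarray | None = None,
    grid_shape: tuple[int, int, int] = (12, 12, 12),
    voxel_size: float = 2.0,
    fwhm_vox: float = 2.0,
    baseline_sd: float = 0.05,
    seed=0,
    modalities: list[str] | None = None,
) -> tuple[dict, dict, list]:
    """Five-timepoint image stacks per modality plus ground-truth masks.

    Baselines are smooth random fields around modality-typical means.
    Later timepoints add unit-variance (smoothed) change noise scaled by
    the modality noise SD; inside each planted cluster the change
    additionally carries the group effect -- full from MRI_2 onward for
    *immediate_persistent* clusters, ramping linearly from 0 at MRI_2 to
    full at MRI_5 for *gradual* ones -- and, if requested, a component
    proportional to the subject's (z-scored) behavioral change, giving
    the target change-behavior correlation in expectation.

    ``behavior_change``: (n_subjects, 4) scores for MRI_2..MRI_5 (the
    MRI_2 column is typically zero: no learning has happened yet).

    Returns ``(stacks, truth_masks, cluster_masks)`` where ``stacks`` maps
    modality -> {timepoint: ImageStack}.
    """
    rng = _rng(seed)
    n = len(cohort)
    group = cohort["group"].to_numpy(float)
    sigma = fwhm_vox / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    mask = np.ones(grid_shape, bool)

    if modalities is None:
        modalities = effect.modalities() or ["FA"]
    for c in effect.cluster_specs:
        cm = _cluster_mask(grid_shape, c.center, c.radius)
        if not cm.any():
            raise ValueError(f"cluster at {c.center} covers no voxels")
        lo = np.array(c.center) - c.radius
        hi = np.array(c.center) + c.radius
        if np.any(lo < 0) or np.any(hi > np.array(grid_shape) - 1):
            raise ValueError(
                f"cluster at {c.center} (radius {c.radius}) exceeds the grid"
            )

    if behavior_change is None:
        behavior_change = np.zeros((n, 4))
    behavior_change = np.asarray(behavior_change, float)
    if behavior_change.shape != (n, 4):
        raise ValueError("behavior_change must be (n_subjects, 4) for MRI_2..MRI_5")
    zb = np.zeros_like(behavior_change)
    for j in range(4):
        col = behavior_change[:, j]
        sd = col.std(ddof=1)
        if sd > 0:
            zb[:, j] = (col - col.mean()) / sd

    stacks: dict[str, dict[str, ImageStack]] = {}
    truth: dict[str, np.ndarray] = {}
    cluster_masks: list[tuple[ClusterSpec, np.ndarray]] = []
    for mod in modalities:
        nsd = effect.noise_for(mod)
        base_mean = _BASELINE_MEAN.get(mod, 0.0)
        baseline = np.stack(
            [
                base_mean + baseline_sd * _smooth_unit_noise(rng, grid_shape, sigma)
                for _ in range(n)
            ]
        )
        mod_clusters = [c for c in effect.cluster_specs if c.modality == mod]
        union = np.zeros(grid_shape, bool)
        masks_c = []
        for c in mod_clusters:
            cm = _cluster_mask(grid_shape, c.center, c.radius)
            union |= cm
            masks_c.append(cm)
            cluster_masks.append((c, cm))
        truth[mod] = union

        per_tp = {"MRI_1": ImageStack(baseline, mask, mod, "MRI_1", voxel_size)}
        for j, tp in enumerate(TIMEPOINTS[1:]):  # j = 0..3 for MRI_2..MRI_5
            eta = np.stack(
                [_smooth_unit_noise(rng, grid_shape, sigma) for _ in range(n)]
            )
            change = eta.copy()
            for c, cm in zip(mod_clusters, masks_c):
                lam = c.behavior_coupling
                coupled = lam * zb[:, j][:, None] + np.sqrt(1 - lam**2) * eta[:, cm]
                change[:, cm] = coupled
                ramp = 1.0 if c.trajectory == "immediate_persistent" else j / 3.0
                amp = c.direction * c.group_effect_size * ramp
                change[:, cm] += amp * group[:, None]
            data = baseline + nsd * change
            per_tp[tp] = ImageStack(data, mask, mod, tp, voxel_size)
        stacks[mod] = per_tp
    return stacks, truth, cluster_masks


def simulate_resting_series(
    cohort: pd.DataFrame,
    effect: EffectSpec,
    n_timepoints: int = 5,
    tr_seconds: float = 1.4,
    n_samples: int = 420,
    n_voxels: int = 16,
    amplitude: float = 1.0,
    noise_sd: float = 0.5,
    in_band_freqs: tuple[float, ...] = (0.02, 0.04, 0.06),
    seed=0,
) -> np.ndarray:
    """Resting time series (n_subjects, n_timepoints, n_voxels, n_samples).

    Each series is a sum of in-band sinusoids with random phases plus
    white noise.  In the treatment arm the in-band amplitude declines
    linearly across timepoints by ``effect.alff_drop`` (fraction of the
    baseline amplitude at the final timepoint); controls stay flat.
    """
    if tr_seconds <= 0:
        raise ValueError("TR must be positive")
    if n_samples * tr_seconds < 3 / 0.01:
        warnings.warn(
            "series covers fewer than 3 cycles of 0.01 Hz; ALFF will be noisy"
        )
    rng = _rng(seed)
    n = len(cohort)
    group = cohort["group"].to_numpy(float)
    t = np.arange(n_samples) * tr_seconds
    out = np.empty((n, n_timepoints, n_voxels, n_samples))
    for i in range(n):
        for tp in range(n_timepoints):
            frac = tp / max(n_timepoints - 1, 1)
            amp = amplitude * (1.0 - effect.alff_drop * frac * group[i])
            phases = rng.uniform(0, 2 * np.pi, size=(n_voxels, len(in_band_freqs)))
            sig = sum(
                amp * np.sin(2 * np.pi * f * t[None, :] + phases[:, [k]])
                for k, f in enumerate(in_band_freqs)
            )
            out[i, tp] = sig + rng.normal(0, noise_sd, size=(n_voxels, n_samples))
    return out


def simulate_mediation_dataset(
    n_treatment: int = 15,
    n_control: int = 16,
    a: tuple[float, ...] = (0.5,),
    b: tuple[float, ...] = (0.4,),
    c_prime: float = 0.0,
    with_covariates: bool = True,
    seed=0,
):
    """Dataset with planted mediation paths (unit error SDs).

    ``M_j = a_j X + e`` and ``Y = c' X + sum_j b_j M_j + e`` with
    standard-normal errors and binary X, so the planted specific indirect
    effects are exactly ``a_j * b_j`` on the generative scale (fit with
    ``standardize=False`` to recover them).  Optional age/sex covariates
    are independent of everything (true coefficients zero).
    """
    if len(a) != len(b):
        raise ValueError("a and b path tuples must have equal length")
    rng = _rng(seed)
    x = np.concatenate([np.zeros(n_control), np.ones(n_treatment)])
    n = x.size
    k = len(a)
    M = np.empty((n, k))
    for j in range(k):
        M[:, j] = a[j] * x + rng.standard_normal(n)
    y = c_prime * x + M @ np.asarray(b, float) + rng.standard_normal(n)
    cov = None
    if with_covariates:
        age = rng.uniform(18, 35, size=n)
        sex = rng.integers(0, 2, size=n).astype(float)
        cov = np.column_stack([age, sex])
    return x, M, y, cov


@dataclass
class SyntheticStudy:
    cohort: pd.DataFrame
    trials: TrialSeries
    stacks: dict  # modality -> {timepoint: ImageStack}
    truth_masks: dict  # modality -> boolean grid
    cluster_masks: list  # (ClusterSpec, boolean grid) pairs
    resting: np.ndarray | None
    resting_tr: float
    cohort_spec: CohortSpec
    effect_spec: EffectSpec

    def behavior_change_for_imaging(self) -> np.ndarray:
        """(n, 4) percentage DBT change from TS_1 aligned to MRI_2..MRI_5
        (zero at MRI_2: the scan precedes learning)."""
        means = session_means(self.trials)
        pc = percent_change_behavior(means, reference_session=1)
        order = self.cohort["subject"].tolist()
        out = np.zeros((len(order), 4))
        for j, tp in enumerate(["MRI_3", "MRI_4", "MRI_5"], start=1):
            out[:, j] = pc[MRI_TO_SESSION[tp]].loc[order].to_numpy()
        return out


def simulate_study(
    cohort_spec: CohortSpec | None = None,
    effect_spec: EffectSpec | None = None,
    grid_shape: tuple[int, int, int] = (12, 12, 12),
    voxel_size: float = 2.0,
    with_resting: bool = False,
    resting_kwargs: dict | None = None,
    **image_kwargs,
) -> SyntheticStudy:
    """Generate a complete synthetic study from a master seed.

    The master seed spawns independent child streams for cohort,
    behavior, images and resting series, so components are mutually
    independent and individually reproducible.
    """
    cohort_spec = cohort_spec or CohortSpec()
    effect_spec = effect_spec if effect_spec is not None else default_effects()
    ss = np.random.SeedSequence(cohort_spec.master_seed)
    s_cohort, s_behav, s_img, s_rest = ss.spawn(4)
    cohort = simulate_cohort(cohort_spec)
    trials = simulate_learning_curves(
        cohort, effect_spec, seed=np.random.default_rng(s_behav)
    )
    study = SyntheticStudy(
        cohort=cohort,
        trials=trials,
        stacks={},
        truth_masks={},
        cluster_masks=[],
        resting=None,
        resting_tr=1.4,
        cohort_spec=cohort_spec,
        effect_spec=effect_spec,
    )
    behavior_change = study.behavior_change_for_imaging()
    stacks, truth, cmasks = simulate_image_stacks(
        cohort,
        effect_spec,
        behavior_change=behavior_change,
        grid_shape=grid_shape,
        voxel_size=voxel_size,
        seed=np.random.default_rng(s_img),
        **image_kwargs,
    )
    study.stacks, study.truth_masks, study.cluster_masks = stacks, truth, cmasks
    if with_resting:
        kw = resting_kwargs or {}
        study.resting = simulate_resting_series(
            cohort, effect_spec, seed=np.random.default_rng(s_rest), **kw
        )
        study.resting_tr = kw.get("tr_seconds", 1.4)
    return study


def write_study(study: SyntheticStudy, outdir) -> None:
    """Write cohort/trials as CSV, images and truth masks as NIfTI, and a
    JSON sidecar with the full spec and seed record."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    study.cohort.to_csv(out / "cohort.csv", index=False)
    study.trials.table.to_csv(out / "trials.csv", index=False)
    for mod, per_tp in study.stacks.items():
        for tp, stack in per_tp.items():
            nib.save(stack.to_nifti(), out / f"{mod}_{tp}.nii")
        aff = per_tp["MRI_1"].affine
        nib.save(
            nib.Nifti1Image(study.truth_masks[mod].astype(np.uint8), aff),
            out / f"truth_{mod}.nii",
        )
    sidecar = {
        "cohort_spec": {
            "n_treatment": study.cohort_spec.n_treatment,
            "n_control": study.cohort_spec.n_control,
            "age_range": list(study.cohort_spec.age_range),
            "sex_balance": study.cohort_spec.sex_balance,
            "master_seed": study.cohort_spec.master_seed,
        },
        "effect_spec": {
            "behavior_slope_shift": study.effect_spec.behavior_slope_shift,
            "alff_drop": study.effect_spec.alff_drop,
            "clusters": [
                {
                    "modality": c.modality,
                    "center": list(c.center),
                    "radius": c.radius,
                    "trajectory": c.trajectory,
                    "direction": c.direction,
                    "group_effect_size": c.group_effect_size,
                    "behavior_coupling": c.behavior_coupling,
                }
                for c in study.effect_spec.cluster_specs
            ],
        },
    }
    (out / "study.json").write_text(json.dumps(sidecar, indent=2))
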