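"""Synthetic-study generator: determinism, planted-parameter recovery."""

import numpy as np
import pytest

from npcpipe.behavior import fit_power_curve, session_means
from npcpipe.change import ImageStack
from npcpipe.roi import alff
from npcpipe.synth import (
    ClusterSpec,
    CohortSpec,
    EffectSpec,
    simulate_cohort,
    simulate_image_stacks,
    simulate_learning_curves,
    simulate_resting_series,
    simulate_study,
    write_study,
)


# ------------------------------------------------------------ simulate_cohort
def test_cohort_validation():
    with pytest.raises(ValueError, match="arm sizes"):
        CohortSpec(n_treatment=0, n_control=5)
    with pytest.raises(ValueError, match="age_range"):
        CohortSpec(age_range=(35, 18))
    with pytest.raises(ValueError, match="sex_balance"):
        CohortSpec(sex_balance=1.5)


def test_cohort_deterministic_and_counts():
    spec = CohortSpec(n_treatment=15, n_control=16, master_seed=7)
    c1 = simulate_cohort(spec)
    c2 = simulate_cohort(spec)
    assert c1.equals(c2)
    assert (c1.group == 1).sum() == 15
    assert (c1.group == 0).sum() == 16
    # female counts per arm: round(0.5 * n)
    assert c1[c1.group == 1]["sex"].sum() == round(0.5 * 15)
    assert c1[c1.group == 0]["sex"].sum() == round(0.5 * 16)
    ages = c1["age"]
    assert ages.between(18, 35).all()


# --------------------------------------------------- simulate_learning_curves
def test_learning_curves_noiseless_closed_form():
    cohort = simulate_cohort(CohortSpec(3, 3, master_seed=1))
    eff = EffectSpec(behavior_slope_shift=0.0)
    series = simulate_learning_curves(
        cohort, eff, seed=0, a_sd=0.0, b_sd=0.0, a_mean=5.0, b_mean=0.3,
        trial_noise_sd=0.0,
    )
    means = session_means(series)
    s = np.arange(1, 7)
    expected = 5.0 * s**0.3
    for subj in means.index:
        assert means.loc[subj].to_numpy() == pytest.approx(expected, abs=1e-10)


def test_learning_curves_slope_shift_recovery():
    # standardized arm difference in fitted exponents recovers the shift
    shift = 0.8
    diffs = []
    for seed in range(60):
        cohort = simulate_cohort(CohortSpec(15, 16, master_seed=seed))
        eff = EffectSpec(behavior_slope_shift=shift)
        series = simulate_learning_curves(cohort, eff, seed=seed, trial_noise_sd=0.0)
        fits = fit_power_curve(session_means(series))
        b = fits.params["b"]
        g = cohort.set_index("subject")["group"]
        diffs.append((b[g == 1].mean() - b[g == 0].mean()) / 0.10)
    assert abs(np.mean(diffs) - shift) < 0.15


def test_learning_curves_null_shift_centered():
    diffs = []
    for seed in range(40):
        cohort = simulate_cohort(CohortSpec(12, 12, master_seed=seed))
        series = simulate_learning_curves(
            cohort, EffectSpec(behavior_slope_shift=0.0), seed=seed,
            trial_noise_sd=0.0,
        )
        fits = fit_power_curve(session_means(series))
        b = fits.params["b"]
        g = cohort.set_index("subject")["group"]
        diffs.append(b[g == 1].mean() - b[g == 0].mean())
    se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
    assert abs(np.mean(diffs)) < 3 * se + 1e-9


def test_learning_curves_bounds_and_validation(rng):
    cohort = simulate_cohort(CohortSpec(4, 4, master_seed=3))
    series = simulate_learning_curves(cohort, EffectSpec(), seed=1)
    bal = series.table["bal"]
    assert bal.between(0, 30).all()
    with pytest.raises(ValueError, match="at least 2"):
        simulate_learning_curves(cohort, EffectSpec(), sessions=1)


# ----------------------------------------------------------------- ClusterSpec
def test_cluster_spec_validation():
    with pytest.raises(ValueError, match="trajectory"):
        ClusterSpec("FA", (3, 3, 3), 2.0, trajectory="linear")
    with pytest.raises(ValueError, match="behavior_coupling"):
        ClusterSpec("FA", (3, 3, 3), 2.0, behavior_coupling=1.0)
    with pytest.raises(ValueError, match="radius"):
        ClusterSpec("FA", (3, 3, 3), 0.5)
    with pytest.raises(ValueError, match="direction"):
        ClusterSpec("FA", (3, 3, 3), 2.0, direction=2)


# ------------------------------------------------------- simulate_image_stacks
def cohort_and_effect(n=24, seed=0, **cluster_kw):
    cohort = simulate_cohort(CohortSpec(n // 2, n - n // 2, master_seed=seed))
    kw = dict(modality="FA", center=(5, 5, 5), radius=2.0,
              group_effect_size=1.0)
    kw.update(cluster_kw)
    eff = EffectSpec(cluster_specs=[ClusterSpec(**kw)])
    return cohort, eff


def test_image_stacks_cluster_exceeds_grid():
    cohort, eff = cohort_and_effect(center=(9, 9, 9), radius=2.0)
    with pytest.raises(ValueError, match="exceeds the grid"):
        simulate_image_stacks(cohort, eff, grid_shape=(10, 10, 10))


def test_image_stacks_complete_null_centered():
    diffs = []
    for seed in range(30):
        cohort = simulate_cohort(CohortSpec(10, 10, master_seed=seed))
        eff = EffectSpec(cluster_specs=[])
        stacks, truth, _ = simulate_image_stacks(
            cohort, eff, grid_shape=(6, 6, 6), seed=seed, modalities=["FA"]
        )
        g = cohort["group"].to_numpy() == 1
        change = stacks["FA"]["MRI_5"].data - stacks["FA"]["MRI_1"].data
        diffs.append(change[g].mean() - change[~g].mean())
        assert not truth["FA"].any()
    se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
    assert abs(np.mean(diffs)) < 3 * se + 1e-9


def _cluster_group_diff(stacks, truth, cohort, tp):
    g = cohort["group"].to_numpy() == 1
    change = stacks["FA"][tp].data - stacks["FA"]["MRI_1"].data
    vals = change[:, truth["FA"]].mean(axis=1)
    return vals[g].mean() - vals[~g].mean()


def test_immediate_persistent_full_from_mri2():
    d2, d5 = [], []
    for seed in range(40):
        cohort, eff = cohort_and_effect(
            seed=seed, trajectory="immediate_persistent", direction=1
        )
        stacks, truth, _ = simulate_image_stacks(
            cohort, eff, grid_shape=(12, 12, 12), seed=seed
        )
        d2.append(_cluster_group_diff(stacks, truth, cohort, "MRI_2"))
        d5.append(_cluster_group_diff(stacks, truth, cohort, "MRI_5"))
    se2 = np.std(d2, ddof=1) / np.sqrt(len(d2))
    se5 = np.std(d5, ddof=1) / np.sqrt(len(d5))
    assert abs(np.mean(d2) - 1.0) < 3 * se2
    assert abs(np.mean(d5) - 1.0) < 3 * se5


def test_gradual_ramp():
    d2, d5 = [], []
    for seed in range(40):
        cohort, eff = cohort_and_effect(seed=seed, trajectory="gradual")
        stacks, truth, _ = simulate_image_stacks(
            cohort, eff, grid_shape=(12, 12, 12), seed=seed
        )
        d2.append(_cluster_group_diff(stacks, truth, cohort, "MRI_2"))
        d5.append(_cluster_group_diff(stacks, truth, cohort, "MRI_5"))
    se2 = np.std(d2, ddof=1) / np.sqrt(len(d2))
    se5 = np.std(d5, ddof=1) / np.sqrt(len(d5))
    assert abs(np.mean(d2)) < 3 * se2  # no effect yet at MRI_2
    assert abs(np.mean(d5) - 1.0) < 3 * se5  # full effect at MRI_5


def test_behavior_coupling_correlation():
    rng = np.random.default_rng(0)
    lam = 0.6
    rs = []
    for seed in range(25):
        cohort, eff = cohort_and_effect(
            n=40, seed=seed, behavior_coupling=lam, group_effect_size=0.0
        )
        beh = np.zeros((40, 4))
        beh[:, 1:] = rng.normal(size=(40, 3))
        stacks, truth, _ = simulate_image_stacks(
            cohort, eff, behavior_change=beh, grid_shape=(12, 12, 12), seed=seed
        )
        change = stacks["FA"]["MRI_5"].data - stacks["FA"]["MRI_1"].data
        vals = change[:, truth["FA"]].mean(axis=1)
        rs.append(np.corrcoef(vals, beh[:, 3])[0, 1])
    # in-cluster change correlates with behavior near the planted level
    # (spatial averaging over the smooth field raises it slightly above lam)
    assert abs(np.mean(rs) - lam) < 0.2


# ----------------------------------------------------- simulate_resting_series
def test_resting_alff_drop_recovery():
    cohort = simulate_cohort(CohortSpec(12, 12, master_seed=5))
    eff = EffectSpec(alff_drop=0.2)
    series = simulate_resting_series(cohort, eff, seed=3, noise_sd=0.05)
    vals = alff(series, 1.4).mean(axis=2)  # (n, timepoints)
    pc = 100 * (vals[:, -1] - vals[:, 0]) / vals[:, 0]
    g = cohort["group"].to_numpy() == 1
    assert np.mean(pc[g]) == pytest.approx(-20.0, abs=3.0)
    assert abs(np.mean(pc[~g])) < 3.0


def test_resting_null_centered():
    cohort = simulate_cohort(CohortSpec(8, 8, master_seed=2))
    eff = EffectSpec(alff_drop=0.0)
    series = simulate_resting_series(cohort, eff, seed=1, noise_sd=0.05)
    vals = alff(series, 1.4).mean(axis=2)
    pc = 100 * (vals[:, -1] - vals[:, 0]) / vals[:, 0]
    g = cohort["group"].to_numpy() == 1
    assert abs(np.mean(pc[g]) - np.mean(pc[~g])) < 3.0


# -------------------------------------------------------------- simulate_study
def test_study_bit_identical():
    s1 = simulate_study(CohortSpec(4, 4, master_seed=11), EffectSpec(), grid_shape=(8, 8, 8),
                        with_resting=True)
    s2 = simulate_study(CohortSpec(4, 4, master_seed=11), EffectSpec(), grid_shape=(8, 8, 8),
                        with_resting=True)
    assert s1.cohort.equals(s2.cohort)
    assert s1.trials.table.equals(s2.trials.table)
    for mod in s1.stacks:
        for tp in s1.stacks[mod]:
            assert np.array_equal(s1.stacks[mod][tp].data, s2.stacks[mod][tp].data)
    assert np.array_equal(s1.resting, s2.resting)


def test_study_component_independence():
    # adding the resting component must not perturb image or behavior draws
    a = simulate_study(CohortSpec(4, 4, master_seed=13), EffectSpec(), grid_shape=(8, 8, 8),
                       with_resting=False)
    b = simulate_study(CohortSpec(4, 4, master_seed=13), EffectSpec(), grid_shape=(8, 8, 8),
                       with_resting=True)
    assert a.trials.table.equals(b.trials.table)
    for mod in a.stacks:
        for tp in a.stacks[mod]:
            assert np.array_equal(a.stacks[mod][tp].data, b.stacks[mod][tp].data)


def test_behavior_change_for_imaging_layout():
    study = simulate_study(CohortSpec(4, 4, master_seed=3), EffectSpec(), grid_shape=(8, 8, 8))
    bc = study.behavior_change_for_imaging()
    assert bc.shape == (8, 4)
    assert (bc[:, 0] == 0).all()  # MRI_2 precedes learning


def test_write_study_roundtrip(tmp_path):
    study = simulate_study(CohortSpec(3, 3, master_seed=9), EffectSpec(), grid_shape=(8, 8, 8))
    write_study(study, tmp_path)
    assert (tmp_path / "cohort.csv").exists()
    assert (tmp_path / "study.json").exists()
    stack = study.stacks["FA"]["MRI_1"]
    back = ImageStack.from_nifti(
        tmp_path / "FA_MRI_1.nii", stack.mask, modality="FA", timepoint="MRI_1"
    )
    assert back.data == pytest.approx(stack.data)
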