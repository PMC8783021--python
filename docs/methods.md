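# Methods

This document describes the statistical model implemented by `npcpipe`, the
choices behind its defaults, and the scope of the synthetic-data generator.
It is written so that every number produced by the package can be traced to a
formula on this page.

## 1. Study design being modelled

The package targets a two-arm longitudinal training study:

- Two groups (treatment, control) of roughly equal size (defaults 15 and 16).
- A dynamic balance task practised over six training sessions; each session
  contains repeated trials scored as time-in-balance (BAL) on a 0–30 s scale.
- Five imaging visits: `MRI_1` and `MRI_2` before training starts, then
  `MRI_3`, `MRI_4`, `MRI_5` interleaved with training (after sessions 2, 4
  and 6 respectively). The three learning intervals analysed voxelwise are
  `MRI_1→MRI_3`, `MRI_1→MRI_4`, `MRI_1→MRI_5`.
- Optional graded exercise testing (GXT) with power and lactate readings, and
  optional resting-state series for ALFF.

## 2. Behavioral metrics (`npcpipe.behavior`)

**Session means.** Mean BAL per subject and session on the complete
subject × session × trial grid (validated on construction).

**Learning curves.** Session means are fit per subject with a two-parameter
power law `BAL(s) = a·s^b` by nonlinear least squares, initialised from the
log–log linear fit. The exponent `b` is the learning-rate parameter.

**Baseline adjustment.** Any per-subject score can be residualized on
baseline performance (ordinary least squares with intercept); this removes
the component linearly predictable from where a subject started. With fewer
than 3 subjects the adjustment is undefined and the adjusted column is NaN
(with a warning) rather than an error.

**Online learning.** Within-session trial slopes from a linear fit of BAL on
trial index.

**Retention.** Between consecutive sessions `i-1` and `i`:
`retention = 100 · initial(TS_i) / final(TS_{i-1}) − 100`, where *initial* is
the mean of the first two trials of the later session and *final* the mean of
the last two trials of the earlier one. Zero means perfect carry-over; the
score is a pure ratio and therefore invariant to rescaling of BAL.

## 3. Fitness indices (`npcpipe.fitness`)

**PWC (physical working capacity).** Power at a fixed heart-rate target by
linear interpolation of the observed power–heart-rate curve
(optionally normalized by body mass). Extrapolation outside the observed
range is refused; non-monotone heart-rate profiles warn and use the first
crossing.

**Lactate indices.** A cubic polynomial is fit to lactate vs. power over at
least four stages. `P3` is the power at 3 mmol/l (root-finding on the fitted
curve); the individual anaerobic threshold (IAT) is the power at
baseline + 1.5 mmol/l, where baseline is the fitted minimum (fallback: first
stage). A curve that never crosses the target is an error, not a NaN.

## 4. Change maps (`npcpipe.change`)

Two change definitions are provided per voxel:

- **Residualized change**: follow-up residualized on baseline across
  subjects (OLS with intercept), standardized to unit variance. Voxels with
  constant baseline are flagged and fall back to deviation-from-mean.
- **Percent change**: `100·(follow − base)/base`, NaN when the baseline is
  non-positive.

Residualized change is what enters the voxelwise GLMs; percent change is
used for ROI summaries where the raw scale is meaningful.

## 5. Voxelwise permutation GLMs (`npcpipe.permglm`)

Each modality contributes six partial tests — for each of the three learning
intervals: (i) a group ANCOVA (group effect on change, adjusting for age and
sex) and (ii) a brain–behavior regression (change on baseline-adjusted
percent behavioral improvement over the matching interval).

Inference is by the Freedman–Lane procedure: the design is split into the
coefficient of interest and nuisance; residuals from the nuisance-only fit
are sign-flipped (or label-shuffled) and the full model refit. For
sign-flipping the permuted t-statistics are computed in closed form — with
`Y* = F + s∘R` and `s² = 1`, the coefficient and both sums of squares are
linear/quadratic in `s`, so the whole (B+1)-permutation t-stack reduces to
three matrix products and no permuted data is ever materialized. Row 0 of
every permutation stack is the identity (observed) statistic, computed
exactly.

A `PermutationScheme` object draws and caches the permutations once, so all
six submodels (and all modalities analysed under the same scheme) see
*synchronized* permutations — the requirement for nonparametric combination.

## 6. Nonparametric combination, TFCE and FWE (`npcpipe.npc`)

Per submodel and voxel, within-permutation p-values are computed by ranking
each column of the t-stack (`p = (B − rank + 1)/B`, minimum rank for ties).
The six p-streams are combined per permutation with Fisher's statistic
`T = −2·Σ ln p`, yielding a combined statistic map per permutation.

Each combined map is enhanced with **TFCE**
(`TFCE(v) = Σ_h extent(v,h)^E · h^H · dh`, defaults `E=0.5`, `H=2`,
26-connectivity). The discrete sum uses `n_steps` equal-height steps up to
the map maximum (default 100). Integer step indexing avoids floating-point
drift; the implementation labels components with `scipy.ndimage` and was
verified against an independent pure-Python flood-fill oracle to 1e-8.

**FWE correction** is by the max-statistic method: the null distribution of
the image-wide maximum TFCE value over permutations (identity included)
gives `p_FWE(v) = #{max_b ≥ TFCE(v)}/(B+1)`. This controls the family-wise
error rate exactly for any fixed enhancement transform, which is also why
the step count is a runtime knob and not a validity knob. Significant voxels
are reported as connected clusters with extents and peak coordinates (voxel
indices and millimetres).

## 7. Rank-based interval battery (`npcpipe.ranknpc`)

ROI summaries (percent change in the FWE-significant region per interval)
are compared between groups with a **studentized Wilcoxon** statistic: Welch
t computed on pooled mid-ranks. P-values come from label permutation
(exhaustive when the group sizes permit, Monte Carlo otherwise; the identity
is always included, `p = count/total`).

Multiplicity over the k ≤ 6 intervals is handled by **closed testing**: all
2^k−1 intersection hypotheses are tested with Fisher-combined permutation
p-streams, and the adjusted p of interval `i` is the maximum over all
intersections containing `i`. The global test is the full intersection. This
controls the FWER strongly without independence assumptions, because all
subsets share the same synchronized permutations.

Effect sizes are **Cliff's delta** with a consistent-variance asymmetric
confidence interval and the conventional magnitude labels
(|d| < 0.147 negligible, < 0.33 small, < 0.474 medium, else large).

## 8. Mediation (`npcpipe.mediation`)

A parallel-mediator model with binary treatment `x`, mediators `M_j` (ROI
change summaries), outcome `y` (baseline-adjusted learning rate) and optional
covariates:

- `M_j = i_j + a_j·x + Γ·cov + e_j`
- `y = i + c′·x + Σ b_j·M_j + Γ'·cov + e`

Point estimates are OLS; standard errors are heteroskedasticity-consistent
(HC3, via statsmodels). The decomposition `c = c′ + Σ a_j b_j` holds exactly
in OLS and is asserted to 1e-10. Indirect-effect uncertainty is by
percentile case-resampling bootstrap (default ≥ 1000 draws; degenerate
resamples are redrawn). The bootstrap is vectorized over draws via normal
equations in blocks.

## 9. ROI features (`npcpipe.roi`)

- **Sphere ROI**: all voxels within a radius (mm) of a peak coordinate,
  intersected with a grey-matter mask at a threshold.
- **ALFF**: mean single-sided spectral amplitude (`2|FFT|/n`) in
  0.01–0.08 Hz by default; requires ≥ 64 samples and a band below Nyquist.
  The amplitude convention is calibrated: a pure sinusoid of amplitude A
  returns exactly A in a narrow band at its frequency, and the spectrum
  satisfies Parseval's identity.
- **rmcorr**: repeated-measures correlation — the common within-subject
  association after removing between-subject offsets (ANCOVA with subject
  intercepts), `df = n_obs − n_units − 1`. Cross-checked against pingouin.

## 10. Synthetic-data generator (`npcpipe.synth`)

All randomness flows from one `master_seed` through a `SeedSequence` spawn
hierarchy, so components are independently reproducible: adding the
resting-state block does not perturb the imaging or behavioral draws.

- **Cohort**: group labels, ages uniform in a range, balanced sex per arm.
- **Behavior**: per-subject power-law curves (`a ~ N(4.5, 0.8)`,
  `b ~ N(0.35, 0.10)`), a group shift on the exponent (default +0.5 SD),
  within-session linear trial improvement, trial noise, clipped to [0, 30].
- **Images**: smoothed Gaussian noise fields plus spherical clusters with a
  chosen trajectory — `immediate_persistent` (full effect from `MRI_2`
  onward) or `gradual` (linear ramp reaching full effect at `MRI_5`) — a
  group effect size in noise-SD units, and optional coupling λ to the
  behavioral change score (`λ·z_behavior + √(1−λ²)·noise`).
- **Resting series**: band-limited oscillations whose in-band amplitude
  drops by a configurable fraction in the treatment arm at the last visit.
- **Mediation datasets**: binary x, mediators and outcome with planted
  `a`, `b`, `c′` paths on the generative scale.

The generator makes no attempt to mimic real MRI physics (no field
inhomogeneity, motion, or spatial covariance beyond Gaussian smoothing); it
exists to give the statistical machinery data with known ground truth.

## 11. Problem sizes and defaults

Grids of 12×12×12 voxels, 31 subjects, 250–1000 permutations and 2000
bootstrap draws are the package's own demonstration scale, chosen so the
full pipeline runs in seconds on one CPU while every statistical property
(calibration, coverage, exactness) is already testable. All sizes scale up
by changing configuration only; the permutation engine is O(B·n·V) with
BLAS-bound constants.

## 12. Numerical choices

- QR-based projections for residual sums of squares (no explicit hat
  matrices).
- Ranking with the minimum-rank convention for ties; permutation p-values
  always include the identity, so they are never zero and are exact under
  exchangeability.
- TFCE with integer step indexing; bounding-box shrinking when the
  supra-threshold set contracts.
- Bootstrap linear algebra by blocked normal equations with a tiny ridge
  for numerical safety; degenerate resamples (constant x) are redrawn.

## 13. Limitations

- The voxelwise engine holds the full (B+1)×V t-stacks in memory; at the
  demonstration scale this is a few hundred MB at most, but very large
  grids would need chunking.
- Closed testing is limited to k ≤ 6 intervals (2^k−1 subsets).
- Path-based (on-disk) pipeline input is limited to the individual CLI
  subcommands; the end-to-end `run-all` pipeline currently runs from the
  built-in generator.
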