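# Methods

This note documents the models, conventions and numerical choices behind
`fatomics`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Image model and conventions

Volumes are NIfTI scalar grids in Hounsfield units with physical spacing
read from the header; the third array axis is axial with slice index
increasing toward the head. A CT and its masks must be grid-congruent
(identical shape, spacing within 10⁻³ mm); resampling is deliberately out
of scope, so a mismatch is an input error, not something to silently fix.
Adipose tissue is defined by the closed HU window **[−190, −30]**, the same
span the HU-bin features tile; when no precomputed EAT mask is supplied,
the EAT mask is the thresholded CT restricted to the pericardial sac.
Volumes are reported in cm³, thicknesses in mm.

## Ray-cast thickness field

Rays leave the unweighted centroid of the sac mask in every direction of a
spherical grid: azimuth θ ∈ {0°, …, 359°} in the axial plane and polar
angle φ ∈ {0°, …, 179°} from +z, i.e. 360 × 180 = 64,800 rays at the
default 1° step, covering the full sphere. Each ray is sampled at a fixed
arc step of **0.25 × min(spacing)** — small enough that a shell one voxel
thick cannot be stepped over — with voxel membership by nearest-voxel
lookup, and terminates at its first sample outside the sac or the grid.
Per-ray thickness is the Euclidean distance between the first and last
sample whose voxel is EAT, so interposed non-fat gaps are *included*
(first-to-last reading). Rays that meet no fat score 0 and are **kept** in
the field; consequently every field holds exactly (360/step)·(180/step)
measurements and the fixed histogram [0,8), [8,16), [16,24), [24,32] mm
(last bin closed, values above 32 mm folded into it and counted) always
conserves the ray count. Excluding zero rays is available as an analysis
choice upstream but is not the default.

Expected discretization error: each endpoint is located to within about
half a voxel diagonal, so per-ray error is bounded by one voxel diagonal
(≈ 2.55 mm at 0.5 × 0.5 × 2.5 mm). The phantom suite verifies both the
per-ray bound and sub-voxel accuracy of the field mean on a constant-shell
sphere, rotation robustness (< 2% mean shift), stability under sampling-
step refinement, and monotonicity in shell thickness.

Statistical conventions: moments use the population (biased) estimators;
kurtosis is *excess* kurtosis; a zero-variance field reports skewness and
kurtosis of 0 rather than NaN so degenerate subjects cannot poison a
feature table.

## Regional partitions

**Axial slabs (PQ1–PQ4).** The axial slices containing sac foreground are
split into four consecutive runs of near-equal count, PQ1 lowermost. When
the count is not divisible by four, the extra slices go to the *lower*
slabs (10 slices → 3, 3, 2, 2); the rule is arbitrary but deterministic and
covered by a z-flip symmetry test.

**Depth shells (SH1–SH4).** Each sac voxel's depth is its Euclidean
distance to the sac exterior computed with the anisotropic sampling of the
grid (at calcium-score geometry an index-space distance would distort
bands five-fold along z). With D the maximum depth, shell k collects
depths in ((k−1)D/4, kD/4], edge values assigned outward; SH1 is the
outermost ribbon. Shells are delineated on the **sac** and intersected
with the EAT mask, so the regional frame does not depend on fat sparsity.
Both partitions are exact: labels are disjoint and exhaustive over the
parent mask, asserted voxel-for-voxel.

Shell banding error is surface-dominated and shrinks roughly linearly with
spacing; the innermost band (smallest volume, largest surface-to-volume
ratio) carries the largest relative error at any practical grid. Tests
therefore check band volumes against the closed-form spherical values
within a boundary-area × voxel-diagonal tolerance and require monotone
error reduction under grid refinement, rather than a fixed percentage.

**Principal axes.** Directions are eigenvectors of the covariance of
foreground voxel centers (physical mm), ordered by descending eigenvalue;
the length of each axis is the projection extent (max − min), which is
parameter-free and directly comparable to caliper-style heart dimensions.
For near-spherical masks the eigenvectors are degenerate and the reported
directions arbitrary; lengths remain stable.

## Feature catalogue

The catalogue holds exactly **148** named features: 8 global morphology,
14 thickness, 30 global intensity, and 12 features for each of the eight
subregions (4 slabs + 4 shells). The headline feature names (`EAT_vol`,
`EAT_mean_HU`, `Thickness_Max`, `Vol_PQ4`, `Vol_50_30`, `Pro_50_30`,
`Thickness_Kurtosis`, …) are all present; the remainder fills the four
blocks symmetrically. HU bins follow the `Vol_<|lo|>_<|hi|>` convention
(`Vol_50_30` = cm³ of EAT with HU ∈ [−50, −30]); the 40-HU-wide bin family
is prefixed `Vol4_`/`Pro4_` to keep the two families disjoint. Bin edges
are right-open except the last; probabilities normalize by in-span region
volume, so they sum to 1 whenever the region lies inside the window.
`neg_skewness` is −1 × sample skewness: positive when HU mass piles toward
the high (inflammation-associated) end.

Degenerate regions produce documented values instead of NaN: an empty
subregion contributes zero volumes/fractions and zeroed moment features
with a per-feature missingness flag exported alongside the table. A
feature vector is validated to be exactly the 148 catalogue names, in
order, all finite.

## Synthetic data

**Phantoms.** The sac is an ellipsoid (semi-axes a ≥ b ≥ c mm) in an
air-valued background with soft-tissue interior (+40 HU). The fat shell is
defined *radially*: along direction (θ, φ) a voxel at radius r is fat iff
r_surf − t(θ, φ) < r ≤ r_surf, so a centered ray crosses exactly t mm of
fat — the ground truth the sweep must recover. t may be constant or an
angular function. A voxel belongs to a region iff its center does. Fat HU
is drawn from a truncated normal (default −100 ± 25 HU) or uniform
distribution supported inside [−190, −30]; optional Gaussian noise can be
added globally. Defaults emulate calcium-score acquisitions
(0.5 × 0.5 mm in-plane, 2.5 mm slices); tests use coarser grids where the
property under test permits, and the canonical spacing where it matters
(thickness recovery). What phantoms do **not** emulate: cardiac anatomy,
partial-volume blur, beam hardening, motion. Passing phantom tests
demonstrates geometric and statistical correctness of the operators, not
clinical validity on patient scans.

**Survival.** Event times follow an exponential-baseline proportional-
hazards model, T = −ln(U)/(λ₀·exp(xᵀβ)), with uniform censoring on
[0, T_max] (λ₀ = 0.1/yr, T_max = 6 yr by default, matching a several-year
follow-up horizon; `censor_tmax=inf` disables censoring for null studies).
Features are multivariate normal unless a phantom-derived table is
supplied. All randomness flows from a single integer seed.

The phantom-cohort generator used by the CLI ties hazard to standardized
fat volume and mean HU (β = 0.8 and 0.5 per SD) — the two canonical risk
drivers — with λ₀ = 0.25/yr to yield event rates appropriate for an
enriched cohort.

## Feature reduction and survival model

**mRMR (FCQ).** Greedy forward selection against the binary event
indicator: relevance is the one-way ANOVA F statistic, redundancy the mean
absolute Pearson correlation with the already-selected set, and the next
pick maximizes relevance/redundancy (first pick: max relevance). Constant
features are excluded with a warning. The event indicator (ignoring time)
is the supervision target; a survival-aware alternative (correlation with
a univariate Cox score) would slot into the same interface. Note a known
property of the quotient scheme: a perfect duplicate of a selected feature
retains score F/1 = F and can still outrank substantially weaker
candidates; redundancy penalization is decisive only among comparably
relevant features.

**Cox elastic net.** Features are standardized to zero mean/unit variance
inside `fit` (train-set parameters are reused at prediction time). The
glmnet-style penalty path is computed once on the full data; the penalty
weight is chosen by 10-fold cross-validation with folds stratified by
event status, scoring each held-out fold by its Breslow partial
log-likelihood under the train-fold model and maximizing the fold mean.
The mixing parameter defaults to α = 0.8. Alternatively a target support
size can be requested (e.g. 15), picking the path point whose nonzero
count is closest (ties toward the sparser model). Hazard ratios from the
standardized fit are per-SD.

**Evaluation.**

* *C-index*: Harrell's, event-anchored, risk-score ties 0.5; tied-time
  pairs with exactly one event are comparable, tied event times are not.
* *AIC*: −2·logPL + 2·k on an **unpenalized refit** of the selected
  support (AIC is undefined for a penalized partial likelihood). The refit
  uses a stabilization ladder — plain Newton, then ridge 10⁻⁶, 10⁻³,
  10⁻¹ — taking the first fit that converges; covariates constant in the
  given cohort are dropped as unidentifiable. k counts the requested
  features.
* *Time-dependent AUC*: cumulative/dynamic with inverse-probability-of-
  censoring weights from a Kaplan–Meier censoring estimate; default
  horizon 2 years. Equals the plain binary AUC when no censoring precedes
  the horizon.
* *Likelihood-ratio test*: 2·ΔlogPL against χ² with df = feature-count
  difference for nested models; non-nested comparisons report ΔlogPL only.
* *Categorical NRI*: two categories split at each model's own median;
  event status at the horizon via Kaplan–Meier within each
  reclassification cell, so early-censored subjects contribute through the
  product-limit weights instead of being dropped. NRI = NRI_event +
  NRI_nonevent by construction. Confidence intervals by seeded percentile
  bootstrap (default B = 1000, medians recomputed per resample); the
  p-value is a normal approximation from the bootstrap spread.
* *KM stratification*: median split of the risk score; per-stratum curves
  and restricted mean survival, log-rank p, and the between-group hazard
  ratio from a univariate Cox fit on the group indicator (a zero-event
  stratum yields a bound, flagged by warning).
* *Train/test*: 80/20 stratified by event status, seeded, preserving the
  event ratio; test-set evaluation reuses the training standardization.

## Problem sizes

Tests and the acceptance script run at desk scale: the thickness-recovery
phantom is the full r = 40 mm sphere at 0.5 × 0.5 × 2.5 mm with the
complete 64,800-ray sweep; catalogue-level tests use smaller phantoms with
coarser angular steps (the catalogue is step-independent in structure);
support recovery uses 20 cohorts of n = 500 with 5 true coefficients of 1
among 50 features; likelihood-ratio null calibration uses 200 simulations
at n = 80; the null AUC check uses n = 2000.

## Known limitations

* Segmentation is out of scope: the pericardium mask is an input, and the
  package's EAT definition is a pure HU threshold within it.
* The slab remainder rule and the shell edge-assignment rule are fixed
  conventions; other choices would shift subregion features slightly.
* The mRMR target ignores event times; features informative only through
  time-ordering within events may rank low at the reduction step.
* The NRI p-value is a bootstrap-normal approximation, adequate at the
  simulated sizes but approximate in tiny cohorts.
* Phantom realism ends at geometry and first-order intensity statistics;
  no claim is made about texture-level behavior on patient scans.
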