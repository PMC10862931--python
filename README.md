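# fatomics

Radiomic analysis of epicardial adipose tissue (EAT) from non-contrast,
calcium-score cardiac CT, coupled to time-to-event modeling of major adverse
cardiovascular events (MACE).

EAT — the fat enclosed by the pericardial sac — is in direct vascular
communication with the myocardium and coronary arteries, and inflamed fat
shifts toward higher CT attenuation. Simple summaries (total EAT volume,
mean HU, a single thickness) carry only weak prognostic signal. `fatomics`
instead computes a comprehensive, hand-crafted 148-feature "fat-omics"
catalogue per subject and feeds it to a penalized Cox survival model:

* **morphology** (8): EAT and sac volumes, EAT fraction, principal-axis
  lengths of the sac and their aspect ratios;
* **thickness** (14): a spherical ray sweep from the sac centroid — 360°
  azimuth × 180° polar at 1° steps = **64,800 rays** — measures per-ray EAT
  thickness as the Euclidean distance between the first and last fat voxel
  intersected; the field is summarized by moments and four fixed 8 mm
  histogram bins;
* **intensity** (30): HU moments over EAT (including negative skewness,
  which rises when mass piles toward high, inflammation-associated HU) and
  fixed HU bins tiling the adipose window [−190, −30] HU in 20-HU and 40-HU
  widths, as absolute volumes (`Vol_50_30` = cm³ of EAT in [−50, −30] HU)
  and probabilities (`Pro_50_30`);
* **spatial** (96): the sac is split into four equal axial slabs (PQ1
  bottom → PQ4 top) and four equidistant depth shells (SH1 outer → SH4
  inner, via an anisotropy-aware Euclidean distance transform); each
  subregion contributes volume, HU moments and 40-HU-bin volumes.

Modeling follows the fat-omics recipe: maximum-relevance minimum-redundancy
(mRMR, FCQ scheme) reduction 148 → 50, then a Cox proportional-hazards
model with elastic-net penalty (mixing α = 0.8, 10-fold cross-validated
penalty weight) selects the final feature subset. Models are judged by
Harrell's C-index, AIC of an unpenalized refit, per-feature hazard ratios,
IPCW time-dependent AUC at a 2-year horizon, likelihood-ratio tests,
categorical net reclassification improvement (NRI) with Kaplan–Meier-
adjusted proportions, and median-split Kaplan–Meier stratification.

Because no patient data ships with the package, a first-class synthetic
module generates ellipsoidal shell phantoms with known fat geometry/HU and
proportional-hazards survival cohorts with known coefficients, so every
stage is testable against ground truth.

## Worked example

A spherical "heart" phantom (sac radius 40 mm, constant 6 mm fat shell,
fat HU ~ truncated normal at −100 ± 25 HU) at calcium-score geometry
(0.5 × 0.5 mm in-plane, 2.5 mm slices):

```python
from fatomics import PhantomSpec, make_shell_phantom, derive_eat_mask, extract_features

spec = PhantomSpec(
    shape=(176, 176, 38), spacing=(0.5, 0.5, 2.5),
    semi_axes_mm=(40.0, 40.0, 40.0), thickness_mm=6.0,
    fat_hu=("truncnorm", -100.0, 25.0), seed=0,
)
ct, sac, truth = make_shell_phantom(spec)
eat = derive_eat_mask(ct, sac)                       # threshold [-190, -30] HU
fv = extract_features(ct, sac, eat, subject_id="phantom-01")

for name in ("EAT_vol", "Sac_vol", "EAT_mean_HU", "Thickness_Mean",
             "Thickness_Max", "Axis_Major", "Vol_PQ4", "Pro_50_30"):
    print(f"{name:16s} {fv.values[name]:10.3f}")
```

prints

```
EAT_vol             103.770
Sac_vol             268.320
EAT_mean_HU        -100.256
Thickness_Mean        5.899
Thickness_Max         8.125
Axis_Major           77.500
Vol_PQ4              23.948
Pro_50_30             0.020
```

Reading the numbers: the voxelized shell volume (103.8 cm³) sits within a
surface-voxel tolerance of the analytic 4/3·π·(40³ − 34³) = 103.4 cm³; the
ray-sweep mean (5.90 mm) recovers the true 6 mm shell to sub-voxel
accuracy, with `Thickness_Max` bounded by one voxel diagonal (≈ 2.55 mm at
this spacing); the mean HU matches the sampling distribution; the top slab
holds ≈ ¼ of the fat by symmetry; and ~2% of fat volume falls in the
highest HU bin, the tail of the −100 ± 25 HU distribution.

From the shell, `fatomics fit --features features.csv --surv survival.csv
--out report/` runs mRMR → elastic net → the full evaluation battery and
writes `model.json`, `report.json`, KM curves and the reclassification
table. `fatomics simulate --n 40 --out cohort/` builds a phantom cohort
end to end.

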