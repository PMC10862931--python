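"""The fat-omics feature catalogue: 148 named features per subject.

Features fall into four blocks:

* global morphology (8) — EAT and sac volumes, EAT fraction, principal-axis
  lengths of the sac and their aspect ratios;
* thickness (14) — moments of the 64,800-ray thickness field plus the four
  fixed 8 mm histogram bins, as counts (TB_*) and fractions (TF_*);
* global intensity (30) — HU moments over EAT (including the
  negative-skewness convention), the eight 20-HU-wide bins over
  [-190, -30] as volumes (Vol_190_170 .. Vol_50_30) and probabilities
  (Pro_*), and the four 40-HU-wide bins (Vol4_*, Pro4_*);
* subregions (96) — for each axial slab PQ1..PQ4 and radial shell SH1..SH4,
  twelve features: volume, volume fraction of total EAT, six HU moments and
  the four 40-HU bin volumes.

Slabs and shells are delineated on the pericardial sac and intersected
with the EAT mask, so the regional frame does not depend on fat sparsity.
Degenerate regions (no fat) yield 0 for every feature and raise a
missingness flag instead of NaN, keeping downstream penalized models fed.
Volumes are cm^3, thicknesses mm, HU dimensionless.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geometry, intensity, thickness as thickness_mod
from .io import ImageVolume, MaskVolume, check_congruent

__all__ = [
    "FeatureVector",
    "extract_features",
    "feature_dictionary",
    "feature_names",
    "extract_features_batch",
    "CATALOGUE_VERSION",
    "N_FEATURES",
]

CATALOGUE_VERSION = "1.0"
N_FEATURES = 148

SUBREGIONS = ("PQ1", "PQ2", "PQ3", "PQ4", "SH1", "SH2", "SH3", "SH4")

_BIN8 = intensity.bin_names(8)  # Vol_190_170 .. Vol_50_30
_BIN4 = intensity.bin_names(4)  # Vol_190_150 .. Vol_70_30
_BIN4_STEMS = [n.removeprefix("Vol_") for n in _BIN4]

_THICK_BINS = ("0_8", "8_16", "16_24", "24_32")


@dataclass(frozen=True)
class FeatureVector:
    """Ordered 148-entry feature map for one subject, with missingness flags."""

    subject_id: str
    values: dict[str, float]
    flags: dict[str, bool] = field(default_factory=dict)
    version: str = CATALOGUE_VERSION

    def __post_init__(self):
        expected = feature_names()
        if list(self.values) != expected:
            raise ValueError(
                f"feature vector must hold exactly the {N_FEATURES} catalogue names in order"
            )
        bad = [k for k, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite feature values: {bad}")

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, name=self.subject_id)


def feature_names() -> list[str]:
    """The catalogue's 148 feature names in canonical order."""
    names = [
        # global morphology (8)
        "EAT_vol",
        "Sac_vol",
        "EAT_fraction",
        "Axis_Major",
        "Axis_Intermediate",
        "Axis_Minor",
        "Aspect_Major_Minor",
        "Aspect_Major_Intermediate",
        # thickness (14)
        "Thickness_Mean",
        "Thickness_Max",
        "Thickness_Median",
        "Thickness_Std",
        "Thickness_Skewness",
        "Thickness_Kurtosis",
    ]
    names += [f"TB_{b}" for b in _THICK_BINS]
    names += [f"TF_{b}" for b in _THICK_BINS]
    # global intensity (30)
    names += [
        "EAT_HUmin",
        "EAT_HUmax",
        "EAT_mean_HU",
        "EAT_HUstd",
        "EAT_HU_NegSkewness",
        "EAT_HUkurtosis",
    ]
    names += _BIN8
    names += [n.replace("Vol_", "Pro_") for n in _BIN8]
    names += [f"Vol4_{s}" for s in _BIN4_STEMS]
    names += [f"Pro4_{s}" for s in _BIN4_STEMS]
    # subregions (12 x 8 = 96)
    for r in SUBREGIONS:
        names += [
            f"Vol_{r}",
            f"VolFrac_{r}",
            f"HUmean_{r}",
            f"HUmin_{r}",
            f"HUmax_{r}",
            f"HUstd_{r}",
            f"HU_NegSkew_{r}",
            f"HUkurt_{r}",
        ]
        names += [f"Vol4_{s}_{r}" for s in _BIN4_STEMS]
    assert len(names) == N_FEATURES
    return names


def feature_dictionary() -> pd.DataFrame:
    """Machine-readable dictionary: (name, category, units, definition)."""
    rows = []

    def add(name, category, units, definition):
        rows.append({"name": name, "category": category, "units": units, "definition": definition})

    add("EAT_vol", "morphology", "cm3", "total EAT volume (voxel count x voxel volume)")
    add("Sac_vol", "morphology", "cm3", "pericardial sac volume")
    add("EAT_fraction", "morphology", "1", "EAT_vol / Sac_vol")
    for ax in ("Major", "Intermediate", "Minor"):
        add(f"Axis_{ax}", "morphology", "mm", f"{ax.lower()} principal-axis extent of the sac; geometry.principal_axes")
    add("Aspect_Major_Minor", "morphology", "1", "Axis_Major / Axis_Minor")
    add("Aspect_Major_Intermediate", "morphology", "1", "Axis_Major / Axis_Intermediate")

    for stat in ("Mean", "Max", "Median", "Std", "Skewness", "Kurtosis"):
        add(f"Thickness_{stat}", "thickness", "mm" if stat in ("Mean", "Max", "Median", "Std") else "1",
            f"{stat.lower()} of the 64,800-ray thickness field; thickness.summarize_thickness")
    for b in _THICK_BINS:
        lo, hi = b.split("_")
        add(f"TB_{b}", "thickness", "rays", f"ray count with thickness in [{lo}, {hi}) mm (last bin closed)")
    for b in _THICK_BINS:
        lo, hi = b.split("_")
        add(f"TF_{b}", "thickness", "1", f"fraction of rays with thickness in [{lo}, {hi}) mm (last bin closed)")

    for nm, desc in (
        ("EAT_HUmin", "minimum HU over EAT voxels"),
        ("EAT_HUmax", "maximum HU over EAT voxels"),
        ("EAT_mean_HU", "mean HU over EAT voxels"),
        ("EAT_HUstd", "HU standard deviation over EAT voxels"),
        ("EAT_HU_NegSkewness", "-1 x sample skewness of EAT HU (positive when mass piles toward high HU)"),
        ("EAT_HUkurtosis", "excess kurtosis of EAT HU"),
    ):
        add(nm, "intensity", "HU" if "Skew" not in nm and "kurt" not in nm else "1", f"{desc}; intensity.hu_summary")
    for nm in _BIN8:
        lo, hi = nm.split("_")[1:]
        add(nm, "intensity", "cm3", f"EAT volume with HU in [-{lo}, -{hi}]; intensity.hu_bins(8)")
    for nm in _BIN8:
        p = nm.replace("Vol_", "Pro_")
        lo, hi = nm.split("_")[1:]
        add(p, "intensity", "1", f"fraction of in-span EAT volume with HU in [-{lo}, -{hi}]")
    for s in _BIN4_STEMS:
        lo, hi = s.split("_")
        add(f"Vol4_{s}", "intensity", "cm3", f"EAT volume with HU in [-{lo}, -{hi}]; intensity.hu_bins(4)")
    for s in _BIN4_STEMS:
        lo, hi = s.split("_")
        add(f"Pro4_{s}", "intensity", "1", f"fraction of in-span EAT volume with HU in [-{lo}, -{hi}] (4-bin)")

    for r in SUBREGIONS:
        kind = "axial slab (PQ1 lowermost)" if r.startswith("PQ") else "radial shell (SH1 outermost)"
        add(f"Vol_{r}", "spatial", "cm3", f"EAT volume inside {kind} {r}")
        add(f"VolFrac_{r}", "spatial", "1", f"Vol_{r} / EAT_vol")
        for nm, desc in (
            (f"HUmean_{r}", "mean HU"),
            (f"HUmin_{r}", "minimum HU"),
            (f"HUmax_{r}", "maximum HU"),
            (f"HUstd_{r}", "HU standard deviation"),
            (f"HU_NegSkew_{r}", "-1 x HU skewness"),
            (f"HUkurt_{r}", "HU excess kurtosis"),
        ):
            add(nm, "spatial", "HU" if "Skew" not in nm and "kurt" not in nm else "1",
                f"{desc} of EAT in {r}")
        for s in _BIN4_STEMS:
            lo, hi = s.split("_")
            add(f"Vol4_{s}_{r}", "spatial", "cm3", f"EAT volume in {r} with HU in [-{lo}, -{hi}]")

    df = pd.DataFrame(rows)
    assert len(df) == N_FEATURES
    df.attrs["version"] = CATALOGUE_VERSION
    return df


def _region_intensity_block(
    ct: ImageVolume, region: MaskVolume, suffix: str, eat_vol_cm3: float,
    values: dict, flags: dict,
) -> None:
    if region.foreground_count() == 0:
        flags[f"Vol_{suffix}"] = True
        values[f"Vol_{suffix}"] = 0.0
        values[f"VolFrac_{suffix}"] = 0.0
        for nm in ("HUmean", "HUmin", "HUmax", "HUstd", "HU_NegSkew", "HUkurt"):
            values[f"{nm}_{suffix}"] = 0.0
        for s in _BIN4_STEMS:
            values[f"Vol4_{s}_{suffix}"] = 0.0
        return
    summ = intensity.hu_summary(ct, region, name=suffix)
    values[f"Vol_{suffix}"] = summ.volume_cm3
    values[f"VolFrac_{suffix}"] = summ.volume_cm3 / eat_vol_cm3 if eat_vol_cm3 > 0 else 0.0
    values[f"HUmean_{suffix}"] = summ.mean
    values[f"HUmin_{suffix}"] = summ.min
    values[f"HUmax_{suffix}"] = summ.max
    values[f"HUstd_{suffix}"] = summ.std
    values[f"HU_NegSkew_{suffix}"] = summ.neg_skewness
    values[f"HUkurt_{suffix}"] = summ.kurtosis
    bins4 = intensity.hu_bins(ct, region, n_bins=4)
    for s in _BIN4_STEMS:
        values[f"Vol4_{s}_{suffix}"] = bins4.volumes_cm3[f"Vol_{s}"]


def extract_features(
    ct: ImageVolume,
    sac: MaskVolume,
    eat: MaskVolume,
    subject_id: str = "subject",
    step_deg: float = 1.0,
) -> FeatureVector:
    """Compute the full 148-feature fat-omics vector for one subject."""
    check_congruent(ct, sac)
    check_congruent(ct, eat)
    if sac.foreground_count() == 0:
        raise ValueError("sac mask is empty")

    values: dict[str, float] = {}
    flags: dict[str, bool] = {}

    vv_cm3 = ct.voxel_volume_mm3 / intensity.MM3_PER_CM3
    eat_vol = eat.foreground_count() * vv_cm3
    sac_vol = sac.foreground_count() * vv_cm3
    empty_eat = eat.foreground_count() == 0
    if empty_eat:
        warnings.warn(f"subject {subject_id}: EAT mask is empty; moment features zeroed", stacklevel=2)

    values["EAT_vol"] = eat_vol
    values["Sac_vol"] = sac_vol
    values["EAT_fraction"] = eat_vol / sac_vol
    axes = geometry.principal_axes(sac)
    values["Axis_Major"] = axes.major
    values["Axis_Intermediate"] = axes.intermediate
    values["Axis_Minor"] = axes.minor
    values["Aspect_Major_Minor"] = axes.aspect_major_minor
    values["Aspect_Major_Intermediate"] = axes.aspect_major_intermediate

    field_ = thickness_mod.measure_thickness_field(eat, sac, step_deg=step_deg)
    ts = thickness_mod.summarize_thickness(field_)
    values["Thickness_Mean"] = ts.mean
    values["Thickness_Max"] = ts.max
    values["Thickness_Median"] = ts.median
    values["Thickness_Std"] = ts.std
    values["Thickness_Skewness"] = ts.skewness
    values["Thickness_Kurtosis"] = ts.kurtosis
    for b, cnt in zip(_THICK_BINS, ts.bin_counts):
        values[f"TB_{b}"] = float(cnt)
    for b, frac in zip(_THICK_BINS, ts.bin_fractions):
        values[f"TF_{b}"] = float(frac)

    if empty_eat:
        for nm in ("EAT_HUmin", "EAT_HUmax", "EAT_mean_HU", "EAT_HUstd",
                   "EAT_HU_NegSkewness", "EAT_HUkurtosis"):
            values[nm] = 0.0
            flags[nm] = True
        for nm in _BIN8:
            values[nm] = 0.0
            values[nm.replace("Vol_", "Pro_")] = 0.0
        for s in _BIN4_STEMS:
            values[f"Vol4_{s}"] = 0.0
            values[f"Pro4_{s}"] = 0.0
    else:
        summ = intensity.hu_summary(ct, eat, name="EAT")
        values["EAT_HUmin"] = summ.min
        values["EAT_HUmax"] = summ.max
        values["EAT_mean_HU"] = summ.mean
        values["EAT_HUstd"] = summ.std
        values["EAT_HU_NegSkewness"] = summ.neg_skewness
        values["EAT_HUkurtosis"] = summ.kurtosis
        bins8 = intensity.hu_bins(ct, eat, n_bins=8)
        for nm in _BIN8:
            values[nm] = bins8.volumes_cm3[nm]
        for nm in _BIN8:
            values[nm.replace("Vol_", "Pro_")] = bins8.probabilities[nm.replace("Vol_", "Pro_")]
        bins4 = intensity.hu_bins(ct, eat, n_bins=4)
        for s in _BIN4_STEMS:
            values[f"Vol4_{s}"] = bins4.volumes_cm3[f"Vol_{s}"]
        for s in _BIN4_STEMS:
            values[f"Pro4_{s}"] = bins4.probabilities[f"Pro_{s}"]

    slabs = geometry.partition_axial_slabs(sac)
    shells = geometry.partition_shells(sac)
    for k in range(1, 5):
        region = MaskVolume(
            ((slabs.data == k) & (eat.data > 0)).astype(np.uint8), ct.spacing, ct.origin
        )
        _region_intensity_block(ct, region, f"PQ{k}", eat_vol, values, flags)
    for k in range(1, 5):
        region = MaskVolume(
            ((shells.data == k) & (eat.data > 0)).astype(np.uint8), ct.spacing, ct.origin
        )
        _region_intensity_block(ct, region, f"SH{k}", eat_vol, values, flags)

    ordered = {name: float(values[name]) for name in feature_names()}
    return FeatureVector(subject_id=str(subject_id), values=ordered, flags=flags)


def extract_features_batch(subjects: list[tuple[str, ImageVolume, MaskVolume, MaskVolume]],
                           step_deg: float = 1.0) -> pd.DataFrame:
    """Feature table for many subjects: rows = subjects, 148 columns, plus flags."""
    rows = []
    flag_rows = []
    for sid, ct, sac, eat in subjects:
        fv = extract_features(ct, sac, eat, subject_id=sid, step_deg=step_deg)
        rows.append(fv.to_series())
        flag_rows.append(pd.Series({f"flag_{k}": int(v) for k, v in fv.flags.items()}, name=sid))
    feats = pd.DataFrame(rows)
    flags = pd.DataFrame(flag_rows).fillna(0).astype(int) if flag_rows else pd.DataFrame()
    if not flags.empty:
        feats = feats.join(flags)
        feats[flags.columns] = feats[flags.columns].fillna(0).astype(int)
    feats.index.name = "id"
    return feats
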