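"""Reading and writing image volumes and tabular data.

Volumes are NIfTI (.nii / .nii.gz) read through nibabel; tables are CSV
through pandas. A CT volume and any mask defined on it must live on the
same voxel lattice ("grid congruence"): identical shape and spacing within
1e-3 mm. Resampling is deliberately out of scope — a mismatch is treated
as a user error and reported with both geometries.

Array axis convention: ``data[x, y, z]`` with the third axis axial; slice
index increases toward the head, so the top of the heart is the highest
slice index containing pericardium.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "ImageVolume",
    "MaskVolume",
    "GridMismatchError",
    "read_volume",
    "read_mask",
    "write_volume",
    "write_mask",
    "derive_eat_mask",
    "read_survival_table",
    "write_feature_table",
    "read_feature_table",
]

#: default Hounsfield window defining adipose tissue, closed interval
FAT_HU_WINDOW = (-190.0, -30.0)

SPACING_TOL_MM = 1e-3


class GridMismatchError(ValueError):
    """CT and mask are not defined on the same voxel lattice."""


@dataclass(frozen=True)
class ImageVolume:
    """A 3D scalar volume (HU) with physical voxel geometry.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar voxel values in Hounsfield units, finite everywhere.
    spacing : tuple of float
        Physical size of a voxel (sx, sy, sz) in mm; strictly positive.
    origin : tuple of float
        Physical coordinate (mm) of the center of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"volume must be 3D, got {data.ndim}D payload of shape {data.shape}")
        if not np.all(np.isfinite(data)):
            raise ValueError("volume contains NaN or Inf voxels")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def voxel_centers_mm(self, indices: np.ndarray) -> np.ndarray:
        """Physical coordinates (mm) of voxel centers for an (n, 3) index array."""
        return np.asarray(indices, dtype=float) * np.array(self.spacing) + np.array(self.origin)


@dataclass(frozen=True)
class MaskVolume:
    """Binary or label mask on the same lattice as an :class:`ImageVolume`.

    ``data`` holds small non-negative integers: 0 background, 1 foreground
    for binary masks, or region labels 1..K for label maps.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"mask must be 3D, got {data.ndim}D payload of shape {data.shape}")
        if data.dtype == bool:
            data = data.astype(np.uint8)
        if not np.issubdtype(data.dtype, np.integer):
            rounded = np.rint(data)
            if not np.allclose(data, rounded):
                raise ValueError("mask values must be integers")
            data = rounded.astype(np.int32)
        if data.min() < 0:
            raise ValueError("mask values must be non-negative labels")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def foreground_count(self) -> int:
        return int(np.count_nonzero(self.data))

    def volume_mm3(self) -> float:
        return self.foreground_count() * self.voxel_volume_mm3

    def voxel_centers_mm(self, indices: np.ndarray) -> np.ndarray:
        return np.asarray(indices, dtype=float) * np.array(self.spacing) + np.array(self.origin)


def check_congruent(a: ImageVolume | MaskVolume, b: ImageVolume | MaskVolume) -> None:
    """Raise :class:`GridMismatchError` unless a and b share a lattice."""
    if a.shape != b.shape or not np.allclose(a.spacing, b.spacing, atol=SPACING_TOL_MM):
        raise GridMismatchError(
            "grids are not congruent: "
            f"shape {a.shape} / spacing {a.spacing} vs shape {b.shape} / spacing {b.spacing}"
        )


# ---------------------------------------------------------------------------
# NIfTI I/O


def _load_nifti(path: str | os.PathLike):
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such volume file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got {data.ndim}D payload of shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"{path}: non-positive voxel spacing {zooms}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return data, tuple(float(z) for z in zooms), origin


def read_volume(path: str | os.PathLike) -> ImageVolume:
    """Read a NIfTI CT volume; HU values are used as stored."""
    data, spacing, origin = _load_nifti(path)
    return ImageVolume(np.asarray(data, dtype=np.float32), spacing, origin)


def read_mask(path: str | os.PathLike) -> MaskVolume:
    """Read a NIfTI binary/label mask."""
    data, spacing, origin = _load_nifti(path)
    return MaskVolume(np.rint(np.asarray(data)).astype(np.int16), spacing, origin)


def _affine(vol: ImageVolume | MaskVolume) -> np.ndarray:
    aff = np.diag(list(vol.spacing) + [1.0])
    aff[:3, 3] = vol.origin
    return aff


def write_volume(vol: ImageVolume, path: str | os.PathLike) -> None:
    nib.save(nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), _affine(vol)), str(path))


def write_mask(mask: MaskVolume, path: str | os.PathLike) -> None:
    nib.save(nib.Nifti1Image(np.asarray(mask.data, dtype=np.int16), _affine(mask)), str(path))


# ---------------------------------------------------------------------------
# EAT mask derivation


def derive_eat_mask(
    ct: ImageVolume,
    sac: MaskVolume,
    hu_window: tuple[float, float] = FAT_HU_WINDOW,
) -> MaskVolume:
    """Threshold the CT inside the pericardial sac to obtain the EAT mask.

    A voxel is adipose iff it lies inside the sac and its HU value falls in
    the closed window ``[lo, hi]`` (default [-190, -30] HU, the span tiled
    by the HU-bin features).
    """
    check_congruent(ct, sac)
    lo, hi = float(hu_window[0]), float(hu_window[1])
    if not lo < hi:
        raise ValueError(f"HU window must satisfy lo < hi, got ({lo}, {hi})")
    fat = (sac.data > 0) & (ct.data >= lo) & (ct.data <= hi)
    return MaskVolume(fat.astype(np.uint8), ct.spacing, ct.origin)


# ---------------------------------------------------------------------------
# Tabular I/O


def read_survival_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read and validate a survival table CSV.

    Requires columns ``id``, ``time`` (days, > 0) and ``event`` ({0,1});
    any extra columns pass through untouched. Offending rows are listed in
    the error message.
    """
    df = pd.read_csv(path)
    return validate_survival_table(df)


def validate_survival_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = {"id", "time", "event"} - set(df.columns)
    if missing:
        raise ValueError(f"survival table missing required columns: {sorted(missing)}")
    dup = df["id"][df["id"].duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicate subject ids: {dup}")
    bad_time = df.index[~(pd.to_numeric(df["time"], errors="coerce") > 0)].tolist()
    if bad_time:
        raise ValueError(f"non-positive or non-numeric times at rows {bad_time}")
    ev = pd.to_numeric(df["event"], errors="coerce")
    bad_ev = df.index[~ev.isin([0, 1])].tolist()
    if bad_ev:
        raise ValueError(f"non-binary event indicators at rows {bad_ev}")
    out = df.copy()
    out["id"] = out["id"].astype(str)
    out["time"] = out["time"].astype(float)
    out["event"] = ev.astype(int)
    return out


def write_feature_table(features: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a per-subject feature table: one row per subject, stable column order."""
    features.to_csv(path, index=True, index_label="id", float_format="%.10g")


def read_feature_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, index_col="id")
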