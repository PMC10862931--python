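"""HU-distribution features over an arbitrary region mask.

Two primitives: summary moments of the region's HU values (with the
negative-skewness sign convention — positive when mass piles toward high,
less negative HU, the pattern associated with fat inflammation) and fixed
equal-width HU bins over the adipose span [-190, -30] HU, reported both as
absolute volumes (cm^3) and as probabilities normalized by the in-span
region volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import ImageVolume, MaskVolume, check_congruent

__all__ = ["HUSummary", "HUBinSet", "hu_summary", "hu_bins", "HU_SPAN"]

#: span tiled by the HU bins; equals the default fat window
HU_SPAN = (-190.0, -30.0)

MM3_PER_CM3 = 1000.0


@dataclass(frozen=True)
class HUSummary:
    min: float
    max: float
    mean: float
    std: float
    neg_skewness: float  # -1 x sample skewness
    kurtosis: float  # excess kurtosis; 0 for constant regions
    voxel_count: int
    volume_cm3: float


@dataclass(frozen=True)
class HUBinSet:
    """Equal-width HU bins over a span; right-open except the last bin.

    Bin names follow the ``Vol_<|lo|>_<|hi|>`` / ``Pro_<|lo|>_<|hi|>``
    convention, e.g. ``Vol_50_30`` is the volume with HU in [-50, -30].
    """

    edges: tuple[float, ...]
    volumes_cm3: dict[str, float]  # name -> cm^3
    probabilities: dict[str, float]  # name -> fraction of in-span volume
    out_of_span_count: int
    voxel_counts: dict[str, int]


def _moments(values: np.ndarray) -> tuple[float, float, float]:
    """(std, skewness, excess kurtosis) with the zero-variance convention."""
    std = float(values.std(ddof=0))
    if std > 0:
        return std, float(stats.skew(values, bias=True)), float(
            stats.kurtosis(values, fisher=True, bias=True)
        )
    return 0.0, 0.0, 0.0


def hu_summary(ct: ImageVolume, region: MaskVolume, name: str = "region") -> HUSummary:
    """Moments of the HU distribution over the region's voxels."""
    check_congruent(ct, region)
    vals = ct.data[region.data > 0]
    if vals.size == 0:
        raise ValueError(f"region '{name}' is empty")
    vals = np.asarray(vals, dtype=float)
    std, skew, kurt = _moments(vals)
    return HUSummary(
        min=float(vals.min()),
        max=float(vals.max()),
        mean=float(vals.mean()),
        std=std,
        neg_skewness=-skew,
        kurtosis=kurt,
        voxel_count=int(vals.size),
        volume_cm3=vals.size * region.voxel_volume_mm3 / MM3_PER_CM3,
    )


def bin_names(n_bins: int, span: tuple[float, float] = HU_SPAN, prefix: str = "Vol") -> list[str]:
    lo, hi = span
    width = (hi - lo) / n_bins
    names = []
    for i in range(n_bins):
        a, b = lo + i * width, lo + (i + 1) * width
        names.append(f"{prefix}_{abs(int(round(a)))}_{abs(int(round(b)))}")
    return names


def hu_bins(
    ct: ImageVolume,
    region: MaskVolume,
    n_bins: int = 8,
    span: tuple[float, float] = HU_SPAN,
) -> HUBinSet:
    """Equal-width HU-bin volumes and probabilities over the region.

    The span is tiled by ``n_bins`` equal-width bins, right-open except the
    last, which is closed. Voxels outside the span are excluded from every
    bin and reported in ``out_of_span_count``; probabilities normalize by
    the in-span region volume so they sum to 1 whenever any voxel is in
    span.
    """
    check_congruent(ct, region)
    lo, hi = float(span[0]), float(span[1])
    if n_bins < 1 or not lo < hi:
        raise ValueError(f"invalid bin spec: n_bins={n_bins}, span={span}")
    vals = np.asarray(ct.data[region.data > 0], dtype=float)
    edges = np.linspace(lo, hi, n_bins + 1)
    in_span = (vals >= lo) & (vals <= hi)
    counts = np.histogram(vals[in_span], bins=edges)[0]
    out_count = int(vals.size - in_span.sum())
    vv = region.voxel_volume_mm3 / MM3_PER_CM3
    names = bin_names(n_bins, (lo, hi), prefix="")
    names = [n.lstrip("_") for n in names]
    total_in_span = counts.sum()
    vols = {f"Vol_{n}": float(c * vv) for n, c in zip(names, counts)}
    probs = {
        f"Pro_{n}": (float(c / total_in_span) if total_in_span else 0.0)
        for n, c in zip(names, counts)
    }
    cnts = {f"Vol_{n}": int(c) for n, c in zip(names, counts)}
    return HUBinSet(
        edges=tuple(float(e) for e in edges),
        volumes_cm3=vols,
        probabilities=probs,
        out_of_span_count=out_count,
        voxel_counts=cnts,
    )
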