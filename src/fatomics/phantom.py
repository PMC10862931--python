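"""Synthetic CT phantoms and simulated survival data.

The phantom is an ellipsoidal "sac" (semi-axes a >= b >= c, mm) in a uniform
background, with a fat shell immediately inside the sac surface. The shell
is defined radially from the sac center: along the direction (theta, phi) a
voxel at radius r is fat iff r_surface - t(theta, phi) < r <= r_surface,
so a centered ray in that direction crosses exactly t mm of fat — the
ground truth the thickness sweep must recover. A voxel belongs to a region
iff its *center* does, matching mask semantics downstream.

Fat HU values are drawn from a truncated-normal (or uniform) distribution
supported inside the adipose window [-190, -30] HU; non-fat sac interior
sits at soft-tissue HU (+40 by default) and background at air (-1000).
Optional Gaussian acquisition noise can be layered on the whole image.

Survival data follow an exponential-baseline proportional-hazards model:
T_i = -ln(U_i) / (lambda0 * exp(x_i' beta)) with uniform censoring on
[0, Tmax]. Every stochastic element flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .io import ImageVolume, MaskVolume

__all__ = [
    "PhantomSpec",
    "SimSurvSpec",
    "make_shell_phantom",
    "simulate_survival",
]

#: CTCS-like acquisition geometry: 0.5 x 0.5 mm in-plane, 2.5 mm slices
DEFAULT_SPACING = (0.5, 0.5, 2.5)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity recipe for one shell phantom.

    ``thickness_mm`` is either a constant (mm) or a callable
    ``t(theta_rad, phi_rad)`` of azimuth and polar angle returning mm.
    ``fat_hu`` is ("truncnorm", mean, sd) or ("uniform", lo, hi) with
    support inside [-190, -30] HU.
    """

    shape: tuple[int, int, int] = (96, 96, 40)
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    semi_axes_mm: tuple[float, float, float] = (20.0, 18.0, 16.0)
    thickness_mm: float | Callable[[np.ndarray, np.ndarray], np.ndarray] = 5.0
    fat_hu: tuple = ("truncnorm", -100.0, 25.0)
    interior_hu: float = 40.0
    background_hu: float = -1000.0
    noise_sd_hu: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        a, b, c = self.semi_axes_mm
        if not (a >= b >= c > 0):
            raise ValueError(f"semi-axes must satisfy a >= b >= c > 0, got {self.semi_axes_mm}")
        half_extent = 0.5 * np.array(self.shape) * np.array(self.spacing)
        margin = 2.0 * np.array(self.spacing)
        if np.any(np.array(self.semi_axes_mm) > half_extent - margin):
            raise ValueError(
                f"semi-axes {self.semi_axes_mm} do not fit in grid "
                f"{self.shape} at spacing {self.spacing} with a 2-voxel margin"
            )
        tmax = self._max_thickness()
        if tmax < 0:
            raise ValueError("thickness function must be non-negative")
        if tmax > min(self.semi_axes_mm) / 2:
            raise ValueError(
                f"shell thickness {tmax:.1f} mm exceeds half the minor semi-axis"
            )

    def _max_thickness(self) -> float:
        if callable(self.thickness_mm):
            th = np.linspace(0, 2 * np.pi, 73)
            ph = np.linspace(0, np.pi, 37)
            tt, pp = np.meshgrid(th, ph)
            vals = np.asarray(self.thickness_mm(tt, pp), dtype=float)
            return float(vals.max()) if vals.min() >= 0 else -1.0
        return float(self.thickness_mm)


def _fat_sampler(fat_hu: tuple):
    family = fat_hu[0]
    if family == "truncnorm":
        mean, sd = float(fat_hu[1]), float(fat_hu[2])
        lo, hi = -190.0, -30.0
        a, b = (lo - mean) / sd, (hi - mean) / sd
        dist = stats.truncnorm(a, b, loc=mean, scale=sd)
        return lambda n, rng: dist.rvs(size=n, random_state=rng)
    if family == "uniform":
        lo, hi = float(fat_hu[1]), float(fat_hu[2])
        if lo < -190.0 or hi > -30.0:
            raise ValueError(f"fat HU support [{lo}, {hi}] leaves the window [-190, -30]")
        return lambda n, rng: rng.uniform(lo, hi, size=n)
    raise ValueError(f"unknown fat HU family: {family!r}")


def make_shell_phantom(spec: PhantomSpec) -> tuple[ImageVolume, MaskVolume, dict]:
    """Build the phantom; returns (ct, sac mask, ground-truth record).

    The truth record holds the exact voxelized fat volume (mm^3), the
    analytic shell volume for constant-thickness specs, the thickness
    evaluated on the standard 1-degree ray grid, the semi-axes, the fat
    mask itself and the HU sample moments.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = np.array(spec.shape)
    spacing = np.array(spec.spacing)
    center = (shape - 1) / 2.0 * spacing  # physical center of the grid

    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    coords = np.stack([ii, jj, kk], axis=-1) * spacing  # voxel centers, origin 0
    rel = coords - center
    r = np.linalg.norm(rel, axis=-1)

    a, b, c = spec.semi_axes_mm
    with np.errstate(divide="ignore", invalid="ignore"):
        unit = rel / r[..., None]
    unit[r == 0] = (1.0, 0.0, 0.0)
    # radius of the ellipsoid surface along each voxel's direction
    inv_r2 = (unit[..., 0] / a) ** 2 + (unit[..., 1] / b) ** 2 + (unit[..., 2] / c) ** 2
    r_surf = 1.0 / np.sqrt(inv_r2)

    sac_fg = r <= r_surf

    if callable(spec.thickness_mm):
        theta = np.arctan2(unit[..., 1], unit[..., 0])
        phi = np.arccos(np.clip(unit[..., 2], -1.0, 1.0))
        t_local = np.asarray(spec.thickness_mm(theta, phi), dtype=float)
    else:
        t_local = np.full(shape, float(spec.thickness_mm))

    fat_fg = sac_fg & (r > r_surf - t_local)

    ct = np.full(shape, spec.background_hu, dtype=np.float64)
    ct[sac_fg] = spec.interior_hu
    n_fat = int(fat_fg.sum())
    sampler = _fat_sampler(spec.fat_hu)
    fat_vals = sampler(n_fat, rng) if n_fat else np.empty(0)
    ct[fat_fg] = fat_vals
    if spec.noise_sd_hu > 0:
        ct += rng.normal(0.0, spec.noise_sd_hu, size=ct.shape)

    voxel_vol = float(np.prod(spacing))
    truth = {
        "semi_axes_mm": tuple(spec.semi_axes_mm),
        "fat_voxel_count": n_fat,
        "fat_volume_mm3": n_fat * voxel_vol,
        "sac_volume_mm3": int(sac_fg.sum()) * voxel_vol,
        "center_mm": tuple(center),
        "fat_hu_mean": float(fat_vals.mean()) if n_fat else float("nan"),
        "fat_hu_std": float(fat_vals.std()) if n_fat else float("nan"),
        "fat_mask": MaskVolume(fat_fg.astype(np.uint8), spec.spacing),
        "thickness_on_ray_grid_mm": _thickness_on_ray_grid(spec),
    }
    if not callable(spec.thickness_mm):
        t = float(spec.thickness_mm)
        truth["analytic_shell_volume_mm3"] = _radial_shell_volume(a, b, c, t)

    return (
        ImageVolume(ct, spec.spacing),
        MaskVolume(sac_fg.astype(np.uint8), spec.spacing),
        truth,
    )


def _thickness_on_ray_grid(spec: PhantomSpec, step_deg: float = 1.0) -> np.ndarray:
    theta = np.deg2rad(np.arange(0.0, 360.0, step_deg))
    phi = np.deg2rad(np.arange(0.0, 180.0, step_deg))
    tt, pp = np.meshgrid(theta, phi, indexing="ij")
    if callable(spec.thickness_mm):
        return np.asarray(spec.thickness_mm(tt, pp), dtype=float)
    return np.full(tt.shape, float(spec.thickness_mm))


def _radial_shell_volume(a: float, b: float, c: float, t: float) -> float:
    """Volume of the radial shell {r_surf - t < r <= r_surf} by quadrature.

    Exact closed form (4/3 pi (R^3 - (R-t)^3)) for spheres; for general
    ellipsoids the radial offset surface has no elementary volume, so the
    solid-angle integral (1/3) \\int (r_surf^3 - (r_surf-t)^3) dOmega is
    evaluated numerically.
    """
    if a == b == c:
        return 4.0 / 3.0 * np.pi * (a**3 - (a - t) ** 3)
    th = np.linspace(0, 2 * np.pi, 721)
    ph = np.linspace(0, np.pi, 361)
    tt, pp = np.meshgrid(th, ph, indexing="ij")
    ux = np.sin(pp) * np.cos(tt)
    uy = np.sin(pp) * np.sin(tt)
    uz = np.cos(pp)
    r_surf = 1.0 / np.sqrt((ux / a) ** 2 + (uy / b) ** 2 + (uz / c) ** 2)
    integrand = (r_surf**3 - np.clip(r_surf - t, 0, None) ** 3) / 3.0 * np.sin(pp)
    return float(np.trapezoid(np.trapezoid(integrand, ph, axis=1), th))


# ---------------------------------------------------------------------------
# survival simulation


@dataclass(frozen=True)
class SimSurvSpec:
    """Recipe for one simulated survival cohort.

    Features come from a multivariate normal (``mean``, ``cov``) unless a
    precomputed feature table is supplied. ``beta`` maps feature names to
    true log-hazard coefficients; unnamed features have coefficient 0.
    """

    n: int = 500
    feature_names: tuple[str, ...] = tuple(f"f{i:02d}" for i in range(50))
    mean: np.ndarray | None = None
    cov: np.ndarray | None = None
    beta: dict[str, float] = field(default_factory=dict)
    baseline_hazard: float = 0.1  # events per unit time
    censor_tmax: float = 6.0  # uniform censoring horizon (years)
    seed: int = 0

    def validate(self) -> None:
        unknown = set(self.beta) - set(self.feature_names)
        if unknown:
            raise ValueError(f"beta names not in feature set: {sorted(unknown)}")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be positive")
        if self.n < 1:
            raise ValueError("need at least one subject")


def simulate_survival(
    spec: SimSurvSpec,
    features: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Draw features and event times; returns (features, survival table, truth).

    Event time T_i = -ln(U_i) / (lambda0 * exp(x_i' beta)); observed time is
    min(T_i, C_i) with C_i ~ Uniform(0, Tmax) and event = 1 iff T_i <= C_i.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    p = len(spec.feature_names)
    if features is None:
        mean = np.zeros(p) if spec.mean is None else np.asarray(spec.mean, dtype=float)
        cov = np.eye(p) if spec.cov is None else np.asarray(spec.cov, dtype=float)
        X = rng.multivariate_normal(mean, cov, size=spec.n, method="cholesky")
        features = pd.DataFrame(X, columns=list(spec.feature_names))
        features.index = [f"S{i:05d}" for i in range(spec.n)]
    else:
        missing = set(spec.beta) - set(features.columns)
        if missing:
            raise ValueError(f"feature table lacks beta columns: {sorted(missing)}")

    beta_vec = np.array([spec.beta.get(name, 0.0) for name in features.columns])
    lp = features.to_numpy(dtype=float) @ beta_vec
    n = len(features)
    u = rng.uniform(size=n)
    t_event = -np.log(u) / (spec.baseline_hazard * np.exp(lp))
    if np.isinf(spec.censor_tmax):
        t_cens = np.full(n, np.inf)  # administrative no-censoring limit
    elif spec.censor_tmax > 0:
        t_cens = rng.uniform(0.0, spec.censor_tmax, size=n)
    else:
        t_cens = np.zeros(n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    # product-limit machinery requires strictly positive follow-up
    time = np.maximum(time, 1e-9)

    surv = pd.DataFrame({"id": features.index.astype(str), "time": time, "event": event})
    truth = {
        "beta": dict(spec.beta),
        "linear_predictor": pd.Series(lp, index=features.index),
        "event_time": t_event,
        "censor_time": t_cens,
    }
    return features, surv, truth
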