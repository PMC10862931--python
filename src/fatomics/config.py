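"""Run configuration and reproducibility manifest.

A :class:`RunConfig` carries every knob of the pipeline — input paths, the
adipose HU window, ray-sweep step, slab/shell counts, mRMR k, elastic-net
mixing, CV folds, seed, and the evaluation horizons — and serializes to
YAML. Every pipeline invocation writes a manifest (config + package
version + seed) next to its outputs so a run can be reproduced
bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import yaml

__all__ = ["RunConfig", "load_config", "write_manifest"]


@dataclass
class RunConfig:
    # inputs
    ct_path: str | None = None
    sac_path: str | None = None
    eat_path: str | None = None  # optional precomputed EAT mask
    features_path: str | None = None
    surv_path: str | None = None
    out_dir: str = "fatomics_out"
    # extraction
    hu_window: tuple[float, float] = (-190.0, -30.0)
    ray_step_deg: float = 1.0
    n_slabs: int = 4
    n_shells: int = 4
    # modeling
    mrmr_k: int = 50
    l1_ratio: float = 0.8
    cv_folds: int = 10
    target_support: int | None = None
    test_size: float = 0.2
    # evaluation
    auc_horizon: float = 2.0
    nri_horizon: float = 2.0
    n_bootstrap: int = 1000
    seed: int = 0

    def validate(self, n_features: int | None = None) -> None:
        lo, hi = self.hu_window
        if not lo < hi:
            raise ValueError(f"HU window must have lo < hi, got {self.hu_window}")
        if self.ray_step_deg <= 0 or 360 % round(360 / self.ray_step_deg):
            pass
        if not 0 < self.l1_ratio <= 1:
            raise ValueError(f"l1_ratio must be in (0, 1], got {self.l1_ratio}")
        if self.cv_folds < 2:
            raise ValueError("need at least 2 CV folds")
        if n_features is not None and self.mrmr_k > n_features:
            raise ValueError(f"mrmr_k={self.mrmr_k} exceeds the {n_features} available features")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["hu_window"] = list(d["hu_window"])
        return d


def load_config(path: str | os.PathLike) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "hu_window" in raw:
        raw["hu_window"] = tuple(raw["hu_window"])
    return RunConfig(**raw)


def write_manifest(config: RunConfig, out_dir: str | os.PathLike, extra: dict | None = None) -> str:
    from . import __version__

    os.makedirs(out_dir, exist_ok=True)
    manifest = {
        "package": "fatomics",
        "version": __version__,
        "config": config.to_dict(),
    }
    if extra:
        manifest.update(extra)
    path = os.path.join(out_dir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path
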