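"""Shared fixtures: phantoms at known geometry and brute-force oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fatomics import ImageVolume, MaskVolume, PhantomSpec, make_shell_phantom


@pytest.fixture(scope="session")
def sphere_shell():
    """Spherical sac r=40 mm with constant 6 mm fat shell at CTCS spacing.

    The canonical thickness-recovery phantom: every centered ray crosses
    exactly 6 mm of fat by construction.
    """
    spec = PhantomSpec(
        shape=(176, 176, 38),
        spacing=(0.5, 0.5, 2.5),
        semi_axes_mm=(40.0, 40.0, 40.0),
        thickness_mm=6.0,
        seed=11,
    )
    ct, sac, truth = make_shell_phantom(spec)
    return spec, ct, sac, truth


@pytest.fixture(scope="session")
def ellipsoid_shell():
    """Axis-aligned ellipsoid, diameters (120, 90, 60) mm, 6 mm shell."""
    spec = PhantomSpec(
        shape=(136, 104, 36),
        spacing=(1.0, 1.0, 2.0),
        semi_axes_mm=(60.0, 45.0, 30.0),
        thickness_mm=6.0,
        seed=7,
    )
    ct, sac, truth = make_shell_phantom(spec)
    return spec, ct, sac, truth


@pytest.fixture(scope="session")
def small_shell():
    """Cheap isotropic-ish phantom for catalogue-level tests."""
    spec = PhantomSpec(
        shape=(64, 64, 32),
        spacing=(1.0, 1.0, 2.0),
        semi_axes_mm=(25.0, 22.0, 20.0),
        thickness_mm=5.0,
        seed=3,
    )
    ct, sac, truth = make_shell_phantom(spec)
    return spec, ct, sac, truth


# ---------------------------------------------------------------------------
# brute-force oracles (kept independent of the library implementations)


def harrell_c_oracle(time, event, risk) -> float:
    """Exhaustive all-pairs Harrell C: event-anchored pairs, score ties 0.5.

    Comparable pairs: (i, j) with t_i < t_j and subject i an event, plus
    tied-time pairs where exactly one subject is an event (the event
    subject is known to fail first). Tied event times are not comparable.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    risk = np.asarray(risk, float)
    num = den = 0.0
    n = len(time)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if time[i] < time[j] and event[i] == 1:
                pass  # i fails first
            elif time[i] == time[j] and event[i] == 1 and event[j] == 0:
                pass  # i fails at the moment j is censored
            else:
                continue
            den += 1
            if risk[i] > risk[j]:
                num += 1
            elif risk[i] == risk[j]:
                num += 0.5
    if den == 0:
        raise ValueError("no usable pairs")
    return num / den


def km_oracle(time, event, t_grid) -> np.ndarray:
    """Hand product-limit estimator evaluated on a time grid."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    ev_times = np.sort(np.unique(time[event == 1]))
    out = np.ones(len(t_grid))
    for gi, t in enumerate(t_grid):
        s = 1.0
        for et in ev_times[ev_times <= t]:
            n_risk = np.sum(time >= et)
            d = np.sum((time == et) & (event == 1))
            s *= 1.0 - d / n_risk
        out[gi] = s
    return out


def bin_count_oracle(values, edges) -> list[int]:
    """Explicit per-bin counting: right-open bins, last bin closed."""
    counts = []
    for k in range(len(edges) - 1):
        lo, hi = edges[k], edges[k + 1]
        if k == len(edges) - 2:
            counts.append(int(sum(lo <= v <= hi for v in values)))
        else:
            counts.append(int(sum(lo <= v < hi for v in values)))
    return counts


def uniform_volume(shape, spacing, hu=-100.0) -> ImageVolume:
    return ImageVolume(np.full(shape, float(hu)), spacing)


def full_mask(shape, spacing) -> MaskVolume:
    return MaskVolume(np.ones(shape, dtype=np.uint8), spacing)
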