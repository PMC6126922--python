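"""Synthetic trial-wise brain volumes with known embedded encodings.

The generator emulates the *output* of single-trial fMRI estimation:
one 3D map per trial, mean-centered within the analysis mask (as after
subtracting the white-matter mean from trial-wise t-maps). Designated
regions linearly encode a chosen model variable: voxel ``v`` of an ROI
carries ``w_v * z(y_t) * snr + noise`` on trial ``t``, where ``w`` is a
fixed random weight pattern (seeded standard normal, one per ROI),
``z(y)`` is the z-scored variable series and the noise is i.i.d. standard
normal everywhere in the mask. ``snr`` is therefore a signal/noise
amplitude ratio per voxel. No haemodynamics or scanner physics are
simulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import as_rng

__all__ = [
    "VolumeGeometry",
    "ROIEncoding",
    "EncodingSpec",
    "sphere_mask",
    "simulate_volumes",
]


def sphere_mask(shape: tuple[int, int, int], center, radius: float) -> np.ndarray:
    """Boolean ball of the given voxel radius inside ``shape``."""
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius**2


@dataclass(frozen=True)
class VolumeGeometry:
    """Voxel grid, voxel size (mm) and analysis mask of the synthetic brain."""

    shape: tuple[int, int, int]
    mask: np.ndarray
    voxel_size: float = 3.0

    def __post_init__(self):
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != tuple(self.shape):
            raise ValueError("mask shape must match volume shape")
        if not mask.any():
            raise ValueError("mask must be non-empty")
        object.__setattr__(self, "mask", mask)

    @property
    def affine(self) -> np.ndarray:
        return np.diag([self.voxel_size] * 3 + [1.0])


@dataclass(frozen=True)
class ROIEncoding:
    """One region encoding one model variable at a given SNR."""

    roi: np.ndarray  # boolean 3D array
    variable: str
    snr: float
    weight_seed: int | None = None

    def __post_init__(self):
        if self.snr < 0:
            raise ValueError("snr must be non-negative")
        object.__setattr__(self, "roi", np.asarray(self.roi, dtype=bool))


@dataclass(frozen=True)
class EncodingSpec:
    """Collection of ROI encodings; ROIs must be pairwise disjoint unless
    ``allow_overlap`` is set."""

    rois: tuple[ROIEncoding, ...] = ()
    allow_overlap: bool = False

    def __post_init__(self):
        if not self.allow_overlap:
            seen = None
            for enc in self.rois:
                if seen is not None and (seen & enc.roi).any():
                    raise ValueError("overlapping ROIs (set allow_overlap to permit)")
                seen = enc.roi if seen is None else (seen | enc.roi)


def _zscore(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float).copy()
    bad = ~np.isfinite(y)
    if bad.all():
        raise ValueError("variable series has no finite values")
    y[bad] = np.nanmean(y)
    sd = y.std()
    return (y - y.mean()) / (sd if sd > 0 else 1.0)


def simulate_volumes(
    trials: pd.DataFrame,
    variables: pd.DataFrame,
    spec: EncodingSpec,
    geometry: VolumeGeometry,
    seed: int | None = None,
) -> np.ndarray:
    """Generate per-trial volumes as a 4D array (x, y, z, trial).

    ``variables`` must be row-aligned with ``trials`` and contain every
    column named by ``spec``. Voxels outside the mask are zero; every
    trial volume is mean-centered within the mask.
    """
    if len(variables) != len(trials):
        raise ValueError("variables must be row-aligned with trials")
    mask = geometry.mask
    n_trials = len(trials)
    rng = as_rng(seed)

    vol = np.zeros(geometry.shape + (n_trials,))
    vol[mask, :] = rng.standard_normal((int(mask.sum()), n_trials))

    for enc in spec.rois:
        if enc.variable not in variables.columns:
            raise KeyError(f"variable {enc.variable!r} not found in variables table")
        if (enc.roi & ~mask).any():
            raise ValueError("ROI extends outside the mask")
        y = _zscore(variables[enc.variable].to_numpy())
        w_rng = as_rng(enc.weight_seed) if enc.weight_seed is not None else rng
        w = w_rng.standard_normal(int(enc.roi.sum()))
        vol[enc.roi, :] += enc.snr * np.outer(w, y)

    # emulate WM-mean subtraction: center each trial map within the mask
    vol[mask, :] -= vol[mask, :].mean(axis=0, keepdims=True)
    return vol
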