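"""Rigid CTA-to-NCCT registration by mutual-information maximization.

Multimodal registration: the moving volume is sampled at transformed fixed
voxel positions and the mutual information of the joint intensity histogram
is maximized over the 6 rigid parameters with a multi-resolution Powell
schedule. A fixed sampling seed makes the result deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize

from .errors import DegenerateInputError, RegistrationWarning
from .image_core import Grid, RigidTransform, Volume3D

__all__ = ["register_rigid", "apply_manual_correction", "mutual_information"]

_SAMPLING_SEED = 946684800
_N_BINS = 32


def mutual_information(a: np.ndarray, b: np.ndarray, bins: int = _N_BINS) -> float:
    """Mutual information (nats) of two paired intensity samples."""
    hist, _, _ = np.histogram2d(a, b, bins=bins)
    p = hist / hist.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


class _MIObjective:
    """Negative MI between fixed samples and the resampled moving volume."""

    def __init__(self, moving: Volume3D, fixed: Volume3D, n_samples: int, smooth_vox: float):
        mov = moving.voxels.astype(float)
        fix = fixed.voxels.astype(float)
        if smooth_vox > 0:
            mov = ndimage.gaussian_filter(mov, smooth_vox)
            fix = ndimage.gaussian_filter(fix, smooth_vox)
        self.moving = mov
        self.moving_grid = moving.grid
        self.center = fixed.grid.center_mm
        rng = np.random.default_rng(_SAMPLING_SEED)
        total = fix.size
        take = min(n_samples, total)
        flat = rng.choice(total, size=take, replace=False)
        idx = np.stack(np.unravel_index(flat, fix.shape), axis=1)
        self.fixed_values = fix[tuple(idx.T)]
        self.fixed_world = fixed.grid.index_to_world(idx)
        self.mov_min = float(mov.min())

    def __call__(self, params) -> float:
        t = RigidTransform(tuple(params[:3]), tuple(params[3:]), tuple(self.center))
        src = self.moving_grid.world_to_index(t.inverse().apply(self.fixed_world))
        vals = ndimage.map_coordinates(
            self.moving, src.T, order=1, mode="constant", cval=self.mov_min
        )
        return -mutual_information(self.fixed_values, vals)


def _shrink(volume: Volume3D, factor: int) -> Volume3D:
    if factor <= 1:
        return volume
    sm = ndimage.gaussian_filter(volume.voxels.astype(float), sigma=factor / 2.5)
    sub = sm[::factor, ::factor, ::factor]
    return Volume3D(sub, tuple(s * factor for s in volume.spacing), volume.origin)


def register_rigid(
    moving: Volume3D,
    fixed: Volume3D,
    init: Optional[RigidTransform] = None,
    n_samples: int = 40000,
) -> RigidTransform:
    """Estimate the rigid transform mapping *moving* world onto *fixed* world.

    Runs Powell optimization of negative mutual information at 4x, 2x and 1x
    resolution. If the full schedule fails to improve on the initialization a
    :class:`RegistrationWarning` is emitted and the best-found transform is
    returned (mirrors the visual-inspection / manual-correction workflow).
    """
    if np.ptp(moving.voxels) == 0 or np.ptp(fixed.voxels) == 0:
        raise DegenerateInputError("cannot register constant volumes")

    center = fixed.grid.center_mm
    if init is not None:
        # re-center the initialization on the fixed volume center
        p0 = _params_with_center(init, center)
    else:
        p0 = np.zeros(6)

    # Powell's unbounded line searches can jump into a distant basin (a
    # near-symmetric head registers plausibly at a 180 deg flip), so the
    # search is boxed around the initialization at rigid capture range.
    lo = p0 - np.array([15.0] * 3 + [20.0] * 3)
    hi = p0 + np.array([15.0] * 3 + [20.0] * 3)
    schedule = [(4, 1.0, 8000, 60), (2, 0.5, 25000, 40)]
    params = p0.copy()
    for factor, smooth, ns, maxiter in schedule:
        obj = _MIObjective(_shrink(moving, factor), _shrink(fixed, factor), ns, smooth)
        res = minimize(
            obj,
            params,
            method="Powell",
            bounds=list(zip(lo, hi)),
            options={"xtol": 1e-3, "ftol": 1e-6, "maxiter": maxiter},
        )
        params = res.x

    final_obj = _MIObjective(moving, fixed, n_samples, 0.0)
    if final_obj(params) > final_obj(p0) + 1e-12:
        warnings.warn(
            "registration failed to improve on the initialization; "
            "returning best-found transform — consider apply_manual_correction",
            RegistrationWarning,
            stacklevel=2,
        )
        params = p0
    return RigidTransform(tuple(params[:3]), tuple(params[3:]), tuple(center))


def _params_with_center(t: RigidTransform, center) -> np.ndarray:
    """Re-express a transform with a different rotation center."""
    c = np.asarray(center, dtype=float)
    M = t.matrix
    v = t.apply(np.zeros(3))
    angles = np.asarray(t.rotation_deg)
    trans = v - c + M @ c
    return np.concatenate([angles, trans])


def apply_manual_correction(
    transform: RigidTransform, correction: RigidTransform
) -> RigidTransform:
    """Compose a manual correction on top of an automatic registration.

    Returns ``correction ∘ transform`` (the correction acts in fixed space,
    after the registration).
    """
    return correction.compose(transform)
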