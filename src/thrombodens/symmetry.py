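"""Midsagittal symmetry-plane estimation and mirror mapping of vessel masks.

The plane is parameterized by two tilt angles and an offset along its
normal. It is found by maximizing the normalized cross-correlation between
the volume and its reflection: a coarse grid search on a downsampled volume
followed by Nelder-Mead refinement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize

from .errors import DegenerateInputError, EmptyMaskError, EmptyResultError
from .image_core import Grid, Volume3D, VoxelMask

__all__ = ["SymmetryPlane", "estimate_symmetry_plane", "mirror_mask", "reflect_volume"]


@dataclass
class SymmetryPlane:
    """A plane given by a point (mm) and a unit normal."""

    point_mm: tuple
    normal: tuple

    def __post_init__(self):
        self.point_mm = tuple(float(v) for v in self.point_mm)
        n = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise ValueError("plane normal must be non-zero")
        self.normal = tuple(n / norm)

    def reflect_points(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        n = np.asarray(self.normal)
        d = (pts - np.asarray(self.point_mm)) @ n
        return pts - 2.0 * d[..., None] * n

    def signed_distance(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return (pts - np.asarray(self.point_mm)) @ np.asarray(self.normal)

    def angle_to(self, other: "SymmetryPlane") -> float:
        """Angle between plane normals, degrees (orientation-insensitive)."""
        c = abs(float(np.dot(self.normal, other.normal)))
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _plane_from_params(params, center: np.ndarray) -> SymmetryPlane:
    theta, phi, offset = params
    th, ph = np.deg2rad(theta), np.deg2rad(phi)
    normal = np.array(
        [np.cos(th) * np.cos(ph), np.sin(th) * np.cos(ph), np.sin(ph)]
    )
    return SymmetryPlane(tuple(center + offset * normal), tuple(normal))


def _params_from_plane(plane: SymmetryPlane, center: np.ndarray) -> np.ndarray:
    n = np.asarray(plane.normal)
    if n[0] < 0:
        n = -n
    theta = np.degrees(np.arctan2(n[1], n[0]))
    phi = np.degrees(np.arcsin(np.clip(n[2], -1, 1)))
    offset = float((np.asarray(plane.point_mm) - center) @ n)
    return np.array([theta, phi, offset])


def reflect_volume(volume: Volume3D, plane: SymmetryPlane) -> Volume3D:
    """Resample the volume through the plane reflection (linear interpolation)."""
    grid = volume.grid
    centers = grid.voxel_centers().reshape(-1, 3)
    refl = plane.reflect_points(centers)
    idx = grid.world_to_index(refl).reshape(grid.shape + (3,))
    out = ndimage.map_coordinates(
        volume.voxels.astype(float),
        np.moveaxis(idx, -1, 0),
        order=1,
        mode="constant",
        cval=-1000.0,
    )
    return Volume3D(out, volume.spacing, volume.origin)


def _symmetry_score(volume: Volume3D, plane: SymmetryPlane) -> float:
    """Normalized cross-correlation between the volume and its reflection."""
    a = volume.voxels.ravel()
    refl = reflect_volume(volume, plane).voxels.ravel()
    a = a - a.mean()
    b = refl - refl.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(a @ b / denom)


def _downsample(volume: Volume3D, factor: int) -> Volume3D:
    if factor <= 1:
        return volume
    sigma = [factor / 2.5] * 3
    sm = ndimage.gaussian_filter(volume.voxels.astype(float), sigma=sigma)
    sub = sm[::factor, ::factor, ::factor]
    spacing = tuple(s * factor for s in volume.spacing)
    return Volume3D(sub, spacing, volume.origin)


def estimate_symmetry_plane(
    volume: Volume3D,
    initial_guess: Optional[SymmetryPlane] = None,
    angle_range_deg: float = 10.0,
    offset_range_mm: float = 10.0,
) -> SymmetryPlane:
    """Find the plane maximizing reflective self-similarity of *volume*.

    Coarse grid search (±*angle_range_deg*, ±*offset_range_mm*) on a 4x
    downsampled copy, then local refinement at 2x. Guaranteed to score at
    least as high as *initial_guess* (the guess is a grid candidate).
    """
    if np.ptp(volume.voxels) == 0:
        raise DegenerateInputError("cannot estimate symmetry of a constant volume")
    center = volume.grid.center_mm
    guess = initial_guess or SymmetryPlane(tuple(center), (1.0, 0.0, 0.0))
    p_guess = _params_from_plane(guess, center)

    coarse = _downsample(volume, 4)
    fine = _downsample(volume, 2)

    candidates = [p_guess]
    angles = p_guess[0] + np.linspace(-angle_range_deg, angle_range_deg, 5)
    phis = p_guess[1] + np.linspace(-angle_range_deg, angle_range_deg, 5)
    offsets = p_guess[2] + np.linspace(-offset_range_mm, offset_range_mm, 5)
    for th in angles:
        for ph in phis:
            for off in offsets:
                candidates.append(np.array([th, ph, off]))
    scores = [
        _symmetry_score(coarse, _plane_from_params(p, center)) for p in candidates
    ]
    best = candidates[int(np.argmax(scores))]

    def neg_score(p):
        return -_symmetry_score(fine, _plane_from_params(p, center))

    # explicit initial simplex: the default one collapses for near-zero
    # parameters and cannot walk the few degrees/mm that matter here
    simplex = [np.asarray(best, dtype=float)]
    for step in np.diag([2.0, 2.0, 2.0]):
        simplex.append(np.asarray(best) + step)
    res = minimize(
        neg_score,
        best,
        method="Nelder-Mead",
        options={
            "xatol": 0.05,
            "fatol": 1e-6,
            "maxiter": 200,
            "initial_simplex": np.asarray(simplex),
        },
    )
    refined = res.x if -res.fun >= _symmetry_score(fine, _plane_from_params(best, center)) else best

    # never return a plane scoring below the caller's initial guess
    if _symmetry_score(volume, _plane_from_params(refined, center)) < _symmetry_score(
        volume, guess
    ):
        return guess
    return _plane_from_params(refined, center)


def mirror_mask(
    mask: VoxelMask, plane: SymmetryPlane, dilate_voxels: int = 0
) -> VoxelMask:
    """Reflect a mask about *plane* in world space (nearest-neighbour resample).

    ``dilate_voxels`` optionally grows the result to absorb small anatomical
    asymmetries when the output is used as a search region.
    """
    if mask.n_foreground == 0:
        raise EmptyMaskError("mirror_mask requires a non-empty mask")
    grid = mask.grid
    centers = grid.voxel_centers().reshape(-1, 3)
    # pull-back: output voxel w is foreground iff refl(w) is in the input mask
    src_idx = grid.world_to_index(plane.reflect_points(centers)).reshape(
        grid.shape + (3,)
    )
    out = ndimage.map_coordinates(
        mask.data.astype(np.uint8),
        np.moveaxis(src_idx, -1, 0),
        order=0,
        mode="constant",
        cval=0,
    ).astype(bool)
    if not out.any():
        raise EmptyResultError("reflection falls entirely outside the grid")
    if dilate_voxels > 0:
        out = ndimage.binary_dilation(
            out, structure=ndimage.generate_binary_structure(3, 3), iterations=dilate_voxels
        )
    return VoxelMask(out, grid)
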