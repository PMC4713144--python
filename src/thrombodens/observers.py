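"""Simulated manual 3-spherical-ROI thrombus density measurement.

The observer model places three small spherical ROIs inside the thrombus
mask on NCCT and reports the mean of the three ROI means. Placement is
governed by a bias strength ``beta``: 0 draws centers uniformly at random
from the mask, 1 places them on the three strongest local maxima of a
smoothed copy of the NCCT (hyperdense-seeking behaviour). This is an
explicit behavioural model of observer bias, not a reconstruction of any
human protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence
import warnings

import numpy as np
from scipy import ndimage

from .density import sample_density, summarize
from .errors import MaskTooSmallError
from .image_core import Volume3D, VoxelMask

__all__ = ["ManualMeasurement", "ObserverPolicy", "simulate_manual", "bias_curve"]


@dataclass
class ObserverPolicy:
    """Behavioural parameters of one simulated observer."""

    beta: float = 0.8
    smoothing_fwhm_mm: float = 2.0
    min_separation_mm: float = 2.0
    seed: int = 0
    noise_sd_hu: float = 0.0
    roi_radius_mm: float = 1.0
    observer_id: str = "sim"

    def __post_init__(self):
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")
        if self.min_separation_mm < 0:
            raise ValueError("separation must be >= 0")


@dataclass
class ManualMeasurement:
    observer_id: str
    roi_centers_voxel: tuple
    roi_radius_mm: float
    roi_means_hu: tuple
    overall_hu: float

    def as_dict(self) -> dict:
        return {
            "observer": self.observer_id,
            "roi_radius_mm": self.roi_radius_mm,
            "roi_means_hu": list(self.roi_means_hu),
            "overall_hu": self.overall_hu,
        }


def _sphere_offsets(radius_mm: float, spacing) -> np.ndarray:
    radii = np.maximum(np.floor(radius_mm / np.asarray(spacing)).astype(int), 0)
    ranges = [np.arange(-r, r + 1) for r in radii]
    ii, jj, kk = np.meshgrid(*ranges, indexing="ij")
    off = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    world = off * np.asarray(spacing)
    keep = (world**2).sum(axis=1) <= radius_mm**2 + 1e-9
    return off[keep]


def _roi_mean(ncct: Volume3D, mask: VoxelMask, center: np.ndarray, offsets: np.ndarray) -> float:
    idx = center[None, :] + offsets
    shape = np.asarray(ncct.shape)
    valid = np.all((idx >= 0) & (idx < shape), axis=1)
    idx = idx[valid]
    inside = mask.data[tuple(idx.T)]
    vox = idx[inside]
    if len(vox) == 0:
        return float(ncct.voxels[tuple(center)])
    return float(ncct.voxels[tuple(vox.T)].mean())


def simulate_manual(
    ncct: Volume3D,
    thrombus_on_ncct: VoxelMask,
    policy: ObserverPolicy,
) -> ManualMeasurement:
    """Place three spherical ROIs per *policy* and return their mean density.

    Each ROI mean is taken over the mask-intersected sphere; deterministic
    given the policy seed. If the mask cannot host three ROIs at the
    requested radius/separation, the radius and separation shrink with a
    warning; a mask too small for any sphere raises
    :class:`~thrombodens.errors.MaskTooSmallError`.
    """
    if thrombus_on_ncct.n_foreground < 3:
        raise MaskTooSmallError("thrombus mask cannot host three distinct ROI centers")
    rng = np.random.default_rng(policy.seed)
    grid = thrombus_on_ncct.grid
    spacing = np.asarray(grid.spacing)

    sigma_vox = (policy.smoothing_fwhm_mm / 2.3548) / spacing
    smoothed = ndimage.gaussian_filter(ncct.voxels.astype(float), sigma=sigma_vox)

    candidates = thrombus_on_ncct.foreground_indices()
    values = smoothed[tuple(candidates.T)]
    # beta blends a hyperdense-seeking score with a uniform-random score
    rank = np.argsort(np.argsort(values)) / max(len(values) - 1, 1)
    score = policy.beta * rank + (1.0 - policy.beta) * rng.uniform(size=len(values))

    radius = policy.roi_radius_mm
    separation = policy.min_separation_mm
    order = np.argsort(score)[::-1]
    centers = _greedy_select(candidates, order, spacing, separation)
    while centers is None and separation > 0.25:
        separation *= 0.5
        warnings.warn(
            f"ROI separation shrunk to {separation:.2f} mm to fit the mask",
            stacklevel=2,
        )
        centers = _greedy_select(candidates, order, spacing, separation)
    if centers is None:
        centers = candidates[order[:3]]

    offsets = _sphere_offsets(radius, spacing)
    roi_means = tuple(
        _roi_mean(ncct, thrombus_on_ncct, c, offsets) for c in centers
    )
    overall = float(np.mean(roi_means))
    if policy.noise_sd_hu > 0:
        overall += float(policy.noise_sd_hu * rng.standard_normal())
    return ManualMeasurement(
        observer_id=policy.observer_id,
        roi_centers_voxel=tuple(tuple(int(v) for v in c) for c in centers),
        roi_radius_mm=radius,
        roi_means_hu=roi_means,
        overall_hu=overall,
    )


def _greedy_select(candidates, order, spacing, separation_mm):
    chosen = []
    for k in order:
        c = candidates[k]
        if all(
            np.linalg.norm((c - other) * spacing) >= separation_mm for other in chosen
        ):
            chosen.append(c)
        if len(chosen) == 3:
            return np.asarray(chosen)
    return None


def bias_curve(
    phantoms: Sequence[tuple],
    policy: ObserverPolicy,
) -> list:
    """Manual-vs-median bias across a phantom cohort.

    *phantoms* is a sequence of ``(ncct, thrombus_mask, truth)`` where
    ``truth`` carries the noiseless ground-truth density summary. Returns
    one row per phantom: ``{"true_median_hu", "manual_hu", "median_hu",
    "difference_hu"}`` with ``difference = manual - entire-thrombus
    median``. Correlation statistics are computed downstream by the
    agreement-statistics module.
    """
    if len(phantoms) < 1:
        raise ValueError("need at least one phantom")
    rows = []
    for i, (ncct, mask, truth) in enumerate(phantoms):
        p = ObserverPolicy(
            beta=policy.beta,
            smoothing_fwhm_mm=policy.smoothing_fwhm_mm,
            min_separation_mm=policy.min_separation_mm,
            seed=policy.seed + 1000 * i,
            noise_sd_hu=policy.noise_sd_hu,
            roi_radius_mm=policy.roi_radius_mm,
            observer_id=policy.observer_id,
        )
        manual = simulate_manual(ncct, mask, p)
        measured = summarize(sample_density(ncct, mask))
        true_median = float(truth.true_summary.median_hu)
        rows.append(
            {
                "true_median_hu": true_median,
                "manual_hu": manual.overall_hu,
                "median_hu": measured.median_hu,
                "difference_hu": manual.overall_hu - measured.median_hu,
            }
        )
    return rows
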