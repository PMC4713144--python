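"""Thrombus segmentation on CTA within the symmetry-mapped occluded artery.

Intensity-bounded region growing: seeds are every voxel of the mapped
region whose HU lies inside the bounds; growth proceeds with
26-connectivity through in-bounds voxels, confined to the mapped region
dilated by a leak margin. Isolated noise voxels are removed by a small
binary opening before connectivity analysis, and the largest connected
component touching a seed is retained (ties broken by higher mean HU).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .errors import EmptyMaskError, NoThrombusFoundError
from .image_core import Volume3D, VoxelMask

__all__ = ["segment_thrombus", "DEFAULT_LOWER_HU", "DEFAULT_UPPER_HU"]

DEFAULT_LOWER_HU = 0.0  # excludes air / fat / CSF-like perivascular space
DEFAULT_UPPER_HU = 100.0  # excludes contrast-enhanced (patent) lumen


def _dilate_mm(mask: np.ndarray, spacing, radius_mm: float) -> np.ndarray:
    if radius_mm <= 0:
        return mask
    radii = np.maximum(np.round(radius_mm / np.asarray(spacing)).astype(int), 0)
    if not radii.any():
        return mask
    zz, yy, xx = np.meshgrid(
        *[np.arange(-r, r + 1) for r in radii], indexing="ij"
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        ball = (
            (zz / max(radii[0], 1)) ** 2
            + (yy / max(radii[1], 1)) ** 2
            + (xx / max(radii[2], 1)) ** 2
        ) <= 1.0
    return ndimage.binary_dilation(mask, structure=ball)


def segment_thrombus(
    cta: Volume3D,
    mapped_region: VoxelMask,
    lower: float = DEFAULT_LOWER_HU,
    upper: float = DEFAULT_UPPER_HU,
    max_leak_mm: float = 1.5,
    min_component_voxels: int = 2,
) -> VoxelMask:
    """Segment the thrombus inside the mapped occluded-artery region.

    Every output voxel lies within ``[lower, upper]`` HU and within the
    mapped region dilated by *max_leak_mm*; the output is one 26-connected
    component reachable from seeds inside the mapped region.
    """
    if mapped_region.n_foreground == 0:
        raise EmptyMaskError("mapped region is empty")
    if not lower < upper:
        raise ValueError(f"need lower < upper, got [{lower}, {upper}]")
    if mapped_region.grid.shape != cta.shape:
        raise ValueError("mapped region is not on the CTA grid")

    in_range = (cta.voxels >= lower) & (cta.voxels <= upper)
    seeds = in_range & mapped_region.data
    if not seeds.any():
        raise NoThrombusFoundError(
            f"no voxel of the mapped region lies within [{lower}, {upper}] HU"
        )

    allowed = in_range & _dilate_mm(mapped_region.data, cta.spacing, max_leak_mm)
    # suppress speckle and the thin partial-volume shell that rings the
    # enhanced lumen (it passes through the HU bounds and would otherwise
    # bridge the thrombus to a hollow cylinder along the patent artery)
    opened = ndimage.binary_opening(
        allowed, structure=ndimage.generate_binary_structure(3, 1)
    )
    grow_seeds = seeds & opened
    if not grow_seeds.any():
        grow_seeds = seeds
        opened = opened | seeds

    structure = np.ones((3, 3, 3), dtype=int)
    labels, n_labels = ndimage.label(opened, structure=structure)
    seed_labels = np.unique(labels[grow_seeds])
    seed_labels = seed_labels[seed_labels > 0]
    if seed_labels.size == 0:
        raise NoThrombusFoundError("region growing produced no connected component")

    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=seed_labels)
    order = np.argsort(sizes)[::-1]
    best = seed_labels[order[0]]
    if len(order) > 1 and sizes[order[0]] == sizes[order[1]]:
        # tie: prefer the component with higher mean HU
        tied = seed_labels[order[sizes[order] == sizes[order[0]]]]
        means = ndimage.mean(cta.voxels, labels, index=tied)
        best = tied[int(np.argmax(means))]

    out = labels == best
    if out.sum() < min_component_voxels:
        raise NoThrombusFoundError("largest grown component is below the size floor")
    return VoxelMask(out, cta.grid)
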