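"""Contralateral artery segmentation from two seed points on CTA.

Threshold-constrained region growing from both seeds with 26-connectivity,
intersected with a geodesic tube around the minimal bright path between the
seeds so growth cannot leak into adjacent bright structures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.graph import MCP_Geometric

from .errors import ConnectivityError, SeedError
from .image_core import Volume3D, VoxelMask

__all__ = ["SeedPair", "segment_contralateral", "DEFAULT_LUMEN_THRESHOLD"]

#: Separates contrast-enhanced lumen (~200 HU) from thrombus and parenchyma.
DEFAULT_LUMEN_THRESHOLD = 120.0


@dataclass(frozen=True)
class SeedPair:
    """Proximal and distal voxel coordinates on the contralateral artery."""

    proximal: tuple
    distal: tuple

    def __post_init__(self):
        object.__setattr__(self, "proximal", tuple(int(v) for v in self.proximal))
        object.__setattr__(self, "distal", tuple(int(v) for v in self.distal))

    def validate(self, volume: Volume3D, lumen_threshold: float) -> None:
        for name, seed in (("proximal", self.proximal), ("distal", self.distal)):
            if len(seed) != 3 or any(
                not (0 <= seed[i] < volume.shape[i]) for i in range(3)
            ):
                raise SeedError(f"{name} seed {seed} lies outside the volume")
            if volume.voxels[seed] < lumen_threshold:
                raise SeedError(
                    f"{name} seed {seed} has HU {volume.voxels[seed]:.1f} "
                    f"below the lumen threshold {lumen_threshold:.1f}"
                )


def _minimal_path(volume: Volume3D, above: np.ndarray, seeds: SeedPair) -> np.ndarray:
    """Spacing-aware minimal-cost path between the seeds within the bright region."""
    cost = np.where(above, 1.0, np.inf)
    mcp = MCP_Geometric(cost, sampling=volume.spacing)
    try:
        costs, _ = mcp.find_costs([seeds.proximal], [seeds.distal])
    except Exception as exc:  # pragma: no cover
        raise ConnectivityError(f"path search failed: {exc}") from exc
    if not np.isfinite(costs[seeds.distal]):
        raise ConnectivityError(
            "no connected above-threshold path joins the two seeds"
        )
    path = mcp.traceback(seeds.distal)
    return np.asarray(path, dtype=float)


def segment_contralateral(
    cta: Volume3D,
    seeds: SeedPair,
    lumen_threshold: float = DEFAULT_LUMEN_THRESHOLD,
    max_radius_mm: float = 4.0,
) -> VoxelMask:
    """Segment the patent contralateral artery on CTA.

    Returns the 26-connected component of above-threshold voxels containing
    both seeds, restricted to voxels within *max_radius_mm* (world distance)
    of the minimal path joining the seeds.
    """
    seeds.validate(cta, lumen_threshold)
    above = cta.voxels >= lumen_threshold

    labels, _ = ndimage.label(above, structure=np.ones((3, 3, 3), dtype=int))
    lab_p = labels[seeds.proximal]
    lab_d = labels[seeds.distal]
    if lab_p != lab_d or lab_p == 0:
        raise ConnectivityError(
            "seeds are not 26-connected within the above-threshold region"
        )
    component = labels == lab_p

    path_idx = _minimal_path(cta, above, seeds)
    grid = cta.grid
    path_world = grid.index_to_world(path_idx)
    tree = cKDTree(path_world)
    comp_idx = np.argwhere(component)
    comp_world = grid.index_to_world(comp_idx)
    dist, _ = tree.query(comp_world, k=1, distance_upper_bound=max_radius_mm + 1e-9)
    keep = np.isfinite(dist) & (dist <= max_radius_mm)

    out = np.zeros(cta.shape, dtype=bool)
    out[tuple(comp_idx[keep].T)] = True
    out[seeds.proximal] = True
    out[seeds.distal] = True
    return VoxelMask(out, grid)
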