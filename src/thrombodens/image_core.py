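"""Spatial data model and file I/O for CT volumes, binary masks and rigid transforms.

Conventions
-----------
* Voxel arrays are indexed ``[ix, iy, iz]`` (x fastest-varying on disk).
* Voxel indices are 0-based; world coordinates (mm) are
  ``world = origin + index * spacing`` with axis-aligned grids.
* All geometry (transforms, reflections, distances) is computed in world
  space so anisotropic voxels are handled uniformly.
* A :class:`RigidTransform` maps *moving*-space world points to
  *fixed*-space world points: ``y = R @ (x - c) + c + t``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .errors import EmptyMaskError, EmptyResultError, FormatError, MetadataError

__all__ = [
    "Grid",
    "Volume3D",
    "VoxelMask",
    "RigidTransform",
    "read_volume",
    "write_volume",
    "read_transform",
    "write_transform",
    "apply_transform",
    "resample_volume",
]


@dataclass(frozen=True)
class Grid:
    """Sampling lattice of a volume: shape, spacing (mm/voxel) and origin (mm)."""

    shape: tuple
    spacing: tuple
    origin: tuple

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise ValueError(f"grid shape must be 3 positive ints, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def index_to_world(self, indices) -> np.ndarray:
        """Map (N, 3) voxel indices (may be fractional) to world mm."""
        idx = np.asarray(indices, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def world_to_index(self, points) -> np.ndarray:
        """Map (N, 3) world mm points to (fractional) voxel indices."""
        pts = np.asarray(points, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of all voxel centers, shape ``shape + (3,)``."""
        idx = np.stack(
            np.meshgrid(*[np.arange(n) for n in self.shape], indexing="ij"), axis=-1
        ).astype(float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    @property
    def center_mm(self) -> np.ndarray:
        return self.index_to_world((np.asarray(self.shape, float) - 1.0) / 2.0)


@dataclass
class Volume3D:
    """A 3D scalar field of HU values on a regular anisotropic grid."""

    voxels: np.ndarray
    spacing: tuple
    origin: tuple = (0.0, 0.0, 0.0)
    orientation: str = "RAS"

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValueError("voxels must be a non-empty 3D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise MetadataError(f"spacing components must be > 0, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("HU values must be finite")

    @property
    def grid(self) -> Grid:
        return Grid(self.voxels.shape, self.spacing, self.origin)

    @property
    def shape(self) -> tuple:
        return self.voxels.shape


@dataclass
class VoxelMask:
    """A binary region on the grid of an associated :class:`Volume3D`."""

    data: np.ndarray
    grid: Grid

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        if self.data.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {self.data.shape} != grid shape {self.grid.shape}"
            )

    @property
    def n_foreground(self) -> int:
        return int(self.data.sum())

    @property
    def volume_mm3(self) -> float:
        return self.n_foreground * self.grid.voxel_volume_mm3

    def foreground_indices(self) -> np.ndarray:
        return np.argwhere(self.data)

    def foreground_world(self) -> np.ndarray:
        return self.grid.index_to_world(self.foreground_indices())

    def centroid_mm(self) -> np.ndarray:
        if self.n_foreground == 0:
            raise EmptyMaskError("cannot compute centroid of an empty mask")
        return self.foreground_world().mean(axis=0)


@dataclass
class RigidTransform:
    """6-DOF rigid mapping ``y = R(angles) @ (x - center) + center + translation``.

    Angles are extrinsic x-y-z Euler rotations in degrees; translation and
    the rotation center are in mm.
    """

    rotation_deg: tuple = (0.0, 0.0, 0.0)
    translation_mm: tuple = (0.0, 0.0, 0.0)
    center_mm: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.rotation_deg = tuple(float(a) for a in self.rotation_deg)
        self.translation_mm = tuple(float(t) for t in self.translation_mm)
        self.center_mm = tuple(float(c) for c in self.center_mm)

    @property
    def matrix(self) -> np.ndarray:
        return Rotation.from_euler("xyz", self.rotation_deg, degrees=True).as_matrix()

    def apply(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        c = np.asarray(self.center_mm)
        t = np.asarray(self.translation_mm)
        return (pts - c) @ self.matrix.T + c + t

    def inverse(self) -> "RigidTransform":
        R = self.matrix
        angles = Rotation.from_matrix(R.T).as_euler("xyz", degrees=True)
        t_inv = -R.T @ np.asarray(self.translation_mm)
        return RigidTransform(tuple(angles), tuple(t_inv), self.center_mm)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply *other* first, then *self*)."""
        M = self.matrix @ other.matrix
        # affine offset of f(x) = Mx + v
        v = self.apply(other.apply(np.zeros(3)))
        c = np.asarray(self.center_mm)
        angles = Rotation.from_matrix(M).as_euler("xyz", degrees=True)
        t = v - c + M @ c
        return RigidTransform(tuple(angles), tuple(t), tuple(c))

    @property
    def is_identity(self) -> bool:
        return np.allclose(self.rotation_deg, 0) and np.allclose(self.translation_mm, 0)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_METAIMAGE_DTYPES = {
    "MET_UCHAR": np.uint8,
    "MET_CHAR": np.int8,
    "MET_SHORT": np.int16,
    "MET_USHORT": np.uint16,
    "MET_INT": np.int32,
    "MET_UINT": np.uint32,
    "MET_FLOAT": np.float32,
    "MET_DOUBLE": np.float64,
}
_METAIMAGE_NAMES = {v: k for k, v in _METAIMAGE_DTYPES.items()}


def _read_metaimage(path: str) -> Volume3D:
    header = {}
    with open(path, "rb") as fh:
        while True:
            line = fh.readline()
            if not line:
                raise FormatError(f"{path}: truncated MetaImage header")
            key, _, value = line.decode("ascii", "replace").partition("=")
            key, value = key.strip(), value.strip()
            header[key] = value
            if key == "ElementDataFile":
                break
        if header.get("ObjectType", "Image") != "Image" or header.get("NDims") != "3":
            raise FormatError(f"{path}: not a 3D MetaImage volume")
        if "ElementSpacing" not in header:
            raise MetadataError(f"{path}: ElementSpacing missing from header")
        dtype = _METAIMAGE_DTYPES.get(header.get("ElementType", ""))
        if dtype is None:
            raise FormatError(f"{path}: unsupported ElementType {header.get('ElementType')}")
        shape = tuple(int(v) for v in header["DimSize"].split())
        spacing = tuple(float(v) for v in header["ElementSpacing"].split())
        origin = tuple(float(v) for v in header.get("Offset", "0 0 0").split())
        datafile = header["ElementDataFile"]
        if datafile == "LOCAL":
            raw = fh.read()
        else:
            with open(os.path.join(os.path.dirname(path), datafile), "rb") as df:
                raw = df.read()
    n = int(np.prod(shape))
    arr = np.frombuffer(raw, dtype=dtype, count=n)
    big_endian = header.get("BinaryDataByteOrderMSB", header.get("ElementByteOrderMSB", "False"))
    if big_endian.lower() == "true":
        arr = arr.byteswap()
    # MetaImage raw data is x-fastest: stored shape is (z, y, x)
    voxels = arr.reshape(shape[::-1]).transpose(2, 1, 0)
    return Volume3D(voxels.copy(), spacing, origin)


def _write_metaimage(volume: Volume3D, path: str) -> None:
    dtype = volume.voxels.dtype
    if dtype.type not in _METAIMAGE_NAMES:
        if np.issubdtype(dtype, np.integer):
            dtype = np.dtype(np.int32)
        elif dtype == bool:
            dtype = np.dtype(np.uint8)
        else:
            dtype = np.dtype(np.float64)
    data = np.ascontiguousarray(volume.voxels.astype(dtype.type).transpose(2, 1, 0))
    local = path.endswith(".mha")
    lines = [
        "ObjectType = Image",
        "NDims = 3",
        "BinaryData = True",
        "BinaryDataByteOrderMSB = False",
        "CompressedData = False",
        "TransformMatrix = 1 0 0 0 1 0 0 0 1",
        "Offset = " + " ".join(f"{o:.10g}" for o in volume.origin),
        "ElementSpacing = " + " ".join(f"{s:.10g}" for s in volume.spacing),
        "DimSize = " + " ".join(str(s) for s in volume.shape),
        "ElementType = " + _METAIMAGE_NAMES[dtype.type],
    ]
    if local:
        lines.append("ElementDataFile = LOCAL")
        with open(path, "wb") as fh:
            fh.write(("\n".join(lines) + "\n").encode("ascii"))
            fh.write(data.tobytes())
    else:
        rawname = os.path.basename(path)[:-4] + ".raw"
        lines.append(f"ElementDataFile = {rawname}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
        with open(os.path.join(os.path.dirname(path) or ".", rawname), "wb") as fh:
            fh.write(data.tobytes())


def read_volume(path: str) -> Volume3D:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) volume."""
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    lower = path.lower()
    if lower.endswith((".mha", ".mhd")):
        return _read_metaimage(path)
    if lower.endswith((".nii", ".nii.gz")):
        try:
            img = nib.load(path)
        except Exception as exc:  # pragma: no cover - nibabel error paths
            raise FormatError(f"cannot read {path}: {exc}") from exc
        zooms = img.header.get_zooms()[:3]
        if any(z <= 0 for z in zooms):
            raise MetadataError(f"{path}: non-positive voxel spacing in header")
        data = np.asanyarray(img.dataobj)
        origin = tuple(float(v) for v in img.affine[:3, 3])
        return Volume3D(np.asarray(data), tuple(float(z) for z in zooms), origin)
    raise FormatError(f"unsupported volume format: {path}")


def write_volume(volume: Volume3D, path: str) -> str:
    """Write a volume; format chosen from the file extension. Returns *path*."""
    lower = path.lower()
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent):
        raise IOError(f"parent directory does not exist: {parent}")
    if lower.endswith((".mha", ".mhd")):
        _write_metaimage(volume, path)
        return path
    if lower.endswith((".nii", ".nii.gz")):
        data = volume.voxels
        if data.dtype == bool:
            data = data.astype(np.uint8)
        affine = np.eye(4)
        affine[0, 0], affine[1, 1], affine[2, 2] = volume.spacing
        affine[:3, 3] = volume.origin
        img = nib.Nifti1Image(data, affine)
        img.header.set_zooms(volume.spacing)
        nib.save(img, path)
        return path
    raise FormatError(f"unsupported volume format: {path}")


def write_transform(transform: RigidTransform, path: str) -> str:
    """Serialize a rigid transform as plain-text ``key: values`` lines."""
    with open(path, "w") as fh:
        fh.write("rotation_deg: " + " ".join(f"{a:.12g}" for a in transform.rotation_deg) + "\n")
        fh.write("translation_mm: " + " ".join(f"{t:.12g}" for t in transform.translation_mm) + "\n")
        fh.write("center_mm: " + " ".join(f"{c:.12g}" for c in transform.center_mm) + "\n")
    return path


def read_transform(path: str) -> RigidTransform:
    values = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, rest = line.partition(":")
            values[key.strip()] = tuple(float(v) for v in rest.split())
    try:
        return RigidTransform(
            values["rotation_deg"], values["translation_mm"], values["center_mm"]
        )
    except KeyError as exc:
        raise FormatError(f"{path}: missing transform field {exc}") from exc


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------


def _source_indices(source_grid: Grid, transform: RigidTransform, target_grid: Grid):
    """Fractional source-grid indices for every target voxel center.

    ``transform`` maps source world -> target world, so each target center is
    pulled back through the inverse.
    """
    centers = target_grid.voxel_centers().reshape(-1, 3)
    src_world = transform.inverse().apply(centers)
    idx = source_grid.world_to_index(src_world)
    return idx.reshape(target_grid.shape + (3,))


def apply_transform(
    mask: VoxelMask, transform: RigidTransform, target_grid: Grid
) -> VoxelMask:
    """Resample *mask* onto *target_grid* through a rigid transform.

    Nearest-neighbour interpolation preserves the binary labels.
    """
    if mask.n_foreground == 0:
        raise EmptyMaskError("apply_transform requires a non-empty mask")
    if transform.is_identity and mask.grid == target_grid:
        return VoxelMask(mask.data.copy(), target_grid)
    idx = _source_indices(mask.grid, transform, target_grid)
    coords = np.moveaxis(idx, -1, 0)
    out = ndimage.map_coordinates(
        mask.data.astype(np.uint8), coords, order=0, mode="constant", cval=0
    ).astype(bool)
    if not out.any():
        raise EmptyResultError("transform maps the entire mask outside the target grid")
    return VoxelMask(out, target_grid)


def resample_volume(
    volume: Volume3D,
    transform: RigidTransform,
    target_grid: Grid,
    order: int = 1,
    cval: float = -1000.0,
) -> Volume3D:
    """Resample a volume onto *target_grid* (linear interpolation by default)."""
    idx = _source_indices(volume.grid, transform, target_grid)
    coords = np.moveaxis(idx, -1, 0)
    out = ndimage.map_coordinates(
        volume.voxels.astype(float), coords, order=order, mode="constant", cval=cval
    )
    return Volume3D(out, target_grid.spacing, target_grid.origin)
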