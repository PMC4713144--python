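"""Paired CTA/NCCT head phantoms with known thrombus density ground truth.

The scene is defined analytically in world coordinates: a brain ellipsoid in
air, a curved contrast-enhanced artery in one hemisphere, its mirror image
about a known symmetry plane on the other side, and an occluding thrombus
along an arc of the mirrored vessel. Both vessels run inside a low-density
perivascular sheath (the cisternal CSF that surrounds real intracranial
arteries). Each output grid is rasterized by evaluating the scene at
(rigidly transformed) voxel centers, so the CTA and NCCT volumes are exact
resamplings of the same anatomy under a known misalignment.

Thrombus voxel densities are drawn from a configurable Gaussian-mixture
model whose component label varies smoothly in space, so the heterogeneity
is locally coherent rather than voxelwise white. The mixture is built from
two material pools — a low-attenuation (fibrin/platelet-like) and a
high-attenuation (red-cell-like) component — and low-density thrombi are
realized with a small admixture of dense material (right-skewed
distributions), which is what makes maxima-seeking manual ROIs overshoot
low-density thrombi most.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.interpolate import splev, splprep
from scipy.optimize import brentq, least_squares
from scipy.spatial import cKDTree
from scipy.stats import norm

from .density import DensitySample, DensitySummary, summarize
from .errors import SpecError
from .image_core import Grid, RigidTransform, Volume3D, VoxelMask

__all__ = ["PhantomSpec", "PhantomTruth", "generate_phantom", "sample_cohort_specs"]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

# Default one-hemisphere centerline control points, mm relative to the grid
# center, entirely on the negative-x side of the default midsagittal plane.
_DEFAULT_CENTERLINE = (
    (-6.0, -10.0, -26.0),
    (-10.0, -6.0, -15.0),
    (-16.0, 0.0, -6.0),
    (-23.0, 7.0, 3.0),
    (-29.0, 14.0, 11.0),
)


@dataclass
class PhantomSpec:
    """Full parameterization of one paired CTA/NCCT phantom."""

    shape: tuple = (96, 96, 96)
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)
    background_hu: float = 35.0
    blood_hu: float = 45.0
    sheath_hu: float = -10.0
    sheath_thickness_mm: float = 3.0
    lumen_enhancement_hu: float = 165.0
    vessel_radius_mm: float = 3.5
    centerline_mm: tuple = _DEFAULT_CENTERLINE  # relative to grid center, mm
    thrombus_arc: tuple = (0.35, 0.65)
    # (weight, mean HU, SD HU) per mixture component
    density_components: tuple = ((1.0, 45.0, 5.0),)
    label_correlation_mm: float = 8.0
    texture_amplitude_hu: float = 8.0
    noise_sd: float = 5.0
    blur_fwhm_mm: float = 0.8
    misalignment: Optional[RigidTransform] = None
    symmetry_tilt_deg: float = 0.0  # tilt of the true plane about the z axis
    symmetry_offset_mm: float = 0.0  # offset of the plane along its normal
    seed: int = 0
    # bookkeeping for cohort sampling
    target_median_hu: Optional[float] = None
    target_iqr_hu: Optional[float] = None

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        weights = [c[0] for c in self.density_components]
        if abs(sum(weights) - 1.0) > 1e-9:
            raise SpecError(f"mixture weights must sum to 1, got {sum(weights)}")
        if any(w < 0 for w in weights) or any(c[2] < 0 for c in self.density_components):
            raise SpecError("mixture weights and SDs must be non-negative")
        t0, t1 = self.thrombus_arc
        if not (0.0 <= t0 < t1 <= 1.0):
            raise SpecError(f"thrombus arc must satisfy 0 <= start < end <= 1, got {self.thrombus_arc}")
        if self.noise_sd < 0:
            raise SpecError("noise SD must be >= 0")
        if self.spacing[2] > 2.5:
            raise SpecError(
                f"slice spacing {self.spacing[2]} mm exceeds the 2.5 mm inclusion limit"
            )

    @property
    def grid(self) -> Grid:
        return Grid(self.shape, self.spacing, self.origin)

    def symmetry_plane(self) -> tuple:
        """True plane as ``(point_mm, unit_normal)``."""
        tilt = np.deg2rad(self.symmetry_tilt_deg)
        normal = np.array([np.cos(tilt), np.sin(tilt), 0.0])
        point = self.grid.center_mm + self.symmetry_offset_mm * normal
        return point, normal


@dataclass
class PhantomTruth:
    """Ground truth record accompanying one generated phantom pair."""

    cta_thrombus_mask: VoxelMask
    ncct_thrombus_mask: VoxelMask
    contralateral_mask: VoxelMask
    occluded_tree_mask: VoxelMask
    misalignment: RigidTransform
    symmetry_point_mm: np.ndarray
    symmetry_normal: np.ndarray
    thrombus_values_hu: np.ndarray  # noiseless per-voxel draws on the NCCT grid
    true_summary: DensitySummary
    seed_points_voxel: tuple  # suggested (proximal, distal) contralateral seeds
    centerline_world_mm: np.ndarray = None  # contralateral centerline samples
    centerline_param: np.ndarray = None  # arclength fraction per sample
    seed_params: tuple = (0.08, 0.92)  # arc fractions of the suggested seeds


def _reflect_points(points: np.ndarray, point: np.ndarray, normal: np.ndarray) -> np.ndarray:
    d = (points - point) @ normal
    return points - 2.0 * d[:, None] * normal[None, :]


def _cosine_field(points: np.ndarray, seed_key, n_waves: int, wavelength_mm: float) -> np.ndarray:
    """Deterministic smooth random field: sum of random-phase plane cosines.

    Defined in world coordinates so it is consistent across resampled grids.
    """
    rng = np.random.default_rng(seed_key)
    dirs = rng.standard_normal((n_waves, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    wl = wavelength_mm * rng.uniform(0.7, 1.4, size=n_waves)
    phases = rng.uniform(0, 2 * np.pi, size=n_waves)
    out = np.zeros(len(points))
    for k in range(n_waves):
        out += np.cos(points @ (2 * np.pi / wl[k] * dirs[k]) + phases[k])
    return out / np.sqrt(n_waves)


class _Scene:
    """Analytic anatomy shared by both modalities of one phantom."""

    def __init__(self, spec: PhantomSpec):
        self.spec = spec
        grid = spec.grid
        self.center = grid.center_mm
        extent = (np.asarray(grid.shape) - 1) * np.asarray(grid.spacing)
        # anisotropic on purpose: a spherical head leaves rotation unobservable
        self.semi_axes = np.array([0.38, 0.46, 0.42]) * extent
        self.plane_point, self.plane_normal = spec.symmetry_plane()
        # the scene is built in a canonical frame whose symmetry plane is the
        # x-midplane; a rotation+offset maps world points into that frame so
        # the whole head (ellipsoid included) honors a tilted/offset plane
        tilt = np.deg2rad(spec.symmetry_tilt_deg)
        self._rot = np.array(
            [
                [np.cos(tilt), -np.sin(tilt), 0.0],
                [np.sin(tilt), np.cos(tilt), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        self._off = spec.symmetry_offset_mm * self.plane_normal

        ctrl = np.asarray(spec.centerline_mm, dtype=float) + self.center
        tck, _ = splprep(ctrl.T, s=0, k=min(3, len(ctrl) - 1))
        u = np.linspace(0, 1, 600)
        self.contra_pts = np.stack(splev(u, tck), axis=1)
        # arclength parameterization in [0, 1]
        seg = np.linalg.norm(np.diff(self.contra_pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        self.contra_param = s / s[-1]
        self.arc_length_mm = float(s[-1])
        # geometry lives in the canonical frame: mirror about the x-midplane
        self.occl_pts = _reflect_points(
            self.contra_pts, np.asarray(self.center), np.array([1.0, 0.0, 0.0])
        )
        self.contra_tree = cKDTree(self.contra_pts)
        self.occl_tree = cKDTree(self.occl_pts)

        if self.contra_param[-1] <= 0:
            raise SpecError("degenerate centerline")
        t0, t1 = spec.thrombus_arc
        if t1 > 1.0 or t0 < 0.0:
            raise SpecError("thrombus arc outside the vessel extent")

    def _tube_query(self, points: np.ndarray, tree: cKDTree, pts: np.ndarray, radius: float):
        """Distance to a centerline within *radius*, +inf elsewhere (bbox-pruned)."""
        dist = np.full(len(points), np.inf)
        idx = np.zeros(len(points), dtype=int)
        lo = pts.min(axis=0) - radius - 1.0
        hi = pts.max(axis=0) + radius + 1.0
        box = np.all((points >= lo) & (points <= hi), axis=1)
        if box.any():
            d, i = tree.query(points[box], k=1, distance_upper_bound=radius + 1.0)
            dist[box] = d
            valid = np.isfinite(d)
            sub = idx[box]
            sub[valid] = i[valid]
            idx[box] = sub
        return dist, idx

    def to_canonical(self, points: np.ndarray) -> np.ndarray:
        c = np.asarray(self.center)
        return (points - c - self._off) @ self._rot + c

    def from_canonical(self, points: np.ndarray) -> np.ndarray:
        c = np.asarray(self.center)
        return (points - c) @ self._rot.T + c + self._off

    def classify(self, world_points: np.ndarray) -> dict:
        """Label every world point with its anatomical compartment."""
        spec = self.spec
        points = self.to_canonical(world_points)
        rel = (points - self.center) / self.semi_axes
        brain = (rel**2).sum(axis=1) <= 1.0
        r = spec.vessel_radius_mm
        r_out = r + spec.sheath_thickness_mm

        d_con, _ = self._tube_query(points, self.contra_tree, self.contra_pts, r_out)
        d_occ, i_occ = self._tube_query(points, self.occl_tree, self.occl_pts, r_out)

        contra_lumen = brain & (d_con <= r)
        occl_lumen = brain & (d_occ <= r)
        t0, t1 = spec.thrombus_arc
        param = self.contra_param[i_occ]
        thrombus = occl_lumen & (param >= t0) & (param <= t1)
        sheath = brain & ((d_con <= r_out) | (d_occ <= r_out)) & ~contra_lumen & ~occl_lumen
        return {
            "brain": brain,
            "contra_lumen": contra_lumen,
            "occl_lumen": occl_lumen,
            "thrombus": thrombus,
            "sheath": sheath,
            "param": param,
        }

    def thrombus_labels(
        self, points: np.ndarray, thrombus: np.ndarray, param: np.ndarray
    ) -> np.ndarray:
        """Mixture-component index per thrombus voxel via a smooth label field.

        The field varies along the vessel axis only (layered composition, in
        the spirit of the laminated structure of real thrombi), so component
        patches meet at small cross-sectional interfaces instead of large 3D
        surfaces. Thresholding the field at its own empirical quantiles makes
        the realized component proportions match the mixture weights exactly.
        """
        spec = self.spec
        comps = spec.density_components
        labels = np.zeros(int(thrombus.sum()), dtype=int)
        if len(comps) > 1:
            axial_mm = param[thrombus] * self.arc_length_mm
            coords = np.column_stack(
                [axial_mm, np.zeros_like(axial_mm), np.zeros_like(axial_mm)]
            )
            g = _cosine_field(
                coords, [spec.seed, 2], 10, 2.5 * spec.label_correlation_mm
            )
            order = np.argsort(np.argsort(g, kind="stable"), kind="stable")
            cum = np.cumsum([c[0] for c in comps])
            edges = np.floor(cum[:-1] * len(g)).astype(int)
            labels = np.searchsorted(edges, order, side="right")
        return labels


def _blur_sigmas_voxels(spec: PhantomSpec) -> Optional[np.ndarray]:
    if spec.blur_fwhm_mm <= 0:
        return None
    s_iso = spec.blur_fwhm_mm * _FWHM_TO_SIGMA
    s_slice = spec.spacing[2] * _FWHM_TO_SIGMA
    sig_mm = np.array([s_iso, s_iso, np.hypot(s_iso, s_slice)])
    return sig_mm / np.asarray(spec.spacing)


def generate_phantom(spec: PhantomSpec):
    """Generate ``(cta, ncct, truth)`` for one phantom specification.

    The CTA is rasterized on the spec grid; the NCCT is the same anatomy
    observed through the spec's rigid misalignment (identity if ``None``).
    Blur and noise are applied per modality in the scanner frame.
    """
    spec.validate()
    scene = _Scene(spec)
    grid = spec.grid
    misalign = spec.misalignment or RigidTransform(center_mm=tuple(grid.center_mm))

    centers = grid.voxel_centers().reshape(-1, 3)

    # ----- CTA: anatomy in its own frame ---------------------------------
    cls = scene.classify(centers)
    texture = spec.texture_amplitude_hu * _cosine_field(centers, [spec.seed, 1], 6, 24.0)
    comps = np.asarray(spec.density_components, dtype=float)

    cta = np.full(len(centers), -1000.0)
    cta[cls["brain"]] = spec.background_hu + texture[cls["brain"]]
    cta[cls["sheath"]] = spec.sheath_hu
    lumen_hu = spec.background_hu + spec.lumen_enhancement_hu
    cta[cls["contra_lumen"]] = lumen_hu
    cta[cls["occl_lumen"]] = lumen_hu
    labels_cta = scene.thrombus_labels(centers, cls["thrombus"], cls["param"])
    cta[cls["thrombus"]] = comps[labels_cta, 1]  # filling defect at component mean

    # ----- NCCT: same anatomy observed through the misalignment ----------
    ncct_points = misalign.inverse().apply(centers)
    ncls = scene.classify(ncct_points)
    ntexture = spec.texture_amplitude_hu * _cosine_field(ncct_points, [spec.seed, 1], 6, 24.0)

    ncct = np.full(len(centers), -1000.0)
    ncct[ncls["brain"]] = spec.background_hu + ntexture[ncls["brain"]]
    ncct[ncls["sheath"]] = spec.sheath_hu
    ncct[ncls["contra_lumen"]] = spec.blood_hu
    ncct[ncls["occl_lumen"]] = spec.blood_hu
    labels_ncct = scene.thrombus_labels(ncct_points, ncls["thrombus"], ncls["param"])
    draw_rng = np.random.default_rng([spec.seed, 3])
    draws = comps[labels_ncct, 1] + comps[labels_ncct, 2] * draw_rng.standard_normal(
        len(labels_ncct)
    )
    ncct[ncls["thrombus"]] = draws

    cta = cta.reshape(grid.shape)
    ncct = ncct.reshape(grid.shape)

    sig = _blur_sigmas_voxels(spec)
    if sig is not None:
        cta = ndimage.gaussian_filter(cta, sigma=sig)
        ncct = ndimage.gaussian_filter(ncct, sigma=sig)
    if spec.noise_sd > 0:
        noise_rng = np.random.default_rng([spec.seed, 4])
        cta = cta + spec.noise_sd * noise_rng.standard_normal(cta.shape)
        ncct = ncct + spec.noise_sd * noise_rng.standard_normal(ncct.shape)

    cta_vol = Volume3D(cta, spec.spacing, spec.origin)
    ncct_vol = Volume3D(ncct, spec.spacing, spec.origin)

    # ----- ground truth ---------------------------------------------------
    shape = grid.shape
    cta_thrombus = VoxelMask(cls["thrombus"].reshape(shape), grid)
    ncct_thrombus = VoxelMask(ncls["thrombus"].reshape(shape), grid)
    contralateral = VoxelMask(cls["contra_lumen"].reshape(shape), grid)
    occluded_tree = VoxelMask(cls["occl_lumen"].reshape(shape), grid)

    truth_sample = DensitySample(draws, grid.voxel_volume_mm3)
    seeds = _suggest_seeds(scene, grid)
    truth = PhantomTruth(
        cta_thrombus_mask=cta_thrombus,
        ncct_thrombus_mask=ncct_thrombus,
        contralateral_mask=contralateral,
        occluded_tree_mask=occluded_tree,
        misalignment=misalign,
        symmetry_point_mm=scene.plane_point,
        symmetry_normal=scene.plane_normal,
        thrombus_values_hu=draws,
        true_summary=summarize(truth_sample),
        seed_points_voxel=seeds,
        centerline_world_mm=scene.from_canonical(scene.contra_pts),
        centerline_param=scene.contra_param.copy(),
    )
    return cta_vol, ncct_vol, truth


def _suggest_seeds(scene: _Scene, grid: Grid) -> tuple:
    """Voxel coordinates near both ends of the contralateral centerline."""
    seeds = []
    for frac in (0.08, 0.92):
        k = int(np.argmin(np.abs(scene.contra_param - frac)))
        world = scene.from_canonical(scene.contra_pts[k][None, :])[0]
        idx = np.round(grid.world_to_index(world)).astype(int)
        idx = np.clip(idx, 0, np.asarray(grid.shape) - 1)
        seeds.append(tuple(int(v) for v in idx))
    return tuple(seeds)


# ---------------------------------------------------------------------------
# Cohort sampling
# ---------------------------------------------------------------------------


def _mixture_quantile(q, a, b, p, s):
    lo = min(a, b) - 8 * s
    hi = max(a, b) + 8 * s

    def cdf(x):
        return p * norm.cdf((x - a) / s) + (1 - p) * norm.cdf((x - b) / s) - q

    return brentq(cdf, lo, hi)


def _component_sd(delta: float) -> float:
    # SD grows with component separation so the mixture never develops an
    # empty density gap at its median (a gap makes the empirical median of a
    # finite voxel sample unstable by tens of HU)
    return max(4.0, 0.30 * delta)


def _solve_mixture(median_hu: float, iqr_hu: float) -> tuple:
    """Two-component mixture hitting a target median and IQR.

    The weight of the low component follows a soft prior that decreases with
    the target median: low-density thrombi are mostly low-attenuation
    material with a minority of dense patches (right-skewed), high-density
    thrombi the reverse.
    """
    p0 = float(np.clip(0.85 - 0.65 * (median_hu - 20.0) / 44.0, 0.2, 0.85))

    def residuals(x):
        a, delta, p = x
        b = a + delta
        s = _component_sd(delta)
        med = _mixture_quantile(0.5, a, b, p, s)
        q1 = _mixture_quantile(0.25, a, b, p, s)
        q3 = _mixture_quantile(0.75, a, b, p, s)
        return [med - median_hu, (q3 - q1) - iqr_hu, 12.0 * (p - p0)]

    x0 = [
        float(np.clip(median_hu - iqr_hu / 2.0, 5.0, 90.0)),
        float(np.clip(iqr_hu, 0.5, 90.0)),
        float(np.clip(p0, 0.12, 0.88)),
    ]
    res = least_squares(
        residuals,
        x0,
        bounds=([5.0, 0.5, 0.12], [90.0, 90.0, 0.88]),
        xtol=1e-10,
        ftol=1e-10,
    )
    a, delta, p = res.x
    s = _component_sd(delta)
    return (
        (float(p), float(a), s),
        (float(1 - p), float(a + delta), s),
    )


def sample_cohort_specs(n: int, seed: int, **overrides) -> list:
    """Draw *n* phantom specs spanning the cohort's density range.

    Target medians are uniform on [20, 64] HU and target IQRs uniform on
    [9, 56] HU, realized through two-component mixture parameters; the
    CTA-to-NCCT misalignment is uniform within ±5° / ±5 mm. Deterministic
    given *seed*.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n):
        median = float(rng.uniform(20.0, 64.0))
        iqr = float(rng.uniform(9.0, 56.0))
        comps = _solve_mixture(median, iqr)
        rot = tuple(rng.uniform(-5.0, 5.0, size=3))
        trans = tuple(rng.uniform(-5.0, 5.0, size=3))
        base = PhantomSpec(**overrides) if overrides else PhantomSpec()
        grid_center = tuple(base.grid.center_mm)
        spec = replace(
            base,
            density_components=comps,
            misalignment=RigidTransform(rot, trans, grid_center),
            seed=int(rng.integers(0, 2**31 - 1)),
            target_median_hu=median,
            target_iqr_hu=iqr,
        )
        specs.append(spec)
    return specs
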