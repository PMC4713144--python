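import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thrombodens.errors import EmptyMaskError, EmptyResultError, FormatError
from thrombodens.image_core import (
    Grid,
    RigidTransform,
    Volume3D,
    VoxelMask,
    apply_transform,
    read_transform,
    read_volume,
    write_transform,
    write_volume,
)

from conftest import dice


def _random_volume(seed=0, shape=(10, 10, 10), spacing=(0.5, 0.5, 1.0)):
    rng = np.random.default_rng(seed)
    vox = rng.integers(-1000, 1000, size=shape).astype(np.int16)
    return Volume3D(vox, spacing, origin=(1.0, -2.0, 3.0))


class TestVolumeIO:
    def test_constant_volume_roundtrip_nifti(self, tmp_path):
        vol = Volume3D(np.full((10, 10, 10), 50, dtype=np.int16), (1, 1, 1))
        path = write_volume(vol, str(tmp_path / "v.nii.gz"))
        back = read_volume(path)
        np.testing.assert_array_equal(back.voxels, vol.voxels)
        assert back.spacing == vol.spacing

    @pytest.mark.parametrize("ext", ["nii", "nii.gz", "mha", "mhd"])
    def test_integer_roundtrip_lossless(self, tmp_path, ext):
        vol = _random_volume()
        back = read_volume(write_volume(vol, str(tmp_path / f"v.{ext}")))
        np.testing.assert_array_equal(back.voxels, vol.voxels)

    def test_spacing_header_roundtrip(self, tmp_path):
        vol = Volume3D(np.zeros((4, 5, 6)), (0.5, 0.5, 1.0))
        back = read_volume(write_volume(vol, str(tmp_path / "v.nii.gz")))
        assert back.spacing == (0.5, 0.5, 1.0)

    def test_origin_roundtrip(self, tmp_path):
        vol = _random_volume()
        for ext in ("nii.gz", "mha"):
            back = read_volume(write_volume(vol, str(tmp_path / f"o.{ext}")))
            np.testing.assert_allclose(back.origin, vol.origin, atol=1e-6)

    def test_cross_format_identity(self, tmp_path):
        """MetaImage -> read -> NIfTI -> read gives voxelwise identical HU."""
        vol = _random_volume(seed=3)
        via_mha = read_volume(write_volume(vol, str(tmp_path / "v.mha")))
        via_nii = read_volume(write_volume(via_mha, str(tmp_path / "v.nii.gz")))
        assert np.abs(via_nii.voxels - vol.voxels).max() == 0

    def test_mask_roundtrip_preserves_count(self, tmp_path):
        rng = np.random.default_rng(1)
        mask = rng.random((8, 8, 8)) > 0.7
        vol = Volume3D(mask.astype(np.uint8), (1, 1, 1))
        back = read_volume(write_volume(vol, str(tmp_path / "m.nii.gz")))
        assert (back.voxels > 0).sum() == mask.sum()

    def test_unreadable_file_raises(self, tmp_path):
        bad = tmp_path / "bad.mha"
        bad.write_text("not a header")
        with pytest.raises(FormatError):
            read_volume(str(bad))
        with pytest.raises(FormatError):
            read_volume(str(tmp_path / "missing.nii.gz"))

    def test_unsupported_extension(self, tmp_path):
        with pytest.raises(FormatError):
            write_volume(_random_volume(), str(tmp_path / "v.png"))


class TestTransform:
    def test_text_roundtrip(self, tmp_path):
        t = RigidTransform((1.5, -2.0, 3.0), (0.1, 0.2, -0.3), (10, 20, 30))
        back = read_transform(write_transform(t, str(tmp_path / "t.txt")))
        np.testing.assert_allclose(back.rotation_deg, t.rotation_deg)
        np.testing.assert_allclose(back.translation_mm, t.translation_mm)
        np.testing.assert_allclose(back.center_mm, t.center_mm)

    @settings(max_examples=25, deadline=None)
    @given(
        rot=st.tuples(*[st.floats(-45, 45) for _ in range(3)]),
        trans=st.tuples(*[st.floats(-20, 20) for _ in range(3)]),
    )
    def test_inverse_composition_is_identity(self, rot, trans):
        t = RigidTransform(rot, trans, (5.0, 6.0, 7.0))
        comp = t.compose(t.inverse())
        pts = np.random.default_rng(0).uniform(-50, 50, (10, 3))
        np.testing.assert_allclose(comp.apply(pts), pts, atol=1e-6)

    def test_apply_matches_affine_definition(self):
        t = RigidTransform((0, 0, 90), (1, 2, 3), (0, 0, 0))
        out = t.apply([[1.0, 0.0, 0.0]])
        np.testing.assert_allclose(out, [[1.0, 3.0, 3.0]], atol=1e-12)

    def test_compose_order(self):
        a = RigidTransform((0, 0, 90), (0, 0, 0), (0, 0, 0))
        b = RigidTransform((0, 0, 0), (1, 0, 0), (0, 0, 0))
        pts = np.array([[0.0, 0.0, 0.0]])
        np.testing.assert_allclose(
            a.compose(b).apply(pts), a.apply(b.apply(pts)), atol=1e-12
        )


class TestMask:
    def test_voxel_volume_exact(self):
        grid = Grid((5, 5, 5), (0.5, 0.7, 2.0), (0, 0, 0))
        data = np.zeros((5, 5, 5), bool)
        data[1:3, 1:4, 2] = True
        mask = VoxelMask(data, grid)
        assert mask.volume_mm3 == mask.n_foreground * 0.5 * 0.7 * 2.0

    def test_shape_mismatch_rejected(self):
        grid = Grid((5, 5, 5), (1, 1, 1), (0, 0, 0))
        with pytest.raises(ValueError):
            VoxelMask(np.zeros((4, 5, 5), bool), grid)


class TestApplyTransform:
    @staticmethod
    def _blob_mask(shape=(32, 32, 32), spacing=(1.0, 1.0, 1.0)):
        grid = Grid(shape, spacing, (0, 0, 0))
        data = np.zeros(shape, bool)
        data[10:21, 11:21, 12:22] = True  # ~1000 voxels, away from borders
        return VoxelMask(data, grid)

    def test_identity_same_grid(self):
        mask = self._blob_mask()
        out = apply_transform(mask, RigidTransform(), mask.grid)
        np.testing.assert_array_equal(out.data, mask.data)

    def test_lattice_aligned_shift(self):
        mask = self._blob_mask(spacing=(0.5, 1.0, 2.0))
        t = RigidTransform(translation_mm=(0.5, 0.0, 0.0))  # one voxel in x
        out = apply_transform(mask, t, mask.grid)
        np.testing.assert_array_equal(out.data[1:], mask.data[:-1])

    def test_inverse_composition_dice(self):
        mask = self._blob_mask()
        t = RigidTransform((4.0, -3.0, 2.0), (2.5, -1.5, 3.0), (15.5, 15.5, 15.5))
        fwd = apply_transform(mask, t, mask.grid)
        back = apply_transform(fwd, t.inverse(), mask.grid)
        assert dice(back.data, mask.data) >= 0.9

    def test_moderate_transform_count_stability(self):
        mask = self._blob_mask()
        t = RigidTransform((5.0, 5.0, 5.0), (5.0, -5.0, 5.0), (15.5, 15.5, 15.5))
        out = apply_transform(mask, t, mask.grid)
        change = abs(out.n_foreground - mask.n_foreground) / mask.n_foreground
        assert change < 0.2

    def test_empty_mask_rejected(self):
        grid = Grid((8, 8, 8), (1, 1, 1), (0, 0, 0))
        with pytest.raises(EmptyMaskError):
            apply_transform(VoxelMask(np.zeros((8, 8, 8), bool), grid), RigidTransform(), grid)

    def test_mask_mapped_outside_grid(self):
        mask = self._blob_mask()
        t = RigidTransform(translation_mm=(500.0, 0.0, 0.0))
        with pytest.raises(EmptyResultError):
            apply_transform(mask, t, mask.grid)
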