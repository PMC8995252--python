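import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from oculodce.core_io import Mask, RigidTransform, VolumeImage
from oculodce.motion import (
    make_eye_mask,
    propagate_mask,
    register_rigid,
    register_secondary,
    resample_volume,
)
from oculodce.phantom import PhantomSpec, _apply_motion, build_phantom
from oculodce.relaxometry import spgr_signal


@pytest.fixture(scope="module")
def anat():
    """A static anatomical frame of the phantom plus its geometry."""
    spec = PhantomSpec(shape=(48, 42, 20), noise_sigma=0.0, seed=5)
    truth = build_phantom(spec)
    base = spgr_signal(truth.m0.values, truth.t1_ms.values, truth.b1.as_fraction() * 13.0, 4.53)
    return spec, truth, truth.grid.with_values(base)


def _rot_err_deg(a: RigidTransform, b: RigidTransform) -> float:
    return float(np.rad2deg(np.linalg.norm(Rotation.from_matrix(a.matrix @ b.matrix.T).as_rotvec())))


class TestEyeMask:
    def test_volume_matches_analytic_sphere(self):
        ref = VolumeImage(np.zeros((64, 53, 21)), (1.25, 1.5, 1.5))
        center = ref.world_center()
        mask = make_eye_mask(ref, center, 11.0, 2.0)
        analytic = 4 / 3 * np.pi * 13.0**3 / np.prod(ref.spacing)
        assert mask.n_voxels == pytest.approx(analytic, rel=0.05)

    def test_subvoxel_radius_keeps_center_voxel(self):
        ref = VolumeImage(np.zeros((9, 9, 9)), (2.0, 2.0, 2.0))
        mask = make_eye_mask(ref, ref.world_center(), 0.1, 0.0)
        assert mask.n_voxels >= 1

    def test_partial_overlap_clipped_but_nonempty(self):
        ref = VolumeImage(np.zeros((10, 10, 10)), (1.0, 1.0, 1.0))
        mask = make_eye_mask(ref, (0.0, 0.0, -3.0), 5.0, 0.0)
        assert 0 < mask.n_voxels < 4 / 3 * np.pi * 125

    def test_disjoint_sphere_rejected(self):
        ref = VolumeImage(np.zeros((10, 10, 10)), (1.0, 1.0, 1.0))
        with pytest.raises(ValueError):
            make_eye_mask(ref, (500.0, 0.0, 0.0), 2.0, 0.0)


class TestRegisterRigid:
    def test_self_registration_is_identity(self, anat):
        _, _, vol = anat
        tf = register_rigid(vol, vol)
        assert np.abs(tf.translation_mm).max() < 0.05 * 1.25
        assert np.abs(tf.rotation_deg).max() < 0.1

    def test_known_shift_recovered(self, anat):
        spec, truth, vol = anat
        c_eye = spec.resolved_eye_center()
        shift = RigidTransform(translation_mm=(2 * spec.spacing[0], 0, 0), center_mm=vol.world_center())
        moved = vol.with_values(
            _apply_motion(vol.values, vol, shift, RigidTransform.identity(c_eye), c_eye, spec.eye_radius_mm)
        )
        rec = register_rigid(moved, vol)
        assert abs(rec.translation_mm[0] - 2.5) < 0.2 * 1.25
        assert np.abs(rec.translation_mm[1:]).max() < 0.2 * 1.5

    def test_masked_resolves_eye_rotation_unmasked_does_not(self, anat):
        spec, truth, vol = anat
        c_eye = spec.resolved_eye_center()
        rot = RigidTransform(rotation_deg=(0, 0, 10), center_mm=c_eye)
        moved = vol.with_values(
            _apply_motion(vol.values, vol, RigidTransform.identity(), rot, c_eye, spec.eye_radius_mm)
        )
        unmasked = register_rigid(moved, vol)
        assert _rot_err_deg(unmasked, RigidTransform.identity()) < 10.0  # eye motion invisible
        mask = make_eye_mask(vol, c_eye, spec.eye_radius_mm, 2.0)
        masked = register_rigid(moved, vol, mask=mask, center_mm=c_eye)
        assert _rot_err_deg(masked, rot) < 0.5

    def test_constant_image_falls_back_to_identity(self):
        flat = VolumeImage(np.ones((12, 12, 8)), (1, 1, 1))
        tf = register_rigid(flat, flat.with_values(np.ones((12, 12, 8))))
        assert tf.is_identity(1e-9, 1e-9)

    def test_empty_mask_rejected(self, anat):
        _, _, vol = anat
        empty = Mask(vol.with_values(np.zeros(vol.shape, np.uint8)), "eye")
        with pytest.raises(ValueError):
            register_rigid(vol, vol, mask=empty)


class TestSecondaryRegistration:
    def test_aligned_volume_gives_identity(self, anat):
        spec, truth, vol = anat
        mask = make_eye_mask(vol, spec.resolved_eye_center(), spec.eye_radius_mm, 2.0)
        tf = register_secondary(vol, vol, mask)
        assert np.abs(tf.translation_mm).max() < 0.1
        assert np.abs(tf.rotation_deg).max() < 0.2

    def test_shifted_anatomy_recovered_within_tolerance(self, anat):
        spec, truth, vol = anat
        c_eye = spec.resolved_eye_center()
        shift = RigidTransform(translation_mm=(1.5, 0, 0), center_mm=c_eye)
        moved = vol.with_values(
            _apply_motion(vol.values, vol, shift, RigidTransform.identity(c_eye), c_eye, spec.eye_radius_mm)
        )
        mask = make_eye_mask(vol, c_eye, spec.eye_radius_mm, 2.0)
        tf = register_secondary(moved, vol, mask)
        assert abs(tf.translation_mm[0] - 1.5) < 0.3

    def test_coarser_grid_resampled_onto_reference(self, anat):
        spec, truth, vol = anat
        coarse = VolumeImage(np.ones((20, 16, 8)), (2.0, 2.0, 2.0))
        out = resample_volume(coarse, RigidTransform.identity(), vol)
        assert out.shape == vol.shape
        assert out.same_geometry(vol)


class TestMaskPropagation:
    def _cuboid_mask(self, grid):
        vals = np.zeros(grid.shape, np.uint8)
        vals[10:20, 10:18, 5:12] = 1
        return Mask(grid.with_values(vals), "lesion")

    def test_identity_same_grid_is_noop(self, anat):
        _, _, vol = anat
        mask = self._cuboid_mask(vol)
        out = propagate_mask(mask, RigidTransform.identity(), vol)
        np.testing.assert_array_equal(out.values, mask.values)

    def test_on_grid_translation_preserves_voxel_count(self, anat):
        _, _, vol = anat
        mask = self._cuboid_mask(vol)
        tf = RigidTransform(translation_mm=(vol.spacing[0], 0, 0))
        out = propagate_mask(mask, tf, vol)
        assert out.n_voxels == mask.n_voxels

    def test_cross_grid_propagation_dice(self):
        # lesion drawn on a 1 mm anatomical grid, mapped to the dynamic grid
        spec = PhantomSpec(shape=(48, 42, 20), seed=6)
        truth = build_phantom(spec)
        anat_grid = VolumeImage(
            np.zeros((60, 63, 30)), (1.0, 1.0, 1.0), origin=truth.grid.origin
        )
        idx = np.indices(anat_grid.shape).reshape(3, -1).T
        world = anat_grid.index_to_world(idx)
        # rasterize the same lesion ball on the anatomical grid
        c = spec.resolved_eye_center()
        p = spec.lesion_prominence_mm
        a = spec.lesion_basal_diameter_mm / 2.0
        r_l = (a**2 + p**2) / (2 * p)
        lc = c + np.array([spec.eye_radius_mm + r_l - p, 0.0, 0.0])
        inside = (np.linalg.norm(world - lc, axis=1) <= r_l) & (
            np.linalg.norm(world - c, axis=1) <= spec.eye_radius_mm
        )
        anat_mask = Mask(anat_grid.with_values(inside.reshape(anat_grid.shape).astype(np.uint8)), "lesion")
        out = propagate_mask(anat_mask, RigidTransform.identity(), truth.grid)
        truth_sel = truth.lesion_mask.as_bool()
        got = out.as_bool()
        dice = 2 * (got & truth_sel).sum() / (got.sum() + truth_sel.sum())
        assert dice >= 0.85


class TestSingleResampling:
    def test_double_resampling_is_distinguishable(self, anat):
        # the test can discriminate once- vs twice-interpolated frames:
        # composing T then T^-1 through two resamplings blurs the image
        spec, truth, vol = anat
        tf = RigidTransform(translation_mm=(0.6, 0.4, 0.3), rotation_deg=(0, 0, 3), center_mm=vol.world_center())
        once = resample_volume(vol, tf, vol)
        twice = resample_volume(resample_volume(vol, tf, vol), tf.inverse(), vol)
        diff = np.abs(twice.values - vol.values)[4:-4, 4:-4, 4:-4]
        assert diff.mean() > 0
        half = resample_volume(vol, tf.inverse().compose(tf), vol)  # single equivalent resample
        np.testing.assert_allclose(half.values, vol.values, atol=1e-9)


def test_default_reference_is_50th_timepoint():
    # 125-frame series: the default reference index is 49 (0-based)
    from oculodce.motion import correct_series

    grid = VolumeImage(np.zeros((4, 4, 2)), (1, 1, 1))
    rng = np.random.default_rng(0)
    frames = [grid.with_values(rng.random((4, 4, 2))) for _ in range(125)]
    from oculodce.core_io import DynamicSeries

    series = DynamicSeries(frames, np.arange(125) * 2.0)
    mask = Mask(grid.with_values(np.ones((4, 4, 2), np.uint8)), "eye")
    # skip both steps: only the bookkeeping (ref choice, identity transforms) runs
    corrected, result = correct_series(series, mask, skip_full_fov=True, skip_masked=True)
    assert result.ref_index == 49
    assert result.transforms[49].is_identity(1e-9, 1e-9)
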