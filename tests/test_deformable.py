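"""Mutual information metric and rigid/BSpline registration stages."""

import numpy as np
import pytest
import SimpleITK as sitk

from historeg.core import (
    BSplineTransform,
    LandmarkSet,
    Volume,
    identity_transform,
    rotation_z,
    translation,
)
from historeg.deformable import (
    RegistrationSettings,
    _bspline_from_sitk,
    mutual_information,
    register_bspline,
    register_deformable,
    register_rigid,
)
from historeg.io import volume_to_sitk

FAST = RegistrationSettings(
    rigid_shrink=(4, 2, 1),
    rigid_sigmas_mm=(2.0, 1.0, 0.0),
    rigid_iterations=60,
    bspline_shrink=(2,),
    bspline_sigmas_mm=(1.0,),
    bspline_iterations=15,
    control_spacing_mm=15.0,
)


def blob_scene(points: np.ndarray, contrast: str = "a") -> np.ndarray:
    """Smooth multi-blob test scene; the two contrasts are related by a
    non-affine intensity relationship (what MI is for)."""
    centers = np.array([[0, 0, 0], [10, 5, -4], [-8, 6, 7], [4, -11, 3], [-5, -6, -9]], float)
    widths = np.array([12.0, 6.0, 5.0, 7.0, 5.5])
    amps = np.array([1.0, 0.8, 0.7, 0.9, 0.6])
    val = np.zeros(len(points))
    for c, w, a in zip(centers, widths, amps):
        val += a * np.exp(-((points - c) ** 2).sum(axis=1) / (2 * w**2))
    if contrast == "b":
        val = 1.5 - val + 0.3 * val**2
    return val


def scene_volume(transform=None, shape=(44, 44, 44), spacing=1.4, contrast="a") -> Volume:
    n = np.asarray(shape)
    origin = -(n - 1) * spacing / 2.0
    vol = Volume(np.zeros(shape), np.full(3, spacing), origin)
    nx, ny, nz = shape
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    pts = vol.voxel_to_world(np.stack([ii, jj, kk], -1).reshape(-1, 3).astype(float))
    if transform is not None:
        pts = transform(pts)
    return vol.geometry_like(blob_scene(pts, contrast).reshape(shape))


@pytest.fixture(scope="module")
def fixed_scene():
    return scene_volume()


class TestMutualInformation:
    def test_self_information_equals_marginal_entropy(self, fixed_scene):
        """MI(I, I) is the entropy of I's binned intensity distribution."""
        mi = mutual_information(fixed_scene, fixed_scene, None, bins=32)
        v = fixed_scene.voxels.ravel()
        lo, hi = np.percentile(v, [0.5, 99.5])
        idx = np.clip(np.floor((v - lo) / (hi - lo) * 32).astype(int), 0, 31)
        p = np.bincount(idx, minlength=32) / idx.size
        entropy = -(p[p > 0] * np.log(p[p > 0])).sum()
        assert mi == pytest.approx(entropy, abs=1e-9)
        assert mi > 0

    def test_independent_noise_has_near_zero_mi(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = Volume(rng.uniform(size=(32, 32, 32)), (1, 1, 1), (0, 0, 0))
            b = Volume(rng.uniform(size=(32, 32, 32)), (1, 1, 1), (0, 0, 0))
            assert mutual_information(a, b, None, bins=32) < 0.05

    def test_invariant_under_linear_intensity_remap(self, fixed_scene):
        remapped = fixed_scene.geometry_like(3.0 * fixed_scene.voxels + 2.0)
        mi0 = mutual_information(fixed_scene, fixed_scene)
        mi1 = mutual_information(fixed_scene, remapped)
        assert mi1 == pytest.approx(mi0, abs=1e-9)

    def test_nonnegative_and_alignment_sensitive(self, fixed_scene):
        # moving(q) = scene(q - 4ex): anatomy at p sits at q = p + 4ex, so
        # the correct pull-back is the +4 mm translation
        truth = translation((4.0, 0, 0))
        moved = scene_volume(truth.inverse(), contrast="b")
        mi_misaligned = mutual_information(fixed_scene, moved, None)
        mi_aligned = mutual_information(fixed_scene, moved, truth)
        assert 0 <= mi_misaligned < mi_aligned

    def test_no_overlap_rejected(self, fixed_scene):
        far = Volume(np.ones((8, 8, 8)), (1, 1, 1), (500, 500, 500))
        with pytest.raises(ValueError, match="overlap"):
            mutual_information(fixed_scene, far)

    def test_constant_images_warn_and_return_zero(self):
        a = Volume(np.full((8, 8, 8), 2.0), (1, 1, 1), (0, 0, 0))
        with pytest.warns(UserWarning, match="constant"):
            assert mutual_information(a, a) == 0.0


class TestRigidRegistration:
    def test_self_registration_is_identity(self, fixed_scene):
        res = register_rigid(fixed_scene, fixed_scene, FAST)
        assert np.linalg.norm(res.transform.translation) < 0.1
        angle = np.degrees(np.arccos(np.clip((np.trace(res.transform.matrix) - 1) / 2, -1, 1)))
        assert angle < 0.1

    def test_known_shift_recovered(self, fixed_scene):
        truth = translation((2.0, -1.0, 0.0))
        moving = scene_volume(truth.inverse(), contrast="b")
        res = register_rigid(fixed_scene, moving, FAST)
        np.testing.assert_allclose(res.transform.translation, truth.translation, atol=0.2)

    def test_known_rotation_recovered(self, fixed_scene):
        truth = rotation_z(5.0)
        moving = scene_volume(truth.inverse(), contrast="b")
        res = register_rigid(fixed_scene, moving, FAST)
        rec = np.degrees(np.arctan2(res.transform.matrix[1, 0], res.transform.matrix[0, 0]))
        assert rec == pytest.approx(5.0, abs=0.5)

    def test_deterministic_across_runs(self, fixed_scene):
        moving = scene_volume(translation((1.0, 0.5, -0.5)), contrast="b")
        r1 = register_rigid(fixed_scene, moving, FAST)
        r2 = register_rigid(fixed_scene, moving, FAST)
        np.testing.assert_array_equal(r1.transform.matrix, r2.transform.matrix)
        np.testing.assert_array_equal(r1.transform.translation, r2.transform.translation)

    def test_disjoint_volumes_rejected(self, fixed_scene):
        far = Volume(np.ones((8, 8, 8)), (1, 1, 1), (500, 500, 500))
        with pytest.raises(ValueError, match="overlap"):
            register_rigid(fixed_scene, far, FAST)


class TestBSplineRegistration:
    def test_zero_deformation_truth_keeps_small_lattice(self, fixed_scene):
        moving = scene_volume(contrast="b")
        res = register_bspline(fixed_scene, moving, identity_transform(), FAST)
        assert res.mi_final >= res.mi_initial
        if res.accepted:
            field = res.transform.children[0]
            assert isinstance(field, BSplineTransform)
            assert field.max_control_displacement < 0.5

    def test_refinement_reduces_phantom_target_error(self, study_default, workflow_default):
        """On the default phantom (fixation shrink + 2 mm free-form truth)
        the BSpline refinement lowers the held-out target TRE below the
        rigid initialization's."""
        from historeg.core import CompositeTransform
        from historeg.workflow import step_tre_distances

        step2 = workflow_default.step2
        assert step2.accepted
        assert step2.mi_final >= step2.mi_initial
        assert isinstance(step2.transform, CompositeTransform)
        field, rigid_init = step2.transform.children
        assert isinstance(field, BSplineTransform)
        d_rigid = step_tre_distances(study_default, workflow_default.step1, rigid_init)
        d_final = step_tre_distances(study_default, workflow_default.step1, step2.transform)
        key = "exvivo vs invivo"
        assert np.median(d_final[key]) < np.median(d_rigid[key])

    def test_control_spacing_guard(self, fixed_scene):
        bad = RegistrationSettings(control_spacing_mm=2.0)
        with pytest.raises(ValueError, match="control-point spacing"):
            register_bspline(fixed_scene, fixed_scene, identity_transform(), bad)


class TestSitkFieldConversion:
    def test_converted_lattice_matches_sitk_pointwise(self, fixed_scene):
        """The package's free-form field evaluation reproduces the ITK
        BSpline transform it was converted from."""
        img = sitk.Cast(volume_to_sitk(fixed_scene), sitk.sitkFloat32)
        btx = sitk.BSplineTransformInitializer(img, [4, 3, 5])
        rng = np.random.default_rng(3)
        params = rng.uniform(-2.0, 2.0, len(btx.GetParameters()))
        btx.SetParameters(tuple(params))
        ours = _bspline_from_sitk(btx)
        pts = rng.uniform(-25, 25, (200, 3))
        theirs = np.array([btx.TransformPoint(tuple(p)) for p in pts])
        np.testing.assert_allclose(ours(pts), theirs, atol=1e-6)


class TestFallback:
    def test_landmark_affine_rescue_triggers_on_large_residual(self, fixed_scene):
        """When the automatic result disagrees with the fiducials by more
        than the threshold, the landmark least-squares affine takes over."""
        rng = np.random.default_rng(5)
        pts = rng.uniform(-12, 12, (6, 3))
        labels = [f"f{i}" for i in range(6)]
        offset = np.array([12.0, 0.0, 0.0])  # fiducials say: moving frame is 12 mm away
        fixed_lms = LandmarkSet(pts, labels, "fixed")
        moving_lms = LandmarkSet(pts + offset, labels, "moving")
        with pytest.warns(UserWarning, match="landmark"):
            res = register_deformable(
                fixed_scene, fixed_scene, FAST, fixed_landmarks=fixed_lms, moving_landmarks=moving_lms
            )
        assert res.used_fallback
        np.testing.assert_allclose(res.transform.translation, offset, atol=1e-6)

    def test_no_fallback_when_consistent(self, fixed_scene):
        rng = np.random.default_rng(6)
        pts = rng.uniform(-12, 12, (6, 3))
        labels = [f"f{i}" for i in range(6)]
        lms = LandmarkSet(pts, labels, "fixed")
        res = register_deformable(
            fixed_scene, fixed_scene, FAST, fixed_landmarks=lms, moving_landmarks=lms
        )
        assert not res.used_fallback
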