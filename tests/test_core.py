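"""Transform algebra, world geometry, and resampling contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from historeg.core import (
    AffineTransform,
    BSplineTransform,
    CompositeTransform,
    LandmarkSet,
    Volume,
    apply_to_points,
    compose,
    identity_transform,
    resample,
    rotation_z,
    similarity_2d,
    transform_from_dict,
    transform_to_dict,
    translation,
)
from tests.conftest import random_volume


def random_affine(rng, dim=3, scale_range=(0.7, 1.4)):
    m = rng.normal(size=(dim, dim)) * 0.3 + np.eye(dim) * rng.uniform(*scale_range)
    t = rng.uniform(-5, 5, dim)
    return AffineTransform(m, t)


class TestVolumeGeometry:
    def test_world_voxel_round_trip(self, rng):
        for _ in range(20):
            spacing = rng.uniform(0.2, 3.0, 3)
            origin = rng.uniform(-50, 50, 3)
            theta = rng.uniform(0, 2 * np.pi)
            c, s = np.cos(theta), np.sin(theta)
            direction = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
            vol = Volume(np.zeros((4, 5, 6)), spacing, origin, direction)
            idx = rng.uniform(-3, 8, size=(40, 3))
            back = vol.world_to_voxel(vol.voxel_to_world(idx))
            np.testing.assert_allclose(back, idx, atol=1e-9)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            Volume(np.zeros((3, 3, 3)), (1.0, 0.0, 1.0), (0, 0, 0))
        with pytest.raises(ValueError, match="orthonormal"):
            Volume(np.zeros((3, 3, 3)), (1, 1, 1), (0, 0, 0), np.eye(3) + 0.1)


class TestAffine:
    def test_kind_classification(self):
        assert translation((1, 2, 3)).kind == "rigid"
        assert rotation_z(30).kind == "rigid"
        assert similarity_2d(15, 2.0, (0, 0)).kind == "similarity"
        shear = AffineTransform(np.array([[1.0, 0.3], [0.0, 1.0]]), np.zeros(2))
        assert shear.kind == "affine"

    def test_singular_matrix_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            AffineTransform(np.zeros((3, 3)), np.zeros(3))

    def test_inverse(self, rng):
        t = random_affine(rng)
        pts = rng.uniform(-20, 20, (50, 3))
        np.testing.assert_allclose(t.inverse()(t(pts)), pts, atol=1e-9)


class TestCompose:
    def test_identity_is_neutral(self, rng):
        t = random_affine(rng)
        p = rng.uniform(-10, 10, (10, 3))
        np.testing.assert_allclose(compose(t, identity_transform())(p), t(p), atol=1e-12)
        np.testing.assert_allclose(compose(identity_transform(), t)(p), t(p), atol=1e-12)

    def test_translation_additivity(self):
        t = compose(translation((1, 0, 0)), translation((0, 2, 0)))
        np.testing.assert_allclose(t(np.zeros(3)), [1, 2, 0], atol=1e-12)

    def test_pointwise_equals_two_step(self, rng):
        outer, inner = random_affine(rng), random_affine(rng)
        pts = rng.uniform(-30, 30, (100, 3))
        np.testing.assert_allclose(compose(outer, inner)(pts), outer(inner(pts)), atol=1e-9)

    def test_affine_pair_collapses_but_nonlinear_stays_composite(self, rng):
        a, b = random_affine(rng), random_affine(rng)
        assert isinstance(compose(a, b), AffineTransform)
        bsp = BSplineTransform(np.zeros((4, 4, 4, 3)), (0, 0, 0), (10, 10, 10))
        assert isinstance(compose(a, bsp), CompositeTransform)

    def test_associativity(self, rng):
        a, b, c = (random_affine(rng) for _ in range(3))
        pts = rng.uniform(-20, 20, (50, 3))
        left = compose(compose(a, b), c)
        right = compose(a, compose(b, c))
        np.testing.assert_allclose(left(pts), right(pts), atol=1e-9)


class TestApplyToPoints:
    def test_identity_and_translation(self):
        lm = LandmarkSet([[0.0, 0.0, 0.0], [1.0, 1.0, 1.0]], ["a", "b"], "s")
        same = apply_to_points(identity_transform(), lm)
        assert same.labels == ["a", "b"]
        np.testing.assert_array_equal(same.points, lm.points)
        moved = apply_to_points(translation((3, 4, 0)), lm)
        np.testing.assert_allclose(moved.points[0], [3, 4, 0], atol=1e-12)

    def test_similarity_doubles_pairwise_distances(self, rng):
        pts = rng.uniform(-5, 5, (8, 2))
        lm = LandmarkSet(pts, [str(i) for i in range(8)], "s")
        doubled = apply_to_points(similarity_2d(0.0, 2.0, (0, 0)), lm)
        d0 = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        d1 = np.linalg.norm(doubled.points[:, None] - doubled.points[None, :], axis=-1)
        np.testing.assert_allclose(d1, 2 * d0, atol=1e-9)

    def test_dimension_mismatch_raises(self):
        lm = LandmarkSet([[0.0, 0.0]], ["a"], "s")
        with pytest.raises(ValueError, match="2D"):
            apply_to_points(identity_transform(3), lm)


class TestBSplineField:
    def test_zero_lattice_is_identity(self, rng):
        t = BSplineTransform(np.zeros((5, 6, 7, 3)), (-10, -10, -10), (8, 8, 8))
        pts = rng.uniform(-40, 60, (1000, 3))
        np.testing.assert_allclose(t(pts), pts, atol=1e-12)

    def test_partition_of_unity_and_central_weight(self):
        # all-ones lattice: interior displacement is exactly 1 (weights sum to 1)
        control = np.zeros((8, 8, 8, 3))
        control[..., 0] = 1.0
        t = BSplineTransform(control, (0, 0, 0), (1, 1, 1))
        pts = np.random.default_rng(0).uniform(2.0, 5.0, (200, 3))
        np.testing.assert_allclose(t.displacement(pts)[:, 0], 1.0, atol=1e-12)
        # lone unit displacement: value at that control point is the tensor
        # product of the cubic B-spline central weight 2/3
        lone = np.zeros((8, 8, 8, 3))
        lone[4, 4, 4, 1] = 1.0
        t2 = BSplineTransform(lone, (0, 0, 0), (1, 1, 1))
        d = t2.displacement(np.array([[4.0, 4.0, 4.0]]))[0]
        np.testing.assert_allclose(d[1], (2.0 / 3.0) ** 3, atol=1e-12)
        assert d[0] == 0.0 and d[2] == 0.0

    def test_fast_and_padded_paths_agree(self, rng):
        control = rng.normal(size=(6, 5, 7, 3))
        t = BSplineTransform(control, (-4, -3, -5), (3, 4, 5))
        pts = rng.uniform(-20, 40, (500, 3))
        np.testing.assert_allclose(t.displacement(pts), t._displacement_padded(pts), atol=1e-12)


class TestResample:
    def test_identity_nearest_is_bit_exact(self, rng):
        vol = random_volume(rng)
        out = resample(vol, identity_transform(), vol, "nearest")
        np.testing.assert_array_equal(out.voxels, vol.voxels)
        out_lin = resample(vol, identity_transform(), vol, "linear")
        np.testing.assert_allclose(out_lin.voxels, vol.voxels, atol=1e-6)

    def test_one_voxel_translation_shifts_indices(self, rng):
        vol = random_volume(rng, spacing=(2.0, 1.0, 1.0))
        # pull-back by +one spacing along axis 0: output[i] = input[i+1]
        out = resample(vol, translation((2.0, 0, 0)), vol, "linear", fill=-7.0)
        np.testing.assert_allclose(out.voxels[:-1], vol.voxels[1:], atol=1e-9)
        np.testing.assert_allclose(out.voxels[-1], -7.0)

    def test_constant_volume_invariance(self, rng):
        vol = Volume(np.full((12, 12, 12), 3.5), (1, 1, 1), (0, 0, 0))
        t = AffineTransform(np.eye(3) * 0.9, (0.3, 0.2, 0.1))
        ref = Volume(np.zeros((6, 6, 6)), (1, 1, 1), (3, 3, 3))
        out = resample(vol, t, ref, "linear", fill=0.0)
        np.testing.assert_allclose(out.voxels, 3.5, atol=1e-9)

    def test_linearity_in_intensities(self, rng, smooth_volume):
        other = smooth_volume.geometry_like(rng.normal(size=smooth_volume.shape))
        t = AffineTransform(np.eye(3), (0.4, -0.7, 1.1))
        a, b = 2.0, -0.5
        combo = smooth_volume.geometry_like(a * smooth_volume.voxels + b * other.voxels)
        lhs = resample(combo, t, smooth_volume, "linear")
        rhs = (
            a * resample(smooth_volume, t, smooth_volume, "linear").voxels
            + b * resample(other, t, smooth_volume, "linear").voxels
        )
        np.testing.assert_allclose(lhs.voxels, rhs, atol=1e-6)

    def test_output_has_reference_geometry(self, rng, smooth_volume):
        ref = Volume(np.zeros((5, 6, 7)), (2.0, 2.0, 2.0), (-3.0, 0.0, 2.0))
        out = resample(smooth_volume, identity_transform(), ref)
        assert out.same_geometry(ref)

    def test_unknown_interpolation_rejected(self, smooth_volume):
        with pytest.raises(ValueError, match="interpolation"):
            resample(smooth_volume, identity_transform(), smooth_volume, "cubic")


class TestSerialization:
    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_transform_json_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        t = random_affine(rng)
        bsp = BSplineTransform(rng.normal(size=(4, 5, 6, 3)), rng.uniform(-5, 5, 3), rng.uniform(2, 9, 3))
        comp = CompositeTransform([bsp, t])
        pts = rng.uniform(-15, 15, (20, 3))
        for original in (t, bsp, comp):
            back = transform_from_dict(transform_to_dict(original))
            np.testing.assert_allclose(back(pts), original(pts), atol=1e-12)

    def test_landmark_set_validation(self):
        with pytest.raises(ValueError, match="duplicate"):
            LandmarkSet([[0, 0], [1, 1]], ["a", "a"], "s")
        with pytest.raises(ValueError, match="finite"):
            LandmarkSet([[0, np.nan]], ["a"], "s")
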