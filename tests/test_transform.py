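"""Geometry core: rigid transforms, TPS fields, backward maps, tiled warps."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.interpolate import RBFInterpolator

from histostack.transform import (
    DeformationField,
    RigidTransform2D,
    assemble_tiles,
    build_backward_map,
    interpolate_volume,
    scale_deformable,
    scale_rigid,
    tps_evaluate,
    tps_fit,
    warp_image,
    warp_tiled,
    wrap_angle,
)

angles = st.floats(-720, 720, allow_nan=False)
shifts = st.floats(-100, 100, allow_nan=False)


class TestRigid:
    def test_apply_matches_matrix(self, rng):
        t = RigidTransform2D(theta=33.0, tx=4.0, ty=-2.5, center=(10.0, 20.0))
        pts = rng.uniform(-50, 50, (20, 2))
        hom = np.column_stack([pts, np.ones(len(pts))])
        expected = (t.as_matrix() @ hom.T).T[:, :2]
        np.testing.assert_allclose(t.apply(pts), expected, atol=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(theta=angles, tx=shifts, ty=shifts, cx=shifts, cy=shifts)
    def test_inverse_roundtrip(self, theta, tx, ty, cx, cy):
        t = RigidTransform2D(theta, tx, ty, (cx, cy))
        p = np.array([[3.0, -7.0], [0.0, 0.0], [11.5, 2.25]])
        np.testing.assert_allclose(t.inverse().apply(t.apply(p)), p, atol=1e-8)

    @settings(deadline=None, derandomize=True)
    @given(t1=angles, t2=angles)
    def test_compose_is_sequential_application(self, t1, t2):
        a = RigidTransform2D(t1, 3.0, -1.0, (5.0, 5.0))
        b = RigidTransform2D(t2, -2.0, 4.0, (-1.0, 2.0))
        p = np.array([[1.0, 2.0], [-3.0, 0.5]])
        np.testing.assert_allclose(b.compose(a).apply(p), b.apply(a.apply(p)), atol=1e-8)

    def test_linear_part_is_pure_rotation(self):
        t = RigidTransform2D(theta=123.4, tx=9.0, ty=-3.0, center=(7.0, 1.0))
        s = np.linalg.svd(t.as_matrix()[:2, :2], compute_uv=False)
        assert np.all(np.abs(s - 1.0) < 1e-9)
        assert abs(np.linalg.det(t.as_matrix()[:2, :2]) - 1.0) < 1e-9

    def test_wrap_angle_half_open(self):
        assert wrap_angle(180.0) == 180.0
        assert wrap_angle(-180.0) == 180.0
        assert wrap_angle(540.0) == 180.0
        assert wrap_angle(90.0, period=180.0) == 90.0
        assert wrap_angle(-90.0, period=180.0) == 90.0


class TestScaleRigid:
    def test_identity_factor(self):
        t = RigidTransform2D(30.0, 10.0, 20.0, (3.0, 4.0))
        assert scale_rigid(t, 1.0) == t

    def test_linearity_by_mapping_grid_points(self):
        t = RigidTransform2D(30.0, 10.0, 20.0)
        t4 = scale_rigid(t, 4.0)
        assert t4.theta == 30.0 and t4.tx == 40.0 and t4.ty == 80.0
        pts = np.array([[0.0, 0.0], [10.0, 5.0], [-3.0, 7.0]])
        np.testing.assert_allclose(t4.apply(pts * 4.0), t.apply(pts) * 4.0, atol=1e-9)

    def test_roundtrip(self):
        t = RigidTransform2D(12.0, 5.0, -8.0, (1.0, 2.0))
        back = scale_rigid(scale_rigid(t, 4.0), 0.25)
        np.testing.assert_allclose(
            [back.theta, back.tx, back.ty], [t.theta, t.tx, t.ty], atol=1e-12
        )

    def test_rejects_nonpositive_factor(self):
        with pytest.raises(ValueError):
            scale_rigid(RigidTransform2D(), 0.0)


class TestTPS:
    def _random_field(self, rng, spacing=64.0, side=256, amp=5.0):
        f = DeformationField.identity_on_grid((side, side), spacing)
        targets = f.control_targets + rng.uniform(-amp, amp, f.control_targets.shape)
        return DeformationField(f.control_sources, targets, spacing)

    def test_matches_scipy_thin_plate_oracle(self, rng):
        src = rng.uniform(0, 100, (15, 2))
        tgt = src + rng.uniform(-5, 5, (15, 2))
        w, a = tps_fit(src, tgt)
        q = rng.uniform(5, 95, (40, 2))
        ours = tps_evaluate(q, src, w, a)
        ref = RBFInterpolator(src, tgt, kernel="thin_plate_spline", smoothing=0.0)(q)
        np.testing.assert_allclose(ours, ref, atol=1e-6)

    def test_reproduces_affine_exactly(self, rng):
        src = rng.uniform(0, 200, (12, 2))
        mat = np.array([[1.02, 0.05], [-0.03, 0.98]])
        tgt = src @ mat.T + [3.0, -2.0]
        w, a = tps_fit(src, tgt)
        q = rng.uniform(0, 200, (30, 2))
        np.testing.assert_allclose(tps_evaluate(q, src, w, a), q @ mat.T + [3.0, -2.0], atol=1e-6)

    def test_scale_equivariance(self, rng):
        f = self._random_field(rng)
        for s in (0.25, 3.0):
            fs = scale_deformable(f, s)
            p = rng.uniform(10, 240, (50, 2))
            np.testing.assert_allclose(fs.map_points(p * s), f.map_points(p) * s, atol=1e-6)

    def test_identity_field_scales_to_identity(self):
        f = DeformationField.identity_on_grid((128, 128), 32.0)
        fs = scale_deformable(f, 4.0)
        p = np.array([[10.0, 20.0], [100.0, 400.0]])
        np.testing.assert_allclose(fs.map_points(p), p, atol=1e-8)

    def test_rejects_nonpositive_factor(self):
        f = DeformationField.identity_on_grid((64, 64), 32.0)
        with pytest.raises(ValueError):
            scale_deformable(f, -1.0)


class TestBackwardMap:
    def test_identity(self):
        m = build_backward_map(None, (8, 6))
        gx, gy = np.meshgrid(np.arange(8.0), np.arange(6.0))
        np.testing.assert_array_equal(m[..., 0], gx)
        np.testing.assert_array_equal(m[..., 1], gy)

    def test_pure_translation_inverts(self):
        t = RigidTransform2D(0.0, 3.0, -2.0)
        m = build_backward_map(t, (8, 8))
        assert m[0, 0, 0] == -3.0 and m[0, 0, 1] == 2.0

    def test_rotation_90_maps_corners_to_corners(self):
        n = 11
        c = (n - 1) / 2.0
        t = RigidTransform2D(90.0, 0.0, 0.0, (c, c))
        m = build_backward_map(t, (n, n))
        np.testing.assert_allclose(m[0, 0], [0.0, n - 1.0], atol=1e-9)
        np.testing.assert_allclose(m[n - 1, n - 1], [n - 1.0, 0.0], atol=1e-9)

    def test_tile_restriction_equals_global_map(self, rng):
        t = RigidTransform2D(37.0, 5.0, -3.0, (64.0, 64.0))
        full = build_backward_map(t, (128, 128))
        tile = build_backward_map(t, (128, 128), (32, 48, 40, 24))
        np.testing.assert_array_equal(tile, full[48:72, 32:72])

    def test_tile_outside_output_rejected(self):
        with pytest.raises(ValueError):
            build_backward_map(None, (64, 64), (50, 50, 32, 32))


class TestWarpTiled:
    def test_identity_any_tiling_equals_input(self, rng):
        img = rng.integers(0, 256, (96, 96, 3), dtype=np.uint8)
        out = assemble_tiles(warp_tiled(img, None, tile_size=32), (96, 96))
        np.testing.assert_array_equal(out, img)

    @pytest.mark.parametrize("tile_size", [64, 128, 256])
    def test_rotation_matches_monolithic(self, rng, tile_size):
        img = np.random.default_rng(5).integers(0, 256, (300, 300, 3), dtype=np.uint8)
        t = RigidTransform2D(37.0, 4.0, -9.0, (149.5, 149.5))
        mono = warp_image(img, t)
        tiled = assemble_tiles(warp_tiled(img, t, tile_size=tile_size), (300, 300))
        np.testing.assert_array_equal(tiled, mono)

    def test_nearest_keeps_masks_binary(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[20:40, 10:50] = True
        t = RigidTransform2D(30.0, 0.0, 0.0, (31.5, 31.5))
        out = warp_image(mask, t, interpolation="nearest", background=0)
        assert out.dtype == bool

    def test_rigid_warp_preserves_mask_area_to_perimeter_order(self):
        mask = np.zeros((128, 128), dtype=bool)
        mask[30:98, 40:90] = True
        t = RigidTransform2D(25.0, 2.0, -1.0, (63.5, 63.5))
        out = warp_image(mask, t, interpolation="nearest", background=0)
        perimeter = 2 * (68 + 50)
        assert abs(int(out.sum()) - int(mask.sum())) < 2 * perimeter

    def test_small_tile_size_rejected(self):
        img = np.zeros((32, 32, 3), dtype=np.uint8)
        with pytest.raises(ValueError):
            list(warp_tiled(img, None, tile_size=8))


class TestInterpolateVolume:
    def test_identical_slices_fill_identically(self):
        m = np.zeros((16, 16), dtype=bool)
        m[4:12, 4:12] = True
        vol = interpolate_volume([m, m], steps_between=3)
        assert vol.shape == (5, 16, 16)
        assert all(np.array_equal(frame, m) for frame in vol)

    def test_halfway_crossfade_matches_per_pixel_oracle(self):
        a = np.zeros((20, 20), dtype=bool)
        a[:, :10] = True  # left half
        b = np.ones((20, 20), dtype=bool)  # full square
        vol = interpolate_volume([a, b], steps_between=1)
        oracle = (0.5 * a.astype(float) + 0.5 * b.astype(float)) >= 0.5
        np.testing.assert_array_equal(vol[1], oracle)

    def test_zero_steps_returns_input_stack(self):
        masks = [np.eye(8, dtype=bool), np.zeros((8, 8), dtype=bool)]
        vol = interpolate_volume(masks, steps_between=0)
        assert vol.shape == (2, 8, 8)
        np.testing.assert_array_equal(vol[0], masks[0])
        np.testing.assert_array_equal(vol[1], masks[1])
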