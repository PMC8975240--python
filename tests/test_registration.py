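"""Homography estimation, warping, overlays and checkerboard detection."""

import numpy as np
import pytest
from skimage.transform import ProjectiveTransform

from conftest import random_homography
from thermograd import registration as reg
from thermograd.errors import (
    BoardDetectionError,
    DegenerateGeometryError,
    DomainError,
    InsufficientDataError,
    SingularTransformError,
)
from thermograd.phantom import _render_board


def _grid_points(nx=5, ny=4, spacing=10.0):
    return np.array([[x * spacing, y * spacing]
                     for y in range(ny) for x in range(nx)], dtype=float)


def _apply(matrix, pts):
    h = matrix @ np.vstack([pts.T, np.ones(len(pts))])
    return (h[:2] / h[2]).T


class TestEstimate:
    def test_identity_from_four_points(self):
        pts = np.array([[0, 0], [10, 0], [10, 10], [0, 10]], float)
        t = reg.estimate_planar_transform(reg.CorrespondenceSet(pts, pts))
        np.testing.assert_allclose(t.matrix, np.eye(3), atol=1e-9)
        assert t.rmse == pytest.approx(0.0, abs=1e-9)

    def test_pure_translation(self):
        pts = np.array([[0, 0], [10, 0], [10, 10], [0, 10]], float)
        t = reg.estimate_planar_transform(
            reg.CorrespondenceSet(pts, pts + [10.0, 5.0]))
        expected = np.array([[1, 0, 10], [0, 1, 5], [0, 0, 1]], float)
        np.testing.assert_allclose(t.matrix, expected, atol=1e-9)

    def test_recovers_known_projective_matrix(self, rng):
        h_true = random_homography(rng)
        h_true /= h_true[2, 2]
        src = _grid_points()
        t = reg.estimate_planar_transform(
            reg.CorrespondenceSet(src, _apply(h_true, src)))
        assert np.abs(t.matrix - h_true).max() / np.abs(h_true).max() < 1e-6
        assert t.rmse < 1e-6

    def test_recovery_property_over_random_transforms(self, rng):
        src = _grid_points()
        for _ in range(50):
            h_true = random_homography(rng)
            h_true /= h_true[2, 2]
            t = reg.estimate_planar_transform(
                reg.CorrespondenceSet(src, _apply(h_true, src)))
            assert np.abs(t.matrix - h_true).max() / np.abs(h_true).max() < 1e-6

    def test_too_few_pairs(self):
        pts = np.array([[0, 0], [1, 0], [0, 1]], float)
        with pytest.raises(InsufficientDataError):
            reg.estimate_planar_transform(reg.CorrespondenceSet(pts, pts))

    def test_collinear_configuration(self):
        src = np.array([[0, 0], [1, 1], [2, 2], [3, 3], [4, 4]], float)
        with pytest.raises(DegenerateGeometryError):
            reg.estimate_planar_transform(reg.CorrespondenceSet(src, src * 2))

    def test_robust_mode_rejects_outliers(self, rng):
        h_true = random_homography(rng)
        h_true /= h_true[2, 2]
        src = _grid_points(6, 6)
        dst = _apply(h_true, src)
        dst[3] += 40.0  # gross outliers
        dst[17] -= 55.0
        t = reg.estimate_planar_transform(
            reg.CorrespondenceSet(src, dst), robust=True, seed=4)
        assert np.abs(t.matrix - h_true).max() / np.abs(h_true).max() < 1e-6

    def test_agrees_with_skimage_least_squares(self, rng):
        # independent solver cross-check on noisy correspondences
        h_true = random_homography(rng)
        src = _grid_points(6, 5)
        dst = _apply(h_true, src) + rng.normal(0, 0.3, (30, 2))
        ours = reg.estimate_planar_transform(
            reg.CorrespondenceSet(src, dst)).matrix
        sk = ProjectiveTransform.from_estimate(src, dst)
        theirs = sk.params / sk.params[2, 2]
        # independent normalized least-squares solvers agree closely
        np.testing.assert_allclose(ours, theirs, rtol=1e-4, atol=1e-5)


class TestTransformObject:
    def test_normalization_and_inverse(self):
        t = reg.PlanarTransform(np.diag([2.0, 2.0, 2.0]))
        np.testing.assert_allclose(t.matrix[2, 2], 1.0)
        pts = np.array([[3.0, 4.0]])
        np.testing.assert_allclose(t.inverse().apply(t.apply(pts)), pts,
                                   atol=1e-12)

    def test_singular_matrix_rejected(self):
        with pytest.raises(SingularTransformError):
            reg.PlanarTransform(np.zeros((3, 3)))

    def test_json_round_trip(self, tmp_path):
        t = reg.PlanarTransform(np.array([[4, 0, 8], [0, 4, 6], [0, 0, 1.0]]),
                                src_space="ir", dst_space="rgb", rmse=0.12)
        t.to_json(tmp_path / "t.json")
        back = reg.PlanarTransform.from_json(tmp_path / "t.json")
        np.testing.assert_allclose(back.matrix, t.matrix)
        assert (back.src_space, back.dst_space) == ("ir", "rgb")
        assert back.rmse == pytest.approx(0.12)


class TestRmse:
    def test_exact_pairs_give_zero(self, rng):
        h = random_homography(rng)
        src = _grid_points()
        t = reg.PlanarTransform(h)
        assert reg.reprojection_rmse(
            t, reg.CorrespondenceSet(src, _apply(h, src))) < 1e-9

    def test_three_four_five(self):
        src = _grid_points()
        corr = reg.CorrespondenceSet(src, src + [3.0, 4.0])
        assert reg.reprojection_rmse(reg.PlanarTransform.identity(), corr) \
            == pytest.approx(5.0)

    def test_invariant_to_pair_order(self, rng):
        h = random_homography(rng)
        src = _grid_points()
        dst = _apply(h, src) + rng.normal(0, 1.0, src.shape)
        t = reg.PlanarTransform(h)
        perm = rng.permutation(len(src))
        a = reg.reprojection_rmse(t, reg.CorrespondenceSet(src, dst))
        b = reg.reprojection_rmse(t, reg.CorrespondenceSet(src[perm], dst[perm]))
        assert a == pytest.approx(b, rel=1e-12)

    def test_noisy_pairs_near_noise_scale(self, rng):
        # isotropic sigma = 1 px on each coordinate -> RMSE ~ sqrt(2)
        src = _grid_points(10, 5)
        dst = src + rng.normal(0, 1.0, src.shape)
        rmse = reg.reprojection_rmse(reg.PlanarTransform.identity(),
                                     reg.CorrespondenceSet(src, dst))
        assert 0.5 < rmse < 2.0

    def test_empty_set_rejected(self):
        empty = reg.CorrespondenceSet(np.empty((0, 2)), np.empty((0, 2)))
        with pytest.raises(DomainError):
            reg.reprojection_rmse(reg.PlanarTransform.identity(), empty)


class TestWarp:
    def test_identity_preserves_frame(self, rng):
        frame = rng.random((30, 40))
        out = reg.warp_frame(frame, reg.PlanarTransform.identity(), (30, 40))
        np.testing.assert_allclose(out, frame, atol=1e-9)

    def test_constant_frame_stays_constant_inside(self, rng):
        frame = np.full((40, 40), 7.5)
        t = reg.PlanarTransform(np.array([[1, 0.1, 2], [0.05, 1, 1],
                                          [0, 0, 1.0]]))
        out = reg.warp_frame(frame, t, (40, 40), fill=np.nan)
        interior = out[~np.isnan(out)]
        np.testing.assert_allclose(interior, 7.5, atol=1e-9)

    def test_ramp_round_trip(self):
        yy, xx = np.mgrid[0:60, 0:80]
        ramp = 20.0 + 0.1 * xx + 0.05 * yy
        h = np.array([[1.1, 0.05, 3], [0.02, 0.95, 2], [1e-5, -1e-5, 1.0]])
        t = reg.PlanarTransform(h)
        there = reg.warp_frame(ramp, t, (60, 80))
        back = reg.warp_frame(there, t.inverse(), (60, 80))
        # compare only where the round trip never touched the fill value
        ones = reg.warp_frame(np.ones_like(ramp), t, (60, 80))
        cover = reg.warp_frame(ones, t.inverse(), (60, 80)) > 0.999
        assert cover.sum() > 1000
        assert np.abs(back - ramp)[cover].max() < 0.5

    def test_warp_composition(self):
        yy, xx = np.mgrid[0:60, 0:80]
        smooth = np.sin(xx / 15.0) + np.cos(yy / 12.0)
        h1 = reg.PlanarTransform(np.array([[1, 0, 4], [0, 1, 3], [0, 0, 1.0]]))
        h2 = reg.PlanarTransform(np.array([[1, 0.02, -2], [0.01, 1, 1],
                                           [0, 0, 1.0]]))
        step = reg.warp_frame(reg.warp_frame(smooth, h1, (60, 80)), h2, (60, 80))
        direct = reg.warp_frame(smooth, h2.compose(h1), (60, 80))
        interior = np.s_[12:48, 12:68]
        assert np.abs(step - direct)[interior].max() < 0.05

    def test_singular_transform_refused(self):
        t = reg.PlanarTransform.identity()
        t.matrix = np.array([[1, 0, 0], [1, 0, 0], [0, 0, 1.0]])  # bypass init
        with pytest.raises(np.linalg.LinAlgError):
            reg.warp_frame(np.zeros((5, 5)), t, (5, 5))


class TestOverlay:
    def test_opacity_zero_returns_color_verbatim(self, rng):
        color = rng.random((10, 10, 3))
        temps = rng.uniform(20, 35, (10, 10))
        np.testing.assert_array_equal(reg.compose_overlay(color, temps, 0.0),
                                      color)

    def test_opacity_one_is_pure_thermal_layer(self, rng):
        color = rng.random((8, 8, 3))
        temps = np.full((8, 8), 30.0)
        out = reg.compose_overlay(color, temps, 1.0, t_range=(20, 40))
        assert np.ptp(out, axis=(0, 1)).max() < 1e-12  # uniform layer

    def test_half_opacity_is_channel_mean(self):
        color = np.full((5, 5, 3), 0.2)
        temps = np.full((5, 5), 25.0)
        out = reg.compose_overlay(color, temps, 0.5, t_range=(25, 25.0001))
        import matplotlib
        layer = matplotlib.colormaps["inferno"](0.0)[:3]
        np.testing.assert_allclose(out[0, 0], (0.2 + np.array(layer)) / 2,
                                   atol=1e-6)

    def test_shape_mismatch(self):
        with pytest.raises(DomainError):
            reg.compose_overlay(np.zeros((4, 4, 3)), np.zeros((5, 5)), 0.5)


class TestCheckerboard:
    GRID = (7, 9)

    def _board(self, h, invert=False, shape=(120, 160), square=12.0):
        from thermograd.phantom import _true_corners
        dark, light = (0.9, 0.1) if invert else (0.1, 0.9)
        img = _render_board(shape, h, self.GRID, square, dark, light, 0.5)
        return img, _true_corners(h, self.GRID, square)

    def test_synthetic_board_corner_accuracy(self):
        h = np.array([[1, 0.02, 22], [0.03, 1, 14], [1e-5, -1e-5, 1.0]])
        img, truth = self._board(h)
        found = reg.detect_checkerboard_corners(img, self.GRID)
        rms = np.sqrt(((found - truth) ** 2).sum(axis=1).mean())
        assert rms < 0.5

    def test_translation_shifts_all_corners(self):
        h = np.array([[1, 0.0, 20], [0.0, 1, 12], [0, 0, 1.0]])
        shift = np.array([[1, 0, 6], [0, 1, 4], [0, 0, 1.0]])
        img_a, _ = self._board(h)
        img_b, _ = self._board(shift @ h)
        a = reg.detect_checkerboard_corners(img_a, self.GRID)
        b = reg.detect_checkerboard_corners(img_b, self.GRID)
        np.testing.assert_allclose(b - a, [[6.0, 4.0]] * len(a), atol=0.5)

    def test_blank_image_raises(self):
        with pytest.raises(BoardDetectionError):
            reg.detect_checkerboard_corners(np.full((60, 60), 0.5), self.GRID)

    def test_ordering_invariant_to_contrast_inversion(self):
        h = np.array([[1, 0.01, 24], [0.02, 1, 13], [0, 0, 1.0]])
        img_pos, _ = self._board(h)
        img_neg, _ = self._board(h, invert=True)
        a = reg.detect_checkerboard_corners(img_pos, self.GRID)
        b = reg.detect_checkerboard_corners(img_neg, self.GRID)
        np.testing.assert_allclose(a, b, atol=0.3)
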