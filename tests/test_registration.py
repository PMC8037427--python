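import dataclasses

import numpy as np
import pytest

from thermofoot.calibration import KeypointSet, detect_blobs, from_point_arrays, pair_grid_keypoints
from thermofoot.evaluation import overlap_metrics
from thermofoot.registration import (
    AsgdConfig,
    IcpConfig,
    RansacConfig,
    estimate_affine_asgd,
    estimate_got,
    estimate_homography_dlt,
    estimate_homography_ransac,
    estimate_icp,
    extract_contour_keypoints,
    fit_affine_lsq,
    fit_rigid_lsq,
)
from thermofoot.synthgen import make_checkerboard_scene, make_foot_mask, make_scene_bundle
from thermofoot.transforms import (
    Transform2D,
    affine,
    angular_scale,
    apply_to_points,
    invert,
    rigid,
    warp_mask,
)

from conftest import make_h_correspondences


def _corr(src, dst, shape=(2000, 2000)):
    return from_point_arrays(src, dst, shape, shape)


class TestGot:
    def test_noiseless_rig_residual_below_half_pixel(self, quiet_rig):
        # premise: a pure scale+shift rig, so the fixed angular scaling is
        # exact (no axial sensor offset)
        pure = dataclasses.replace(
            quiet_rig,
            thermal=dataclasses.replace(quiet_rig.thermal, axial_offset_mm=0.0),
        )
        quiet_rig = pure
        sc = make_checkerboard_scene(quiet_rig, jitter_px=0.0, n_outliers=0, seed=0)
        kp_v = detect_blobs(sc.visible_image, polarity="bright")
        kp_t = detect_blobs(sc.thermal_image, polarity="dark")
        corr = pair_grid_keypoints(kp_v, kp_t, sc.grid_rows, sc.grid_cols)
        t = estimate_got(corr, quiet_rig.visible, quiet_rig.thermal)
        res = apply_to_points(t, corr.src_points) - corr.dst_points
        assert np.linalg.norm(res, axis=1).max() < 0.5

    def test_single_pair_offset_becomes_translation(self, rig):
        scale = angular_scale(rig.visible, rig.thermal)
        src = np.array([[100.0, 100.0]])
        dst = apply_to_points(scale, src) + [7.0, -3.0]
        t = estimate_got(_corr(src, dst), rig.visible, rig.thermal)
        resid = t.matrix[:2, 2] - scale.matrix[:2, 2]  # translation added to scale
        assert np.allclose(resid, [7.0, -3.0])

    def test_median_shrugs_off_gross_outlier(self, rig):
        scale = angular_scale(rig.visible, rig.thermal)
        rng = np.random.default_rng(1)
        gx, gy = np.meshgrid(np.arange(5), np.arange(3))
        src = np.column_stack([100 + 150.0 * gx.ravel(), 100 + 200.0 * gy.ravel()])
        src += rng.uniform(-10, 10, src.shape)
        dst = apply_to_points(scale, src) + [5.0, 2.0]
        clean = estimate_got(_corr(src, dst), rig.visible, rig.thermal)
        dst_bad = dst.copy()
        dst_bad[4] += [80.0, 60.0]
        dirty = estimate_got(_corr(src, dst_bad), rig.visible, rig.thermal)
        assert np.linalg.norm(clean.matrix[:2, 2] - dirty.matrix[:2, 2]) < 0.5

    def test_empty_correspondences_rejected(self, rig):
        with pytest.raises(ValueError, match="at least one"):
            estimate_got(
                _corr(np.empty((0, 2)), np.empty((0, 2))), rig.visible, rig.thermal
            )


class TestHomographyDlt:
    H = np.array([[1.02, 0.03, 15.0], [-0.02, 0.97, -8.0], [1e-5, -2e-5, 1.0]])

    def test_exact_recovery_from_four_points(self):
        src = np.array([[10.0, 10.0], [400.0, 30.0], [50.0, 380.0], [420.0, 400.0]])
        dst = apply_to_points(Transform2D(self.H, "homography"), src)
        est = estimate_homography_dlt(_corr(src, dst))
        assert np.abs(est.matrix - self.H / self.H[2, 2]).max() <= 1e-8

    def test_identity_correspondences(self):
        src = np.array([[0.0, 0.0], [100.0, 0.0], [0.0, 100.0], [100.0, 100.0]])
        est = estimate_homography_dlt(_corr(src, src))
        assert np.allclose(est.matrix, np.eye(3), atol=1e-10)

    def test_pure_translation_pairs(self):
        src = np.array([[10.0, 10.0], [200.0, 20.0], [30.0, 250.0], [220.0, 240.0]])
        est = estimate_homography_dlt(_corr(src, src + [12.0, -7.0]))
        off = est.matrix - np.eye(3)
        off[:2, 2] = 0
        assert np.abs(off).max() < 1e-10
        assert np.allclose(est.matrix[:2, 2], [12.0, -7.0])

    def test_collinear_points_rejected(self):
        src = np.array([[0.0, 0.0], [10.0, 10.0], [20.0, 20.0], [30.0, 30.0]])
        with pytest.raises(ValueError, match="collinear"):
            estimate_homography_dlt(_corr(src, src + 1.0))

    def test_fewer_than_four_pairs_rejected(self):
        src = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        with pytest.raises(ValueError, match=">= 4"):
            estimate_homography_dlt(_corr(src, src))


class TestHomographyRansac:
    H = np.array([[0.98, -0.01, 22.0], [0.02, 1.03, -14.0], [2e-5, 1e-5, 1.0]])

    def test_recovers_generator_inlier_labels(self):
        corr, labels = make_h_correspondences(self.H, 20, 8, jitter_px=0.3, seed=0)
        cfg = RansacConfig(n_iters=300, inlier_thresh_px=2.0, min_inliers=8, seed=0)
        _, idx = estimate_homography_ransac(corr, cfg)
        assert set(idx.tolist()) == set(np.flatnonzero(labels).tolist())

    def test_all_inlier_input_keeps_every_pair(self):
        corr, _ = make_h_correspondences(self.H, 16, 0, jitter_px=0.1, seed=1)
        cfg = RansacConfig(n_iters=200, inlier_thresh_px=2.0, min_inliers=8, seed=1)
        _, idx = estimate_homography_ransac(corr, cfg)
        assert len(idx) == 16

    def test_three_pairs_rejected(self):
        src = np.array([[0.0, 0.0], [50.0, 0.0], [0.0, 50.0]])
        with pytest.raises(ValueError, match=">= 4"):
            estimate_homography_ransac(_corr(src, src))

    def test_deterministic_given_seed(self):
        corr, _ = make_h_correspondences(self.H, 20, 8, jitter_px=0.3, seed=2)
        cfg = RansacConfig(n_iters=200, seed=5)
        t1, i1 = estimate_homography_ransac(corr, cfg)
        t2, i2 = estimate_homography_ransac(corr, cfg)
        assert np.array_equal(i1, i2)
        assert np.array_equal(t1.matrix, t2.matrix)

    def test_no_consensus_raises(self):
        rng = np.random.default_rng(3)
        src = rng.uniform(0, 500, (12, 2))
        dst = rng.uniform(0, 500, (12, 2))  # unrelated point clouds
        cfg = RansacConfig(n_iters=100, inlier_thresh_px=0.5, min_inliers=10, seed=0)
        with pytest.raises(ValueError, match="no model supported"):
            estimate_homography_ransac(_corr(src, dst), cfg)


class TestContourKeypoints:
    def test_rectangle_four_points_equally_spaced(self):
        mask = np.zeros((40, 60), np.uint8)
        mask[10:30, 15:45] = 1  # boundary length 2*(20+30) - 4 = 96 px
        pts = extract_contour_keypoints(mask, 4)
        assert len(pts) == 4
        # arc positions: locate the samples on the full ordered boundary
        full = extract_contour_keypoints(mask, 10_000)  # saturated: whole trace
        idx = sorted(
            int(np.flatnonzero((full == p).all(axis=1))[0]) for p in pts
        )
        gaps = np.diff(idx + [idx[0] + len(full)])
        assert gaps.max() - gaps.min() <= 1

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            extract_contour_keypoints(np.zeros((10, 10), np.uint8), 10)

    def test_saturates_at_boundary_length(self):
        mask = np.zeros((12, 12), np.uint8)
        mask[4:7, 4:7] = 1  # 8 boundary pixels
        pts = extract_contour_keypoints(mask, 500)
        assert len(pts) == 8
        assert len(np.unique(pts, axis=0)) == 8

    def test_points_lie_on_boundary(self, foot_mask):
        from scipy import ndimage

        pts = extract_contour_keypoints(foot_mask, 100)
        boundary = foot_mask.astype(bool) & ~ndimage.binary_erosion(
            foot_mask.astype(bool)
        )
        for x, y in pts:
            assert boundary[int(y), int(x)]


class TestIcp:
    def test_identical_sets_give_identity(self, foot_mask):
        eye = Transform2D(np.eye(3), "affine")
        res = estimate_icp(foot_mask, foot_mask, eye, IcpConfig(smooth_sigma_px=0.0))
        assert res.rmse < 1e-9
        assert np.allclose(res.transform.matrix, np.eye(3), atol=1e-9)

    def test_recovers_rotation_and_shift(self, foot_mask):
        gt = rigid(np.radians(5.0), (4.0, 2.0), center=(191.5, 143.5))
        moved = warp_mask(gt, foot_mask, foot_mask.shape)
        eye = Transform2D(np.eye(3), "affine")
        # dense contour sampling: arc spacing bounds the achievable angular
        # resolution, so probe recovery with ~1 px spacing
        res = estimate_icp(
            foot_mask, moved, eye, IcpConfig(n_keypoints=800, smooth_sigma_px=0.0)
        )
        est = res.transform.matrix
        theta = np.degrees(np.arctan2(est[1, 0], est[0, 0]))
        assert abs(theta - 5.0) <= 0.5
        # translation error measured at the rotation centre
        probe = np.array([[191.5, 143.5]])
        err = apply_to_points(res.transform, probe) - apply_to_points(gt, probe)
        assert np.linalg.norm(err[0]) <= 0.5

    def test_rmse_history_non_increasing(self, foot_mask):
        gt = rigid(np.radians(4.0), (-6.0, 3.0), center=(191.5, 143.5))
        moved = warp_mask(gt, foot_mask, foot_mask.shape)
        eye = Transform2D(np.eye(3), "affine")
        res = estimate_icp(foot_mask, moved, eye, IcpConfig(smooth_sigma_px=0.0))
        hist = np.array(res.rmse_history)
        assert np.all(np.diff(hist) <= 1e-9)

    def test_empty_mask_rejected(self, foot_mask):
        eye = Transform2D(np.eye(3), "affine")
        with pytest.raises(ValueError, match="empty"):
            estimate_icp(np.zeros((10, 10), np.uint8), foot_mask, eye)


class TestAsgd:
    def test_self_registration_is_identity(self, foot_mask):
        t = estimate_affine_asgd(foot_mask, foot_mask, AsgdConfig(seed=0))
        assert np.linalg.norm(t.matrix[:2, :2] - np.eye(2)) < 0.01
        assert np.linalg.norm(t.matrix[:2, 2]) < 0.5

    def test_recovers_affine_warp(self, foot_mask):
        gt = affine(
            np.array([[1.05, 0.03], [0.0, 1.05]]), (6.0, -4.0), center=(191.5, 143.5)
        )
        warped = warp_mask(gt, foot_mask, foot_mask.shape)
        dices = []
        for seed in (0, 1):
            est = estimate_affine_asgd(foot_mask, warped, AsgdConfig(seed=seed))
            reg = warp_mask(est, foot_mask, foot_mask.shape)
            dices.append(overlap_metrics(reg, warped).dice)
        assert min(dices) >= 0.99
        assert abs(dices[0] - dices[1]) < 0.005

    def test_disjoint_masks_rejected_with_advice(self):
        a = np.zeros((64, 64), np.uint8)
        b = np.zeros((64, 64), np.uint8)
        a[2:6, 2:6] = 1
        b[55:60, 55:60] = 1
        with pytest.raises(ValueError, match="pre-align"):
            estimate_affine_asgd(a, b, AsgdConfig(max_iters=10))

    def test_empty_mask_rejected(self, foot_mask):
        with pytest.raises(ValueError, match="nonempty"):
            estimate_affine_asgd(np.zeros((32, 32), np.uint8), foot_mask)


class TestModelHierarchy:
    def test_residual_ordering_on_perspective_scene(self):
        """More degrees of freedom fit a projective displacement better:
        homography <= affine <= rigid residual."""
        h = np.array([[1.04, 0.06, 10.0], [-0.03, 0.96, 5.0], [3e-4, -2e-4, 1.0]])
        rng = np.random.default_rng(0)
        gx, gy = np.meshgrid(np.arange(8), np.arange(5))
        src = np.column_stack([20 + 50.0 * gx.ravel(), 20 + 80.0 * gy.ravel()])
        src += rng.uniform(-15, 15, src.shape)
        dst = apply_to_points(Transform2D(h, "homography"), src)
        t_h = estimate_homography_dlt(_corr(src, dst))
        t_a = fit_affine_lsq(src, dst)
        t_r = fit_rigid_lsq(src, dst)
        res = {
            m: np.linalg.norm(apply_to_points(t, src) - dst, axis=1).mean()
            for m, t in (("h", t_h), ("a", t_a), ("r", t_r))
        }
        assert res["h"] <= res["a"] + 1e-9
        assert res["a"] <= res["r"] + 1e-9
        assert res["h"] < 1e-6  # exact in the noiseless case

    def test_all_methods_reach_dice_097_on_noiseless_focal_scene(self, quiet_rig):
        """On a clean focal-plane scene every estimator overlaps the thermal
        mask with Dice >= 0.97."""
        from thermofoot.evaluation import ExperimentConfig, estimate_all_methods

        bundle = make_scene_bundle(quiet_rig, quiet_rig.focal_plane_mm, seed=42)
        calib = make_checkerboard_scene(quiet_rig, jitter_px=0.0, n_outliers=0, seed=7)
        cfg = ExperimentConfig(
            use_fused_references=False, ransac=RansacConfig(n_iters=300, seed=0)
        )
        transforms = estimate_all_methods(bundle, calib, quiet_rig, cfg)
        for name, t in transforms.items():
            reg = warp_mask(t, bundle.visible_mask, bundle.thermal_mask.shape)
            dice = overlap_metrics(reg, bundle.thermal_mask).dice
            assert dice >= 0.97, f"{name}: {dice:.4f}"
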