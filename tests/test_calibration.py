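import numpy as np
import pytest

from pmpscan.calibration import (
    CalibBoard,
    CorrespondenceSet,
    DegenerateGeometryError,
    DetectionError,
    ProjectionMatrix,
    board_mesh_and_albedo,
    detect_circle_centers,
    estimate_projection_matrix,
    make_board_poses,
    projector_pixel_from_phase,
    reprojection_error,
    sample_map_subpixel,
)
from pmpscan.experiments import make_scene, rig_devices
from pmpscan.render import render_frame, render_white_patch


def random_projection_matrix(rng):
    from pmpscan.geometry import PinholeDevice
    cam = PinholeDevice(focal_length=20, sensor_width=36, sensor_height=24,
                        resolution_u=1138, resolution_v=489)
    center = rng.uniform(-50, 50, 3) + [0, 0, 1000]
    cam = cam.posed_at(center, rng.uniform(-20, 20, 3))
    P = cam.projection_matrix
    return P / P[2, 3]


def synth_correspondences(P, rng, n=200, noise=0.0, views=4):
    pts = rng.uniform(-150, 150, size=(n, 3))
    ph = np.column_stack([pts, np.ones(n)]) @ P.T
    pix = ph[:, :2] / ph[:, 2:3]
    if noise:
        pix = pix + rng.normal(0, noise, pix.shape)
    return CorrespondenceSet(world_points=pts, pixels=pix,
                             view_index=rng.integers(0, views, n))


class TestBoard:
    def test_symmetric_fiducials_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            CalibBoard(large_grid_positions=((4, 4), (4, 6)))

    def test_centers_unique_and_counted(self):
        board = CalibBoard()
        c = board.centers_local()
        assert len(c) == board.rows * board.cols
        assert len(np.unique(c, axis=0)) == len(c)
        assert board.is_large().sum() == 4

    def test_albedo_map_dark_inside_dots(self):
        board = CalibBoard()
        pose = np.eye(4)
        _, albedo_fn, world = board_mesh_and_albedo(board, pose)
        assert albedo_fn(world[:1])[0] == board.dot_albedo
        off = world[:1] + [board.spacing / 2, board.spacing / 2, 0]
        assert albedo_fn(off)[0] == board.background_albedo


class TestDetection:
    @pytest.fixture(scope="class")
    def rendered_pose(self, config_full):
        board = CalibBoard()
        pose = make_board_poses(3, seed=7)[1]
        mesh, albedo_fn, world = board_mesh_and_albedo(board, pose)
        scene = make_scene(config_full, mesh, albedo_fn=albedo_fn,
                           supersample=2, aperture=0.0)
        Wp, Hp = config_full.projector_resolution
        img, _ = render_frame(scene, np.ones((Hp, Wp)))
        return board, scene, img, world

    def test_subpixel_accuracy_against_projection(self, config_full, rendered_pose):
        board, scene, img, world = rendered_pose

        def refine(r0, r1, c0, c1):
            return render_white_patch(scene, r0, r1, c0, c1, supersample=32)

        centers = detect_circle_centers(img, board, refine_patch=refine)
        cam, _ = rig_devices(config_full)
        uv, _ = cam.project_points(world)
        err = np.linalg.norm(centers - uv, axis=1)
        assert err.mean() < 0.05
        assert err.max() < 0.5

    def test_grid_order_invariant_under_180_rotation(self, rendered_pose):
        board, scene, img, world = rendered_pose
        centers = detect_circle_centers(img, board)
        rot = detect_circle_centers(np.rot90(img, 2).copy(), board)
        H, W = img.shape
        # rotating the image maps pixel (u, v) -> (W-1-u, H-1-v); the detector
        # must still report dots in the same grid order
        expected = np.column_stack([W - 1 - centers[:, 0], H - 1 - centers[:, 1]])
        assert np.allclose(rot, expected, atol=0.2)

    def test_failure_reports_found_count(self, rendered_pose):
        board, _, img, _ = rendered_pose
        with pytest.raises(DetectionError):
            detect_circle_centers(img[: img.shape[0] // 4], board)


class TestProjectionEstimation:
    def test_exact_recovery_from_noiseless_points(self, rng):
        P = random_projection_matrix(rng)
        corr = synth_correspondences(P, rng)
        est = estimate_projection_matrix(corr)
        assert est.rms_reprojection < 1e-9
        assert np.allclose(est.matrix, P, atol=1e-8)

    def test_noise_level_sets_rms_and_more_points_help(self, rng):
        P = random_projection_matrix(rng)
        rms_small = estimate_projection_matrix(
            synth_correspondences(P, rng, n=60, noise=0.1)).rms_reprojection
        big = estimate_projection_matrix(
            synth_correspondences(P, rng, n=2000, noise=0.1))
        assert 0.05 < big.rms_reprojection < 0.2  # rms tracks the noise level
        # parameter error shrinks with the point count
        err_small = np.abs(
            estimate_projection_matrix(
                synth_correspondences(P, rng, n=60, noise=0.1)).matrix - P
        ).max()
        err_big = np.abs(big.matrix - P).max()
        assert err_big < err_small

    def test_monotone_residual_with_injected_noise(self, rng):
        P = random_projection_matrix(rng)
        pts = rng.uniform(-150, 150, size=(400, 3))
        res = []
        for noise in (0.0, 0.05, 0.1):
            ph = np.column_stack([pts, np.ones(len(pts))]) @ P.T
            pix = ph[:, :2] / ph[:, 2:3] + rng.normal(0, noise, (len(pts), 2))
            est = estimate_projection_matrix(
                CorrespondenceSet(world_points=pts, pixels=pix))
            res.append(est.mean_reprojection)
        assert res[0] < res[1] < res[2]

    def test_duplicated_views_change_nothing(self, rng):
        P = random_projection_matrix(rng)
        corr = synth_correspondences(P, rng, n=100)
        dup = CorrespondenceSet(
            world_points=np.vstack([corr.world_points, corr.world_points]),
            pixels=np.vstack([corr.pixels, corr.pixels]),
        )
        a = estimate_projection_matrix(corr).matrix
        b = estimate_projection_matrix(dup).matrix
        assert np.allclose(a, b, atol=1e-6)

    def test_coplanar_world_points_rejected(self, rng):
        P = random_projection_matrix(rng)
        pts = rng.uniform(-100, 100, size=(50, 3))
        pts[:, 2] = 0.0
        ph = np.column_stack([pts, np.ones(50)]) @ P.T
        corr = CorrespondenceSet(world_points=pts, pixels=ph[:, :2] / ph[:, 2:3])
        with pytest.raises(DegenerateGeometryError, match="coplanar"):
            estimate_projection_matrix(corr)

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(DegenerateGeometryError, match=">= 6"):
            estimate_projection_matrix(
                CorrespondenceSet(world_points=np.eye(3), pixels=np.zeros((3, 2))))


class TestReprojectionError:
    def test_exact_is_zero_and_perturbation_is_one(self, rng):
        P = random_projection_matrix(rng)
        corr = synth_correspondences(P, rng, n=50)
        pm = ProjectionMatrix(matrix=P)
        stats = reprojection_error(pm, corr)
        assert stats["max"] < 1e-9
        corr.pixels[7, 0] += 1.0
        stats = reprojection_error(pm, corr)
        assert stats["residuals"][7] == pytest.approx(1.0, abs=1e-9)
        assert stats["mean"] == pytest.approx(1.0 / 50, abs=1e-9)

    def test_invariant_under_common_rigid_motion(self, rng):
        from pmpscan.geometry import look_at_rotation
        P = random_projection_matrix(rng)
        corr = synth_correspondences(P, rng, n=80, noise=0.2)
        pm = estimate_projection_matrix(corr, refine=False)
        base = reprojection_error(pm, corr)["rms"]
        R = look_at_rotation([5, 4, 3], [0, 0, 0])
        t = np.array([10.0, -20.0, 5.0])
        moved = CorrespondenceSet(
            world_points=corr.world_points @ R.T + t, pixels=corr.pixels)
        T = np.eye(4)
        T[:3, :3] = R
        T[:3, 3] = t
        pm_moved = ProjectionMatrix(matrix=pm.matrix @ np.linalg.inv(T))
        assert reprojection_error(pm_moved, moved)["rms"] == pytest.approx(base, rel=1e-9)


class TestPhaseToProjector:
    def test_examples(self):
        assert projector_pixel_from_phase(0.0, 120.0) == 0.0
        assert projector_pixel_from_phase(2 * np.pi, 120.0) == pytest.approx(120.0)
        # single-period pattern reduces to the textbook full-width mapping
        assert projector_pixel_from_phase(np.pi, 1920.0) == pytest.approx(960.0)

    def test_subpixel_map_sampling(self, rng):
        # a linear map sampled through the weighted plane fit is exact
        vv, uu = np.mgrid[0:40, 0:40]
        m = 3.0 + 0.25 * uu - 0.1 * vv
        w = np.ones_like(m)
        got = sample_map_subpixel(m, w, 17.3, 21.8)
        assert got == pytest.approx(3.0 + 0.25 * 17.3 - 0.1 * 21.8, abs=1e-9)
        assert sample_map_subpixel(m, np.zeros_like(m), 17.3, 21.8) is None
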