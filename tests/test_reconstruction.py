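import numpy as np
import pytest

from pmpscan.experiments import make_scene, rig_devices, scan_patterns
from pmpscan.reconstruction import (
    PointCloud,
    ReferencePlaneGeometry,
    height_from_phase,
    remove_statistical_outliers,
    scan_to_pointcloud,
    triangulate_pixels,
)


def two_ray_oracle(Pc, Pp, uc, vc, up):
    """Independent oracle: camera pixel ray intersected with the projector
    column plane ``{X : (p1 - up * p3) . [X, 1] = 0}``."""
    M = np.linalg.inv(Pc[:, :3])
    center = -M @ Pc[:, 3]
    d = M @ np.array([uc, vc, 1.0])
    plane = Pp[0] - up * Pp[2]          # 4-vector
    n, c = plane[:3], plane[3]
    t = -(n @ center + c) / (n @ d)
    return center + t * d


class TestTriangulation:
    @pytest.fixture(scope="class")
    def matrices(self, config_full, ideal_calib_full):
        return (ideal_calib_full.camera.matrix, ideal_calib_full.projector.matrix)

    def test_noiseless_closure(self, matrices, rng):
        Pc, Pp = matrices
        pts = rng.uniform(-100, 100, size=(200, 3))
        ph_c = np.column_stack([pts, np.ones(200)]) @ Pc.T
        uvc = ph_c[:, :2] / ph_c[:, 2:3]
        ph_p = np.column_stack([pts, np.ones(200)]) @ Pp.T
        up = ph_p[:, 0] / ph_p[:, 2]
        got, ok = triangulate_pixels(Pc, Pp, uvc[:, 0], uvc[:, 1], up)
        assert ok.all()
        assert np.abs(got - pts).max() < 1e-8

    def test_agrees_with_two_ray_oracle(self, matrices, rng):
        Pc, Pp = matrices
        n = 1000
        uc = rng.uniform(0, 1137, n)
        vc = rng.uniform(0, 488, n)
        up = rng.uniform(200, 1700, n)
        got, ok = triangulate_pixels(Pc, Pp, uc, vc, up)
        ref = np.array([two_ray_oracle(Pc, Pp, a, b, c)
                        for a, b, c in zip(uc, vc, up)])
        assert np.abs(got[ok] - ref[ok]).max() < 1e-6
        assert ok.mean() > 0.99

    def test_degenerate_ray_rejected(self, matrices):
        Pc, Pp = matrices
        # a projector "column plane" parallel to the camera ray: synthesize by
        # using the camera itself as the projector (identical device)
        pt, ok = triangulate_pixels(Pc, Pc, 500.0, 200.0, 500.0)
        assert not ok
        assert np.isnan(pt).all()


class TestHeightFromPhase:
    def test_zero_phase_is_zero_height(self):
        geom = ReferencePlaneGeometry()
        assert height_from_phase(0.0, geom) == 0.0

    def test_reference_values(self):
        geom = ReferencePlaneGeometry(L=1000, D=400, f0=0.172)
        h = height_from_phase(2 * np.pi, geom)
        assert h == pytest.approx(1000.0 / (0.172 * 400 + 1), abs=1e-9)
        assert h == pytest.approx(14.327, abs=5e-4)

    def test_small_phase_limit_is_linear(self):
        geom = ReferencePlaneGeometry(L=1000, D=400, f0=0.172)
        eps = 1e-6
        slope = height_from_phase(eps, geom) / eps
        assert slope == pytest.approx(1000.0 / (2 * np.pi * 0.172 * 400), rel=1e-5)

    def test_singular_denominator_is_nan(self):
        geom = ReferencePlaneGeometry(L=1000, D=400, f0=0.172)
        assert np.isnan(height_from_phase(-2 * np.pi * 0.172 * 400, geom))

    def test_invalid_geometry(self):
        with pytest.raises(ValueError):
            ReferencePlaneGeometry(L=-1.0)


class TestOutlierFilter:
    def test_keeps_small_sets(self, rng):
        pts = rng.normal(size=(5, 3))
        assert remove_statistical_outliers(pts).all()

    def test_removes_isolated_stray_keeps_sparse_sheet(self, rng):
        # dense sheet + sparse sheet + one stray far point
        dense = np.column_stack([rng.uniform(0, 10, (400,)),
                                 rng.uniform(0, 10, (400,)), np.zeros(400)])
        sparse = np.column_stack([rng.uniform(20, 60, (100,)),
                                  rng.uniform(0, 40, (100,)), np.zeros(100)])
        stray = np.array([[5.0, 5.0, 40.0]])
        pts = np.vstack([dense, sparse, stray])
        keep = remove_statistical_outliers(pts)
        assert not keep[-1]
        assert keep[:400].mean() > 0.99
        assert keep[400:500].mean() > 0.9


class TestScanToPointcloud:
    def test_plane_scan_fits_plane(self, config_small, ideal_calib_small):
        import trimesh
        v = np.array([[-2000, -2000, 0], [2000, -2000, 0], [2000, 2000, 0],
                      [-2000, 2000, 0]], dtype=float)
        mesh = trimesh.Trimesh(vertices=v, faces=[[0, 1, 2], [0, 2, 3]],
                               process=False)
        scene = make_scene(config_small, mesh, aperture=0.0)
        patterns = scan_patterns(config_small)
        cloud = scan_to_pointcloud(scene, patterns, ideal_calib_small.camera,
                                   ideal_calib_small.projector)
        assert len(cloud) > 1000
        # plane z = 0: RMS of z residuals under 0.1 mm
        assert np.sqrt((cloud.points[:, 2] ** 2).mean()) < 0.1

    def test_determinism(self, config_small, ideal_calib_small, frustum):
        scene = make_scene(config_small, frustum)
        patterns = scan_patterns(config_small)
        a = scan_to_pointcloud(scene, patterns, ideal_calib_small.camera,
                               ideal_calib_small.projector)
        b = scan_to_pointcloud(scene, patterns, ideal_calib_small.camera,
                               ideal_calib_small.projector)
        assert np.array_equal(a.points, b.points)

    def test_empty_mask_warns_and_returns_empty(self, config_small, ideal_calib_small):
        import trimesh
        # a mesh behind the camera: no pixel can see it
        mesh = trimesh.creation.box(extents=[10, 10, 10])
        mesh.apply_translation([0, 0, 5000.0])
        scene = make_scene(config_small, mesh)
        patterns = scan_patterns(config_small)
        with pytest.warns(UserWarning, match="empty"):
            cloud = scan_to_pointcloud(scene, patterns, ideal_calib_small.camera,
                                       ideal_calib_small.projector)
        assert len(cloud) == 0

    def test_cloud_roundtrip(self, tmp_path, rng):
        cloud = PointCloud(points=rng.uniform(-10, 10, size=(50, 3)))
        cloud.save(tmp_path / "c.ply")
        back = PointCloud.load(tmp_path / "c.ply")
        assert np.allclose(back.points, cloud.points, atol=1e-12)
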