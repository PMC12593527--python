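"""End-to-end experiment drivers: calibration run and parameter sweeps.

Reproduces the simulator studies from a single configuration: the
distance sweep (object moved through the camera's depth of field), the
viewpoint sweep (lateral and foot-of-couch views of a torso), the
light-intensity sweep (gain 0.5 / 1 / 2), and the 20-pose board
calibration.  Each driver returns a tidy ``pandas.DataFrame`` whose columns
mirror the study tables (CMAE/MAE/HD/MDTA as applicable) plus provenance
columns (fixture and config hashes).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
import trimesh
import yaml

from .calibration import (
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
    sample_map_subpixel,
)
from .fixtures import make_frustum, make_torso
from .geometry import PinholeDevice, build_rig
from .patterns import PSPSpec, PatternStack, make_scan_patterns
from .phase import decode_fringe_orders, modulation_mask, unwrap_phase, wrapped_phase
from .raycast import RayCaster
from .render import (CapturedStack, PhotometricParams, SceneConfig,
                     render_frame, render_stack, render_white_patch)
from .reconstruction import PointCloud, scan_to_pointcloud
from . import metrics as pm_metrics

logger = logging.getLogger("pmpscan")

__all__ = [
    "ExperimentConfig",
    "CalibrationReport",
    "rig_devices",
    "make_scene",
    "scan_patterns",
    "run_scan",
    "run_calibration",
    "run_distance_sweep",
    "run_view_sweep",
    "run_intensity_sweep",
    "scannable_surface_samples",
    "scan_metrics",
]


@dataclass
class ExperimentConfig:
    """Rig and processing defaults for the standard virtual scanner.

    The defaults are the reference configuration: 20 mm camera lens on a
    36 x 24 mm sensor at 1138 x 489 px, a 1920 x 1080 projector, baseline
    D = 400 mm, stand-off L = 1000 mm, 12-step PSP with 16 fringe periods
    plus complementary gray codes.  ``f0`` parameterizes the reference-plane
    height mapping (line-pairs/mm) used by the secondary reference-plane mode.
    """

    camera_focal: float = 20.0
    camera_sensor: tuple = (36.0, 24.0)
    camera_resolution: tuple = (1138, 489)
    projector_focal: float = 20.0
    projector_sensor: tuple = (12.8, 7.2)
    projector_resolution: tuple = (1920, 1080)
    D: float = 400.0
    L: float = 1000.0
    f0: float = 0.172
    n_steps: int = 12
    n_periods: int = 16
    n_periods_v: int = 9
    focus_distance: float = 1000.0
    aperture_diameter: float = 50.0
    supersample: int = 2
    calib_supersample: int = 32
    gain: float = 1.0
    ambient: float = 0.05
    albedo: float = 0.90
    noise_sigma: float = 0.0
    b_min: float = 0.05
    dc_max: float = 0.98
    seed: int = 0
    n_calib_poses: int = 20
    resolution_scale: float = 1.0

    def __post_init__(self):
        for name in ("camera_focal", "projector_focal", "D", "L", "f0", "gain"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    # -- serialization --------------------------------------------------
    def to_yaml(self, path) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for k in ("camera_sensor", "camera_resolution", "projector_sensor",
                  "projector_resolution"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    def hash(self) -> str:
        payload = yaml.safe_dump(
            {k: list(v) if isinstance(v, tuple) else v for k, v in asdict(self).items()},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def scaled(self, scale: float) -> "ExperimentConfig":
        """Resolution-scaled copy for fast runs (camera raster only)."""
        ru, rv = self.camera_resolution
        return replace(
            self,
            camera_resolution=(max(8, round(ru * scale)), max(8, round(rv * scale))),
            resolution_scale=self.resolution_scale * scale,
        )


def fixture_hash(mesh: trimesh.Trimesh) -> str:
    h = hashlib.sha256()
    h.update(np.asarray(mesh.vertices, dtype=np.float64).tobytes())
    h.update(np.asarray(mesh.faces, dtype=np.int64).tobytes())
    return h.hexdigest()[:12]


def rig_devices(config: ExperimentConfig):
    """Posed (camera, projector) pair for the configured rig."""
    cam = PinholeDevice(
        focal_length=config.camera_focal,
        sensor_width=config.camera_sensor[0],
        sensor_height=config.camera_sensor[1],
        resolution_u=config.camera_resolution[0],
        resolution_v=config.camera_resolution[1],
        role="camera",
    )
    proj = PinholeDevice(
        focal_length=config.projector_focal,
        sensor_width=config.projector_sensor[0],
        sensor_height=config.projector_sensor[1],
        resolution_u=config.projector_resolution[0],
        resolution_v=config.projector_resolution[1],
        role="projector",
    )
    return build_rig(cam, proj, D=config.D, L=config.L)


def make_scene(config: ExperimentConfig, mesh, albedo_fn=None, gain=None,
               supersample=None, aperture=None, seed=None) -> SceneConfig:
    cam, proj = rig_devices(config)
    photo = PhotometricParams(
        ambient=config.ambient,
        albedo=config.albedo,
        gain=config.gain if gain is None else gain,
        noise_sigma=config.noise_sigma,
    )
    return SceneConfig(
        camera=cam, projector=proj, mesh=mesh, photometrics=photo,
        D=config.D, L=config.L,
        focus_distance=config.focus_distance,
        aperture_diameter=config.aperture_diameter if aperture is None else aperture,
        rng_seed=config.seed if seed is None else seed,
        supersample=config.supersample if supersample is None else supersample,
        albedo_fn=albedo_fn,
    )


def vertical_psp_spec(config: ExperimentConfig) -> PSPSpec:
    return PSPSpec(
        width_px=config.projector_resolution[0],
        height_px=config.projector_resolution[1],
        n_steps=config.n_steps,
        n_periods=config.n_periods,
        axis="u",
    )


def horizontal_psp_spec(config: ExperimentConfig) -> PSPSpec:
    return PSPSpec(
        width_px=config.projector_resolution[0],
        height_px=config.projector_resolution[1],
        n_steps=config.n_steps,
        n_periods=config.n_periods_v,
        axis="v",
    )


def scan_patterns(config: ExperimentConfig, axis: str = "u") -> PatternStack:
    spec = vertical_psp_spec(config) if axis == "u" else horizontal_psp_spec(config)
    return make_scan_patterns(spec)


def run_scan(config: ExperimentConfig, mesh, calib: "CalibrationReport",
             gain=None, patterns=None, return_stack: bool = False):
    """Scan a mesh with the calibrated rig and reconstruct a point cloud."""
    patterns = patterns if patterns is not None else scan_patterns(config)
    scene = make_scene(config, mesh, gain=gain)
    stack = render_stack(scene, patterns)
    cloud = scan_to_pointcloud(
        scene, patterns, calib.camera, calib.projector,
        b_min=config.b_min, dc_max=config.dc_max, captured=stack,
    )
    if return_stack:
        return cloud, stack
    return cloud


# ---------------------------------------------------------------------------
# calibration run
# ---------------------------------------------------------------------------

@dataclass
class CalibrationReport:
    camera: ProjectionMatrix
    projector: ProjectionMatrix
    n_poses: int = 0
    n_points: int = 0
    dropped_poses: list = field(default_factory=list)
    config_hash: str = ""
    detected_centers: "pd.DataFrame | None" = None

    def centers_to_csv(self, path) -> None:
        """Write the detected sub-pixel dot centers (one row per dot/pose)."""
        if self.detected_centers is None:
            raise ValueError("no detected centers recorded")
        self.detected_centers.to_csv(path, index=False)

    def to_yaml(self, path) -> None:
        def pm_dict(pm):
            return {
                "matrix": np.asarray(pm.matrix).tolist(),
                "role": pm.role,
                "mean_reprojection_px": float(pm.mean_reprojection),
                "rms_reprojection_px": float(pm.rms_reprojection),
                "max_reprojection_px": float(pm.max_reprojection),
                "n_points": int(pm.n_points),
                "per_view": pm.per_view,
            }

        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "camera": pm_dict(self.camera),
                    "projector": pm_dict(self.projector),
                    "n_poses": self.n_poses,
                    "n_points": self.n_points,
                    "dropped_poses": self.dropped_poses,
                    "config_hash": self.config_hash,
                },
                fh,
                sort_keys=False,
            )

    @classmethod
    def from_yaml(cls, path) -> "CalibrationReport":
        with open(path) as fh:
            d = yaml.safe_load(fh)

        def pm_load(dd, role):
            return ProjectionMatrix(
                matrix=np.asarray(dd["matrix"], dtype=float), role=role,
                mean_reprojection=dd["mean_reprojection_px"],
                rms_reprojection=dd["rms_reprojection_px"],
                max_reprojection=dd["max_reprojection_px"],
                n_points=dd["n_points"], per_view=dd.get("per_view", []),
            )

        return cls(
            camera=pm_load(d["camera"], "camera"),
            projector=pm_load(d["projector"], "projector"),
            n_poses=d.get("n_poses", 0), n_points=d.get("n_points", 0),
            dropped_poses=d.get("dropped_poses", []),
            config_hash=d.get("config_hash", ""),
        )


def exact_calibration(config: ExperimentConfig) -> CalibrationReport:
    """Ideal calibration straight from the rig's true device matrices.

    Useful as a ground-truth reference and for experiments that probe the
    rendering/decoding physics rather than the calibration pipeline.
    """
    cam, proj = rig_devices(config)
    Pc = cam.projection_matrix
    Pp = proj.projection_matrix
    return CalibrationReport(
        camera=ProjectionMatrix(matrix=Pc / Pc[2, 3], role="camera",
                                mean_reprojection=0.0, rms_reprojection=0.0,
                                max_reprojection=0.0),
        projector=ProjectionMatrix(matrix=Pp / Pp[2, 3], role="projector",
                                   mean_reprojection=0.0, rms_reprojection=0.0,
                                   max_reprojection=0.0),
        n_poses=0, n_points=0, config_hash=config.hash(),
    )


def _decode_scan(stack_frames, kinds, b_min, dc_max, spec):
    """Wrapped phase -> orders -> absolute phase -> projector coordinate."""
    sub = CapturedStack(frames=stack_frames, kinds=kinds, depth_map=None)
    wrapped = wrapped_phase(sub.select("psp"))
    orders = decode_fringe_orders(sub.select("gray_k1"), sub.select("gray_k2"), wrapped.dc)
    unwrapped = unwrap_phase(wrapped.phi, orders)
    mask = modulation_mask(wrapped, b_min=b_min, dc_max=dc_max) & unwrapped.valid_mask
    coord = projector_pixel_from_phase(
        unwrapped.Phi, spec.pixels_per_period, phase_offset=spec.phase_offset
    )
    return coord, wrapped.modulation * mask


def run_calibration(config: ExperimentConfig, board: CalibBoard | None = None,
                    n_poses: int | None = None) -> CalibrationReport:
    """Full synthetic calibration: render, detect, scan, estimate, report.

    Per board pose: a uniform-white frame (rendered with high supersampling
    and no defocus -- calibration imagery is assumed in focus) for dot
    detection, then vertical and horizontal fringe sequences whose absolute
    phase maps each detected dot to a projector pixel.  Poses failing
    detection are dropped with a warning; fewer than 3 usable poses aborts.
    """
    board = board or CalibBoard()
    n_poses = n_poses if n_poses is not None else config.n_calib_poses
    poses = make_board_poses(n_poses=n_poses, seed=config.seed)
    spec_v = vertical_psp_spec(config)
    spec_h = horizontal_psp_spec(config)
    pat_v = make_scan_patterns(spec_v)
    pat_h = make_scan_patterns(spec_h)
    combined = pat_v + pat_h
    n_v = len(pat_v)
    Wp, Hp = config.projector_resolution
    white = np.ones((Hp, Wp))

    cam_world, cam_pix, cam_view = [], [], []
    prj_world, prj_pix, prj_view = [], [], []
    center_rows = []
    dropped = []
    for vi, pose in enumerate(poses):
        mesh, albedo_fn, world_centers = board_mesh_and_albedo(board, pose)
        scene_hi = make_scene(config, mesh, albedo_fn=albedo_fn,
                              supersample=2, aperture=0.0)
        img, _ = render_frame(scene_hi, white)

        def refine(r0, r1, c0, c1, _scene=scene_hi):
            return render_white_patch(_scene, r0, r1, c0, c1,
                                      supersample=config.calib_supersample)

        try:
            centers = detect_circle_centers(img, board, refine_patch=refine)
        except DetectionError as exc:
            logger.warning("pose %d dropped: %s", vi, exc)
            dropped.append({"pose": vi, "reason": str(exc)})
            continue
        cam_world.append(world_centers)
        cam_pix.append(centers)
        cam_view.append(np.full(len(centers), vi))
        for gi, (grid_rc, (u, v)) in enumerate(zip(board.grid_indices(), centers)):
            center_rows.append({"view": vi, "grid_row": grid_rc[0],
                                "grid_col": grid_rc[1], "u_px": u, "v_px": v})

        scene = make_scene(config, mesh, albedo_fn=albedo_fn, supersample=1,
                           aperture=0.0)
        stack = render_stack(scene, combined)
        up_map, w_u = _decode_scan(stack.frames[:n_v], combined.kinds[:n_v],
                                   config.b_min, config.dc_max, spec_v)
        vp_map, w_v = _decode_scan(stack.frames[n_v:], combined.kinds[n_v:],
                                   config.b_min, config.dc_max, spec_h)
        for wc, (u, v) in zip(world_centers, centers):
            up = sample_map_subpixel(up_map, w_u, u, v)
            vp = sample_map_subpixel(vp_map, w_v, u, v)
            if up is None or vp is None:
                continue
            prj_world.append(wc)
            prj_pix.append([up, vp])
            prj_view.append(vi)

    if len(cam_world) < 3:
        raise DegenerateGeometryError(
            f"only {len(cam_world)} usable calibration poses (need >= 3)"
        )
    cam_corr = CorrespondenceSet(
        world_points=np.concatenate(cam_world),
        pixels=np.concatenate(cam_pix),
        view_index=np.concatenate(cam_view),
    )
    prj_corr = CorrespondenceSet(
        world_points=np.asarray(prj_world),
        pixels=np.asarray(prj_pix),
        view_index=np.asarray(prj_view),
    )
    cam_pm = estimate_projection_matrix(cam_corr, role="camera")
    prj_pm = estimate_projection_matrix(prj_corr, role="projector")
    logger.info(
        "calibration: camera mean residual %.4f px, projector %.4f px "
        "(%d poses, %d dots)",
        cam_pm.mean_reprojection, prj_pm.mean_reprojection,
        len(set(cam_corr.view_index.tolist())), cam_pm.n_points,
    )
    return CalibrationReport(
        camera=cam_pm, projector=prj_pm,
        n_poses=n_poses - len(dropped), n_points=cam_pm.n_points,
        dropped_poses=dropped, config_hash=config.hash(),
        detected_centers=pd.DataFrame(center_rows),
    )


# ---------------------------------------------------------------------------
# ground-truth sampling and metrics
# ---------------------------------------------------------------------------

def _scannable_point_mask(config: ExperimentConfig, mesh, pts, normals,
                          cos_cam_min: float, cos_proj_min: float) -> np.ndarray:
    """Visibility + incidence test of surface points against both devices."""
    cam, proj = rig_devices(config)
    keep = np.ones(len(pts), dtype=bool)
    caster = RayCaster(mesh.vertices, mesh.faces)
    for device, cos_min in ((cam, cos_cam_min), (proj, cos_proj_min)):
        to_dev = device.center - pts
        to_dev /= np.linalg.norm(to_dev, axis=1, keepdims=True)
        cosine = np.einsum("ij,ij->i", normals, to_dev)
        vis = cosine > cos_min
        if vis.any():
            vis[vis.copy()] &= ~caster.occluded(pts[vis], device.center, t_min=0.5)
        uv, depth = device.project_points(pts)
        vis &= (
            (depth > 0)
            & (uv[:, 0] > -0.5) & (uv[:, 0] < device.resolution_u - 0.5)
            & (uv[:, 1] > -0.5) & (uv[:, 1] < device.resolution_v - 0.5)
        )
        keep &= vis
    return keep


def scannable_surface_samples(config: ExperimentConfig, mesh,
                              density: float = 10.0, seed: int = 0,
                              cos_cam_min: float = 0.35,
                              cos_proj_min: float = 0.20,
                              edge_margin: float = 5.0):
    """Dense ground-truth samples over the surface a single scan can resolve.

    Samples the mesh at ``density`` points/mm^2 and keeps points that face
    and are unoccluded to both devices.  ``cos_cam_min`` additionally demands
    that the camera's pixel footprint on the surface stays within ~3x its
    fronto-parallel size, so set-to-set distances measure reconstruction
    error rather than pixel-sampling gaps on near-grazing faces.  The kept
    region is finally eroded by ``edge_margin`` mm at its boundary with the
    unscannable region (edge pixels mixing two surfaces are inherently
    unmeasurable).

    Returns ``(samples, excluded)``: the evaluation samples and the excluded
    sample set (used to crop reconstructed clouds to the same region).
    """
    n = max(1000, int(mesh.area * density))
    pts, face_idx = trimesh.sample.sample_surface(mesh, n, seed=seed)
    normals = mesh.face_normals[face_idx]
    keep = _scannable_point_mask(config, mesh, pts, normals,
                                 cos_cam_min, cos_proj_min)
    good = pts[keep]
    bad = pts[~keep]
    if edge_margin > 0 and len(bad) and len(good):
        from scipy.spatial import cKDTree

        d, _ = cKDTree(bad).query(good)
        good = good[d > edge_margin]
    return good, bad


def crop_cloud_to_scannable(cloud: PointCloud, mesh, config: ExperimentConfig,
                            excluded: np.ndarray,
                            cos_cam_min: float = 0.35,
                            cos_proj_min: float = 0.20,
                            edge_margin: float = 5.0) -> PointCloud:
    """Cloud restricted to the scannable evaluation region.

    Each point is projected to its closest surface foot; the foot must pass
    the same visibility/incidence test as the ground-truth samples and lie
    farther than ``edge_margin`` from the excluded region.
    """
    if len(cloud) == 0:
        return cloud
    dist, face_idx = pm_metrics.point_to_surface_distances(
        cloud.points, mesh, return_closest=True
    )
    normals = mesh.face_normals[face_idx]
    # foot point = projection onto the closest face plane (adequate here:
    # classification only)
    origin = mesh.vertices[mesh.faces[face_idx][:, 0]]
    feet = cloud.points - ((cloud.points - origin) * normals).sum(1)[:, None] * normals
    keep = _scannable_point_mask(config, mesh, feet, normals,
                                 cos_cam_min, cos_proj_min)
    if edge_margin > 0 and len(excluded):
        from scipy.spatial import cKDTree

        d, _ = cKDTree(excluded).query(feet)
        keep &= d > edge_margin
    return cloud.subset(keep)


def scan_metrics(cloud: PointCloud, mesh, config: ExperimentConfig,
                 truth_samples=None, with_cmae: bool = True,
                 density: float = 10.0) -> pm_metrics.MetricsReport:
    """MAE / CMAE / HD / MDTA of a reconstructed cloud vs its source mesh.

    MAE uses the full filtered cloud against the full mesh surface; HD and
    MDTA are computed between the scannable-region samples and the cloud
    cropped to that same region (see :func:`scannable_surface_samples`).
    """
    if truth_samples is None:
        truth_samples = scannable_surface_samples(config, mesh, density=density,
                                                  seed=config.seed)
    samples, excluded = truth_samples
    report = pm_metrics.MetricsReport()
    report.mae = pm_metrics.mae_point_to_surface(cloud, mesh)
    cropped = crop_cloud_to_scannable(cloud, mesh, config, excluded)
    if len(cropped) == 0 or len(samples) == 0:
        report.hd = np.nan
        report.mdta = np.nan
    else:
        report.hd = pm_metrics.hausdorff(cropped, samples)
        report.mdta = pm_metrics.mdta(cropped, samples)
    if with_cmae:
        report.cmae = pm_metrics.cmae(cloud, mesh)
    report.counts = {
        "points": len(cloud),
        "points_evaluated": len(cropped),
        "truth_samples": len(samples),
        "rejected": int(cloud.meta.get("n_outliers_removed", 0)),
    }
    return report


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------

def run_distance_sweep(config: ExperimentConfig, calib: CalibrationReport,
                       distances=(900.0, 950.0, 1000.0, 1050.0, 1100.0),
                       mesh=None, density: float = 10.0) -> pd.DataFrame:
    """Scan the frustum at several stand-off distances (depth-of-field study).

    The rig (and its calibration) stays fixed; the object is translated
    along the optical axis so the camera-to-surface distance takes each
    value in ``distances``.  Off-focus positions degrade through the
    thin-lens defocus model.
    """
    if not len(distances):
        raise ValueError("distances must be nonempty")
    base = mesh if mesh is not None else make_frustum()
    patterns = scan_patterns(config)
    rows = []
    for L in distances:
        moved = base.copy()
        moved.apply_translation([0.0, 0.0, config.L - L])
        try:
            cloud = run_scan(config, moved, calib, patterns=patterns)
            if len(cloud) == 0:
                raise RuntimeError("empty reconstruction")
            rep = scan_metrics(cloud, moved, config, density=density)
            rows.append({
                "position_mm": L, "cmae_mm": rep.cmae, "mae_mm": rep.mae,
                "hd_mm": rep.hd, "mdta_mm": rep.mdta,
                "n_points": rep.counts["points"], "failed": False,
            })
        except Exception as exc:  # flagged row, sweep continues
            logger.warning("distance %s failed: %s", L, exc)
            rows.append({"position_mm": L, "cmae_mm": np.nan, "mae_mm": np.nan,
                         "hd_mm": np.nan, "mdta_mm": np.nan, "n_points": 0,
                         "failed": True})
    df = pd.DataFrame(rows)
    df["fixture_hash"] = fixture_hash(base)
    df["config_hash"] = config.hash()
    return df


# Presets are applied to a torso lying along the x axis (the rig's baseline
# axis): both devices sit in the y = 0 plane, so the left/right lateral views
# (rotations about x) are exact mirror images of each other with respect to
# the rig, as they are for a physically repositioned scanner.
VIEW_PRESETS = {
    "left": ("x", -45.0),
    "right": ("x", 45.0),
    "distal": ("y", 65.0),
    "control": ("z", 0.0),
}


def _view_transform(axis: str, angle_deg: float) -> np.ndarray:
    ax = {"x": [1, 0, 0], "y": [0, 1, 0], "z": [0, 0, 1]}[axis]
    return trimesh.transformations.rotation_matrix(np.deg2rad(angle_deg), ax)


def run_view_sweep(config: ExperimentConfig, calib: CalibrationReport,
                   views=("left", "right", "distal"), mesh=None,
                   density: float = 2.0) -> pd.DataFrame:
    """Scan a torso-like body from lateral and foot-of-couch viewpoints.

    Implemented by rotating the body under the fixed calibrated rig, which
    is geometrically equivalent to repositioning the rig around the patient.
    """
    base = mesh if mesh is not None else make_torso()
    base = base.copy()
    # lie the body along the baseline (x) axis
    base.apply_transform(_view_transform("z", 90.0))
    patterns = scan_patterns(config)
    rows = []
    for view in views:
        axis, angle = VIEW_PRESETS[view]
        moved = base.copy()
        moved.apply_transform(_view_transform(axis, angle))
        # rest the highest surface at the focus plane
        moved.apply_translation([0, 0, -moved.bounds[1][2]])
        try:
            cloud, stack = run_scan(config, moved, calib, patterns=patterns,
                                    return_stack=True)
            if len(cloud) == 0:
                raise RuntimeError("empty reconstruction")
            truth = scannable_surface_samples(config, moved, density=density,
                                              seed=config.seed)
            rep = scan_metrics(cloud, moved, config, truth_samples=truth,
                               with_cmae=False)
            n_hit = int(np.isfinite(stack.depth_map).sum())
            rows.append({
                "view": view, "mae_mm": rep.mae, "hd_mm": rep.hd,
                "mdta_mm": rep.mdta, "n_points": rep.counts["points"],
                "coverage": rep.counts["points"] / max(n_hit, 1), "failed": False,
            })
        except Exception as exc:
            logger.warning("view %s failed: %s", view, exc)
            rows.append({"view": view, "mae_mm": np.nan, "hd_mm": np.nan,
                         "mdta_mm": np.nan, "n_points": 0, "coverage": 0.0,
                         "failed": True})
    df = pd.DataFrame(rows)
    df["fixture_hash"] = fixture_hash(base)
    df["config_hash"] = config.hash()
    return df


def run_intensity_sweep(config: ExperimentConfig, calib: CalibrationReport,
                        gains=(0.5, 1.0, 2.0), mesh=None,
                        density: float = 2.0) -> pd.DataFrame:
    """Scan under weak / normal / strong projector light (gain sweep)."""
    base = mesh if mesh is not None else make_torso()
    base = base.copy()
    base.apply_translation([0, 0, -base.bounds[1][2]])
    patterns = scan_patterns(config)
    truth = scannable_surface_samples(config, base, density=density,
                                      seed=config.seed)
    rows = []
    for gain in gains:
        try:
            cloud, stack = run_scan(config, base, calib, gain=gain,
                                    patterns=patterns, return_stack=True)
            if len(cloud) == 0:
                raise RuntimeError("empty reconstruction")
            rep = scan_metrics(cloud, base, config, truth_samples=truth,
                               with_cmae=False)
            psp = stack.select("psp")
            hit = np.isfinite(stack.depth_map)
            sat = float((psp == 255).any(axis=0)[hit].mean()) if hit.any() else 0.0
            rows.append({
                "gain": gain, "mae_mm": rep.mae, "hd_mm": rep.hd,
                "mdta_mm": rep.mdta, "n_points": rep.counts["points"],
                "saturation_fraction": sat, "failed": False,
            })
        except Exception as exc:
            logger.warning("gain %s failed: %s", gain, exc)
            rows.append({"gain": gain, "mae_mm": np.nan, "hd_mm": np.nan,
                         "mdta_mm": np.nan, "n_points": 0,
                         "saturation_fraction": np.nan, "failed": True})
    df = pd.DataFrame(rows)
    df["fixture_hash"] = fixture_hash(base)
    df["config_hash"] = config.hash()
    return df
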