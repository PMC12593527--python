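"""Pinhole camera/projector models and rig geometry.

Conventions
-----------
* World units are millimetres, right-handed frame; the default rig places the
  camera above the scene looking down ``-Z``.
* Image coordinates: origin top-left, ``u`` rightward, ``v`` downward,
  pixel centers at integer coordinates, 0-based.
* A device pose is (``rotation`` world->device, ``center`` in world mm), so a
  world point maps to device coordinates as ``R @ (X - C)``; the device looks
  along its local ``+z``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["PinholeDevice", "look_at_rotation", "build_rig"]


def look_at_rotation(center, target, up_hint=(0.0, 1.0, 0.0)):
    """World->device rotation for a device at ``center`` looking at ``target``.

    The device ``+z`` axis points from ``center`` to ``target``; image "down"
    (+v) is anti-aligned with ``up_hint`` as far as orthogonality allows.
    """
    center = np.asarray(center, dtype=float)
    forward = np.asarray(target, dtype=float) - center
    norm = np.linalg.norm(forward)
    if norm == 0:
        raise ValueError("look_at: center and target coincide")
    z = forward / norm
    up = np.asarray(up_hint, dtype=float)
    x = np.cross(up, z)
    if np.linalg.norm(x) < 1e-12:  # forward parallel to up hint
        up = np.array([0.0, 0.0, 1.0]) if abs(z[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
        x = np.cross(up, z)
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    return np.stack([x, y, z], axis=0)


@dataclass
class PinholeDevice:
    """An ideal pinhole imager (camera or projector).

    Parameters
    ----------
    focal_length : float
        Focal length in mm.
    sensor_width, sensor_height : float
        Physical sensor (or projector panel) size in mm.
    resolution_u, resolution_v : int
        Pixel counts along u (columns) and v (rows).
    principal_point : (float, float), optional
        (cu, cv) in pixels; defaults to the sensor center,
        ``((res_u - 1) / 2, (res_v - 1) / 2)`` under the integer-pixel-center
        convention.
    rotation, center : arrays
        Pose: world->device rotation and device center in world mm.
    role : str
        ``"camera"`` or ``"projector"`` (informational).
    """

    focal_length: float
    sensor_width: float
    sensor_height: float
    resolution_u: int
    resolution_v: int
    principal_point: tuple[float, float] | None = None
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    role: str = "camera"

    def __post_init__(self):
        if self.focal_length <= 0:
            raise ValueError("focal_length must be positive")
        if self.resolution_u < 1 or self.resolution_v < 1:
            raise ValueError("resolution must be at least 1x1")
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.center = np.asarray(self.center, dtype=float)
        err = np.abs(self.rotation @ self.rotation.T - np.eye(3)).max()
        if err > 1e-9:
            raise ValueError(f"rotation is not orthonormal (deviation {err:g})")
        if self.principal_point is None:
            self.principal_point = (
                (self.resolution_u - 1) / 2.0,
                (self.resolution_v - 1) / 2.0,
            )

    # -- intrinsics -----------------------------------------------------
    @property
    def pixel_pitch_u(self) -> float:
        return self.sensor_width / self.resolution_u

    @property
    def pixel_pitch_v(self) -> float:
        return self.sensor_height / self.resolution_v

    @property
    def fx(self) -> float:
        return self.focal_length / self.pixel_pitch_u

    @property
    def fy(self) -> float:
        return self.focal_length / self.pixel_pitch_v

    @property
    def intrinsic_matrix(self) -> np.ndarray:
        cu, cv = self.principal_point
        return np.array([[self.fx, 0.0, cu], [0.0, self.fy, cv], [0.0, 0.0, 1.0]])

    @property
    def projection_matrix(self) -> np.ndarray:
        """3x4 world->pixel matrix ``K [R | -R C]`` (unnormalized)."""
        Rt = np.hstack([self.rotation, -self.rotation @ self.center[:, None]])
        return self.intrinsic_matrix @ Rt

    # -- projection -----------------------------------------------------
    def project_points(self, points):
        """Project world points to pixel coordinates.

        Returns ``(uv, depth)`` where ``uv`` has shape (..., 2) and ``depth``
        is the signed device-frame z in mm.  Points with ``depth <= 0`` are
        behind the device; their pixel coordinates are still returned (from
        the homogeneous division) but should be treated as non-visible.
        """
        pts = np.asarray(points, dtype=float)
        squeeze = pts.ndim == 1
        pts = np.atleast_2d(pts)
        local = (pts - self.center) @ self.rotation.T
        depth = local[..., 2]
        with np.errstate(divide="ignore", invalid="ignore"):
            u = self.fx * local[..., 0] / depth + self.principal_point[0]
            v = self.fy * local[..., 1] / depth + self.principal_point[1]
        uv = np.stack([u, v], axis=-1)
        if squeeze:
            return uv[0], depth[0]
        return uv, depth

    def pixel_rays(self, u, v):
        """World-frame unit ray directions through pixels ``(u, v)``.

        Rays originate at ``self.center``.
        """
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        d = np.stack(
            [
                (u - self.principal_point[0]) / self.fx,
                (v - self.principal_point[1]) / self.fy,
                np.ones_like(u),
            ],
            axis=-1,
        )
        d = d @ self.rotation  # R.T applied to each row
        return d / np.linalg.norm(d, axis=-1, keepdims=True)

    def posed_at(self, center, target, up_hint=(0.0, 1.0, 0.0)) -> "PinholeDevice":
        """Copy of this device placed at ``center`` looking at ``target``."""
        return replace(
            self,
            rotation=look_at_rotation(center, target, up_hint),
            center=np.asarray(center, dtype=float),
            principal_point=self.principal_point,
        )


def build_rig(camera: PinholeDevice, projector: PinholeDevice, D: float, L: float,
              target=(0.0, 0.0, 0.0), baseline_axis=(1.0, 0.0, 0.0)):
    """Pose a camera-projector pair from baseline ``D`` and stand-off ``L``.

    The camera sits at ``target + L * z_hat`` looking straight down at the
    scene center; the projector is displaced by ``D`` along ``baseline_axis``
    and pitched so its axis also passes through the scene center (triangulation
    angle ``atan(D / L)``).
    """
    if D <= 0 or L <= 0:
        raise ValueError("D and L must be positive")
    target = np.asarray(target, dtype=float)
    axis = np.asarray(baseline_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    cam_center = target + np.array([0.0, 0.0, L])
    proj_center = cam_center + D * axis
    cam = camera.posed_at(cam_center, target)
    proj = projector.posed_at(proj_center, target)
    cam.role = "camera"
    proj.role = "projector"
    assert abs(np.linalg.norm(cam.center - proj.center) - D) < 1e-6
    return cam, proj
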