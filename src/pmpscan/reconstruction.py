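"""Absolute phase -> 3-D geometry.

The primary path is calibrated triangulation: with camera matrix ``Ac`` and
projector matrix ``Ap`` (both 3x4, a34 = 1), a camera pixel ``(uc, vc)``
whose absolute phase maps to projector column ``up`` satisfies the 3x3
linear system built from two camera rows and one projector-column row:

    | a11c - uc a31c  a12c - uc a32c  a13c - uc a33c | |Xw|   |uc a34c - a14c|
    | a21c - vc a31c  a22c - vc a32c  a23c - vc a33c | |Yw| = |vc a34c - a24c|
    | a11p - up a31p  a12p - up a32p  a13p - up a33p | |Zw|   |up a34p - a14p|

A reference-plane height mapping ``h = L dphi / (2 pi f0 D + dphi)`` is kept
as a secondary, didactic mode (valid for small heights over a reference
plane in the crossed-optical-axis geometry).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .calibration import ProjectionMatrix, projector_pixel_from_phase
from .phase import (
    decode_fringe_orders,
    modulation_mask,
    unwrap_phase,
    wrapped_phase,
)
from .render import SceneConfig, render_stack

__all__ = [
    "ReferencePlaneGeometry",
    "PointCloud",
    "triangulate_pixels",
    "height_from_phase",
    "remove_statistical_outliers",
    "scan_to_pointcloud",
]


@dataclass(frozen=True)
class ReferencePlaneGeometry:
    """Crossed-axis reference-plane geometry for the height mapping.

    ``L``: camera-to-surface distance (mm); ``D``: camera-projector baseline
    (mm); ``f0``: fringe frequency on the reference plane (line-pairs/mm).
    """

    L: float = 1000.0
    D: float = 400.0
    f0: float = 0.172

    def __post_init__(self):
        if min(self.L, self.D, self.f0) <= 0:
            raise ValueError("L, D and f0 must all be positive")


@dataclass
class PointCloud:
    """Reconstructed surface samples (mm) with per-point provenance."""

    points: np.ndarray
    pixels: np.ndarray | None = None      # (N, 2) source camera pixel (u, v)
    phase: np.ndarray | None = None       # absolute phase per point
    quality: np.ndarray | None = None     # fringe modulation per point
    meta: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.points)

    def subset(self, mask) -> "PointCloud":
        def take(a):
            return a[mask] if a is not None else None

        return PointCloud(
            points=self.points[mask], pixels=take(self.pixels),
            phase=take(self.phase), quality=take(self.quality), meta=dict(self.meta),
        )

    def save(self, path) -> None:
        from .fixtures import write_pointcloud

        write_pointcloud(self.points, path)

    @classmethod
    def load(cls, path) -> "PointCloud":
        from .fixtures import read_pointcloud

        return cls(points=read_pointcloud(Path(path)))


def _triangulation_system(Ac: np.ndarray, Ap: np.ndarray, uc, vc, up):
    M = np.empty(uc.shape + (3, 3))
    b = np.empty(uc.shape + (3,))
    M[..., 0, :] = Ac[0, :3] - uc[..., None] * Ac[2, :3]
    M[..., 1, :] = Ac[1, :3] - vc[..., None] * Ac[2, :3]
    M[..., 2, :] = Ap[0, :3] - up[..., None] * Ap[2, :3]
    b[..., 0] = uc * Ac[2, 3] - Ac[0, 3]
    b[..., 1] = vc * Ac[2, 3] - Ac[1, 3]
    b[..., 2] = up * Ap[2, 3] - Ap[0, 3]
    return M, b


def triangulate_pixels(Ac, Ap, uc, vc, up, cond_limit: float = 1e10):
    """Solve the per-pixel triangulation system for world points.

    Parameters may be :class:`ProjectionMatrix` or raw 3x4 arrays; pixel
    inputs broadcast.  Returns ``(points, ok)`` where ``ok`` flags pixels
    whose system was well-conditioned (near-parallel camera/projector rays
    are rejected rather than returning wild points).
    """
    Ac = Ac.matrix if isinstance(Ac, ProjectionMatrix) else np.asarray(Ac, dtype=float)
    Ap = Ap.matrix if isinstance(Ap, ProjectionMatrix) else np.asarray(Ap, dtype=float)
    uc = np.asarray(uc, dtype=float)
    vc = np.asarray(vc, dtype=float)
    up = np.asarray(up, dtype=float)
    uc, vc, up = np.broadcast_arrays(uc, vc, up)
    scalar = uc.ndim == 0
    uc, vc, up = np.atleast_1d(uc, vc, up)
    M, b = _triangulation_system(Ac, Ap, uc, vc, up)
    det = np.linalg.det(M)
    row_norms = np.linalg.norm(M, axis=-1)
    scale = np.prod(row_norms, axis=-1)
    ok = np.abs(det) > scale / cond_limit
    Msafe = np.where(ok[..., None, None], M, np.eye(3))
    pts = np.linalg.solve(Msafe, b[..., None])[..., 0]
    pts[~ok] = np.nan
    if scalar:
        return pts[0], bool(ok[0])
    return pts, ok


def height_from_phase(delta_phi, geom: ReferencePlaneGeometry):
    """Reference-plane height mapping ``h = L dphi / (2 pi f0 D + dphi)``.

    ``delta_phi`` is the phase difference relative to the reference plane.
    Pixels whose denominator is near zero are returned as NaN.
    """
    dphi = np.asarray(delta_phi, dtype=float)
    den = 2 * np.pi * geom.f0 * geom.D + dphi
    with np.errstate(divide="ignore", invalid="ignore"):
        h = geom.L * dphi / den
    return np.where(np.abs(den) < 1e-9, np.nan, h)


def remove_statistical_outliers(points: np.ndarray, k: int = 8,
                                ratio: float = 2.5):
    """Mask of inliers by neighborhood-relative k-nearest-neighbor distance.

    A point is discarded when its mean distance to its ``k`` nearest
    neighbors exceeds ``ratio`` times the median of the same statistic over
    those neighbors.  Stray triangulations (mask borders, halo artifacts)
    stick out from whatever surface is nearby and are removed, while
    contiguous regions that are merely sparse -- e.g. strongly foreshortened
    flanks of a curved body -- are kept, which a global mean + n-sigma cut
    would wrongly delete.
    """
    n = len(points)
    if n <= k + 1:
        return np.ones(n, dtype=bool)
    tree = cKDTree(points)
    dist, idx = tree.query(points, k=k + 1)
    mean_d = dist[:, 1:].mean(axis=1)
    local_ref = np.median(mean_d[idx[:, 1:]], axis=1)
    return mean_d <= ratio * np.maximum(local_ref, 1e-12)


def scan_to_pointcloud(scene: SceneConfig, patterns, Ac, Ap,
                       b_min: float = 0.05, dc_max: float = 0.98,
                       outlier_k: int = 8, outlier_ratio: float = 2.5,
                       captured=None) -> PointCloud:
    """Full pipeline: render -> phase -> unwrap -> mask -> triangulate -> filter.

    ``patterns`` must contain PSP frames plus both gray-code sets (see
    :func:`pmpscan.patterns.make_scan_patterns`).  ``captured`` may supply a
    pre-rendered stack (e.g. for decode-only use); otherwise the scene is
    rendered here.  Returns a filtered :class:`PointCloud`; an empty cloud
    (with a warning in ``meta``) when the valid mask is empty.
    """
    stack = captured if captured is not None else render_stack(scene, patterns)
    psp = stack.select("psp")
    wrapped = wrapped_phase(psp)
    orders = decode_fringe_orders(
        stack.select("gray_k1"), stack.select("gray_k2"), wrapped.dc
    )
    unwrapped = unwrap_phase(wrapped.phi, orders)
    mask = modulation_mask(wrapped, b_min=b_min, dc_max=dc_max) & unwrapped.valid_mask

    spec = patterns.psp_spec
    up = projector_pixel_from_phase(
        unwrapped.Phi, spec.pixels_per_period, phase_offset=spec.phase_offset
    )
    H, W = mask.shape
    vv, uu = np.mgrid[0:H, 0:W]
    sel = mask.ravel()
    meta = {"n_pixels_valid": int(sel.sum()), "mask_shape": (H, W)}
    if not sel.any():
        import warnings

        warnings.warn("empty valid mask: no reconstructable pixels")
        meta["warning"] = "empty valid mask"
        return PointCloud(points=np.empty((0, 3)), meta=meta)

    pts, ok = triangulate_pixels(
        Ac, Ap, uu.ravel()[sel], vv.ravel()[sel], up.ravel()[sel]
    )
    pix = np.column_stack([uu.ravel()[sel], vv.ravel()[sel]])[ok]
    cloud = PointCloud(
        points=pts[ok],
        pixels=pix,
        phase=unwrapped.Phi.ravel()[sel][ok],
        quality=wrapped.modulation.ravel()[sel][ok],
        meta=meta,
    )
    inliers = remove_statistical_outliers(cloud.points, k=outlier_k, ratio=outlier_ratio)
    cloud = cloud.subset(inliers)
    cloud.meta["n_outliers_removed"] = int((~inliers).sum())
    return cloud
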