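"""Virtual camera: ray-cast rendering of fringe projections onto meshes.

The renderer replaces a game-engine scene with a deterministic physically
motivated model: per camera (sub)pixel the nearest mesh intersection is
found, the hit point is shadow-tested toward the projector, the projector
pattern is sampled bilinearly at the hit's projector pixel, and the raw
intensity follows a single-bounce Lambertian model

    raw = gain * (ambient + albedo * pattern * max(0, n . l))

clamped at the saturation level.  Saturation halo ("bloom") is modeled by
adding back a Gaussian-blurred copy of the clipped excess; defocus as a
per-pixel Gaussian blur whose sigma follows the thin-lens circle of
confusion at the pixel's depth; optional Gaussian sensor noise is seeded and
the result quantized to 8 bits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import PinholeDevice
from .raycast import RayCaster

__all__ = ["PhotometricParams", "SceneConfig", "CapturedStack", "SceneGeometry",
           "compute_geometry", "render_frame", "render_stack",
           "render_white_patch"]


@dataclass
class PhotometricParams:
    """Lighting/sensor model parameters (intensities unitless, 1.0 = full scale).

    ``gain`` is the light-intensity multiplier studied in the sweeps
    (0.5 = weak, 1 = normal, 2 = strong light).
    """

    ambient: float = 0.05
    albedo: float = 0.90
    gain: float = 1.0
    noise_sigma: float = 0.0
    saturation_level: float = 1.0
    bloom_radius: float = 18.0
    bloom_strength: float = 1.5

    def __post_init__(self):
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        for name in ("ambient", "albedo", "noise_sigma", "saturation_level",
                     "bloom_radius", "bloom_strength"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class SceneConfig:
    """Complete description of one virtual capture setup.

    ``mesh`` is a ``trimesh.Trimesh`` in world mm.  ``albedo_fn``, when given,
    maps world points (N, 3) to per-point albedo in (0, 1] (used for the
    calibration board's dot texture); otherwise the scalar
    ``photometrics.albedo`` applies everywhere.
    """

    camera: PinholeDevice
    projector: PinholeDevice
    mesh: "object"
    photometrics: PhotometricParams = field(default_factory=PhotometricParams)
    D: float | None = None
    L: float | None = None
    focus_distance: float = 1000.0
    aperture_diameter: float = 50.0
    rng_seed: int = 0
    supersample: int = 2
    albedo_fn: "object" = None

    def __post_init__(self):
        if self.D is not None and self.D <= 0:
            raise ValueError("D must be positive")
        if self.L is not None and self.L <= 0:
            raise ValueError("L must be positive")
        if self.supersample < 1:
            raise ValueError("supersample must be >= 1")


@dataclass
class SceneGeometry:
    """Cached per-subpixel geometry shared by every frame of a capture."""

    shape: tuple          # native (H, W)
    supersample: int
    hit: np.ndarray       # (H*s, W*s) bool
    depth: np.ndarray     # camera-frame z, mm; inf where no hit (subpixel res)
    points: np.ndarray    # (n_hit, 3) world
    normals: np.ndarray   # (n_hit, 3), oriented toward the camera
    shade: np.ndarray     # (n_hit,) Lambert factor toward projector, lit only
    albedo: np.ndarray    # (n_hit,)
    pat_idx: np.ndarray   # (n_hit, 4) flat bilinear indices into the pattern
    pat_w: np.ndarray     # (n_hit, 4) bilinear weights (0 where unlit)
    depth_native: np.ndarray  # (H, W) mean hit depth, inf where empty


def _subpixel_grid(cam: PinholeDevice, s: int):
    H, W = cam.resolution_v, cam.resolution_u
    offs = (np.arange(s) + 0.5) / s - 0.5
    u = (np.arange(W)[:, None] + offs[None, :]).reshape(-1)   # W*s
    v = (np.arange(H)[:, None] + offs[None, :]).reshape(-1)   # H*s
    U, V = np.meshgrid(u, v)
    return U, V


def compute_geometry(scene: SceneConfig) -> SceneGeometry:
    """Ray casting, shadowing, shading and projector lookup for one scene.

    All quantities that do not depend on the projected pattern are computed
    once here; rendering a frame is then a cheap weighted gather.
    """
    mesh = scene.mesh
    if mesh is None or len(mesh.faces) == 0:
        raise ValueError("scene mesh is empty")
    cam, proj = scene.camera, scene.projector
    s = scene.supersample
    H, W = cam.resolution_v, cam.resolution_u
    caster = RayCaster(mesh.vertices, mesh.faces)

    U, V = _subpixel_grid(cam, s)
    dirs = cam.pixel_rays(U.ravel(), V.ravel())
    t, fi = caster.intersect(cam.center, dirs)
    hit = np.isfinite(t)
    forward = cam.rotation[2]
    depth = np.where(hit, t * (dirs @ forward), np.inf).reshape(H * s, W * s)

    pts = cam.center + t[hit, None] * dirs[hit]
    normals = caster.face_normals[fi[hit]]
    # orient toward the camera (board planes are two-sided)
    to_cam = dirs[hit]
    flip = np.einsum("ij,ij->i", normals, to_cam) > 0
    normals = np.where(flip[:, None], -normals, normals)

    # projector visibility: in frustum, facing, unshadowed
    uvp, depth_p = proj.project_points(pts)
    Wp, Hp = proj.resolution_u, proj.resolution_v
    in_frustum = (
        (depth_p > 0)
        & (uvp[:, 0] > -0.5) & (uvp[:, 0] < Wp - 0.5)
        & (uvp[:, 1] > -0.5) & (uvp[:, 1] < Hp - 0.5)
    )
    l = proj.center - pts
    l /= np.linalg.norm(l, axis=1, keepdims=True)
    cos_in = np.einsum("ij,ij->i", normals, l)
    facing = cos_in > 0
    cand = in_frustum & facing
    shadowed = np.zeros(len(pts), dtype=bool)
    if cand.any():
        shadowed[cand] = caster.occluded(pts[cand], proj.center, t_min=0.5)
    lit = cand & ~shadowed
    shade = np.where(lit, np.maximum(cos_in, 0.0), 0.0)

    albedo = (
        np.asarray(scene.albedo_fn(pts), dtype=float)
        if scene.albedo_fn is not None
        else np.full(len(pts), scene.photometrics.albedo)
    )

    # bilinear sample footprint in the pattern raster (pixel centers at ints)
    up = np.clip(uvp[:, 0], 0.0, Wp - 1.0)
    vp = np.clip(uvp[:, 1], 0.0, Hp - 1.0)
    u0 = np.clip(np.floor(up).astype(np.int64), 0, Wp - 2)
    v0 = np.clip(np.floor(vp).astype(np.int64), 0, Hp - 2)
    fu = up - u0
    fv = vp - v0
    pat_idx = np.stack(
        [v0 * Wp + u0, v0 * Wp + u0 + 1, (v0 + 1) * Wp + u0, (v0 + 1) * Wp + u0 + 1],
        axis=1,
    )
    pat_w = np.stack(
        [(1 - fu) * (1 - fv), fu * (1 - fv), (1 - fu) * fv, fu * fv], axis=1
    )
    pat_w[~lit] = 0.0

    hit_grid = hit.reshape(H * s, W * s)
    d = depth.reshape(H, s, W, s)
    with np.errstate(invalid="ignore"):
        finite = np.isfinite(d)
        cnt = finite.sum(axis=(1, 3))
        dsum = np.where(finite, d, 0.0).sum(axis=(1, 3))
        depth_native = np.where(cnt > 0, dsum / np.maximum(cnt, 1), np.inf)

    return SceneGeometry(
        shape=(H, W), supersample=s, hit=hit_grid, depth=depth,
        points=pts, normals=normals, shade=shade, albedo=albedo,
        pat_idx=pat_idx, pat_w=pat_w, depth_native=depth_native,
    )


def _coc_sigma_px(scene: SceneConfig, depth_native: np.ndarray) -> np.ndarray:
    """Thin-lens circle-of-confusion radius (as Gaussian sigma) in pixels."""
    if scene.aperture_diameter <= 0:
        return np.zeros(depth_native.shape)
    f = scene.camera.focal_length
    zf = scene.focus_distance
    z = depth_native
    with np.errstate(invalid="ignore", divide="ignore"):
        c_mm = scene.aperture_diameter * f * np.abs(z - zf) / (z * (zf - f))
    c_px = np.where(np.isfinite(z), c_mm / scene.camera.pixel_pitch_u, 0.0)
    return 0.5 * c_px


_BLUR_LEVELS = np.array([0.0, 0.5, 1.0, 2.0, 4.0, 8.0])


def _defocus_blur(img: np.ndarray, sigma_px: np.ndarray) -> np.ndarray:
    """Per-pixel Gaussian blur approximated by blending fixed blur levels."""
    smax = float(sigma_px.max(initial=0.0))
    if smax < 0.05:
        return img
    sig = np.clip(sigma_px, 0.0, _BLUR_LEVELS[-1])
    hi_idx = int(np.searchsorted(_BLUR_LEVELS, min(smax, _BLUR_LEVELS[-1])))
    levels = _BLUR_LEVELS[: hi_idx + 1]
    stack = [img] + [gaussian_filter(img, lv) for lv in levels[1:]]
    out = np.empty_like(img)
    idx = np.clip(np.searchsorted(levels, sig, side="right"), 1, len(levels) - 1)
    lo = levels[idx - 1]
    hi = levels[idx]
    w = np.clip((sig - lo) / (hi - lo), 0.0, 1.0)
    blur_lo = np.choose(idx - 1, stack, mode="clip")
    blur_hi = np.choose(idx, stack, mode="clip")
    out = (1 - w) * blur_lo + w * blur_hi
    return out


def _sensor_stage(img: np.ndarray, scene: SceneConfig, sigma_px, rng) -> np.ndarray:
    """Defocus -> saturation + bloom -> noise -> 8-bit quantization."""
    p = scene.photometrics
    img = _defocus_blur(img, sigma_px)
    sat = p.saturation_level
    excess = np.maximum(img - sat, 0.0)
    img = np.minimum(img, sat)
    if excess.any() and p.bloom_strength > 0 and p.bloom_radius > 0:
        img = img + p.bloom_strength * gaussian_filter(excess, p.bloom_radius)
    if p.noise_sigma > 0 and rng is not None:
        img = img + rng.normal(0.0, p.noise_sigma, size=img.shape)
    return np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)


def _raw_image(scene: SceneConfig, geom: SceneGeometry, pattern: np.ndarray) -> np.ndarray:
    """Pre-sensor intensity at native resolution (supersamples averaged)."""
    p = scene.photometrics
    H, W = geom.shape
    s = geom.supersample
    flat = np.zeros(H * s * W * s)
    patt_flat = np.asarray(pattern, dtype=float).ravel()
    patt_at_hit = np.einsum("ij,ij->i", patt_flat[geom.pat_idx], geom.pat_w)
    flat[geom.hit.ravel()] = p.gain * (
        p.ambient + geom.albedo * patt_at_hit * geom.shade
    )
    img = flat.reshape(H, s, W, s).mean(axis=(1, 3))
    return img


def render_frame(scene: SceneConfig, pattern, geometry: SceneGeometry | None = None,
                 rng=None):
    """Render one pattern: returns (uint8 image, native depth map)."""
    geom = geometry if geometry is not None else compute_geometry(scene)
    if rng is None:
        rng = np.random.default_rng([int(scene.rng_seed) & 0x7FFFFFFF, 0])
    sigma = _coc_sigma_px(scene, geom.depth_native)
    img = _sensor_stage(_raw_image(scene, geom, pattern), scene, sigma, rng)
    return img, geom.depth_native


def render_white_patch(scene: SceneConfig, row0: int, row1: int, col0: int,
                       col1: int, supersample: int = 32) -> np.ndarray:
    """Render a small pixel window under full projector illumination.

    Used for sub-pixel feature refinement (calibration dots): a small patch
    can afford a much higher supersampling rate than a full frame, which
    removes the coverage staircase that otherwise pixel-locks sub-pixel
    estimates.  No defocus/bloom stages (calibration imagery is in focus and
    unsaturated); output is quantized to 8 bits like any capture.
    """
    cam = scene.camera
    p = scene.photometrics
    mesh = scene.mesh
    caster = RayCaster(mesh.vertices, mesh.faces)
    s = supersample
    offs = (np.arange(s) + 0.5) / s - 0.5
    us = (np.arange(col0, col1)[:, None] + offs[None, :]).reshape(-1)
    vs = (np.arange(row0, row1)[:, None] + offs[None, :]).reshape(-1)
    U, V = np.meshgrid(us, vs)
    dirs = cam.pixel_rays(U.ravel(), V.ravel())
    t, fi = caster.intersect(cam.center, dirs)
    hit = np.isfinite(t)
    flat = np.zeros(U.size)
    if hit.any():
        pts = cam.center + t[hit, None] * dirs[hit]
        normals = caster.face_normals[fi[hit]]
        flip = np.einsum("ij,ij->i", normals, dirs[hit]) > 0
        normals = np.where(flip[:, None], -normals, normals)
        proj = scene.projector
        l = proj.center - pts
        l /= np.linalg.norm(l, axis=1, keepdims=True)
        shade = np.maximum(np.einsum("ij,ij->i", normals, l), 0.0)
        occ = caster.occluded(pts, proj.center, t_min=0.5)
        shade[occ] = 0.0
        albedo = (np.asarray(scene.albedo_fn(pts), dtype=float)
                  if scene.albedo_fn is not None else p.albedo)
        flat[hit] = p.gain * (p.ambient + albedo * shade)
    img = flat.reshape(row1 - row0, s, col1 - col0, s).mean(axis=(1, 3))
    return np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)


@dataclass
class CapturedStack:
    """A rendered capture: 8-bit frames + shared depth map + provenance."""

    frames: np.ndarray          # (n, H, W) uint8
    kinds: list
    depth_map: np.ndarray       # (H, W) mm, inf where no surface
    config: dict = field(default_factory=dict)

    def select(self, kind: str) -> np.ndarray:
        idx = [i for i, k in enumerate(self.kinds) if k == kind]
        return self.frames[idx]

    @classmethod
    def load(cls, directory) -> "CapturedStack":
        """Read a capture directory written by :meth:`save` (or an external
        stack following the same layout: PNG frames + capture.json)."""
        import imageio.v3 as iio
        import json

        directory = Path(directory)
        meta = json.loads((directory / "capture.json").read_text())
        frames = np.stack([iio.imread(directory / name) for name in meta["frames"]])
        depth = np.full(frames.shape[1:], np.inf)
        return cls(frames=frames, kinds=list(meta["kinds"]), depth_map=depth,
                   config=meta.get("config", {}))

    def save(self, directory, write_depth: bool = False) -> None:
        import imageio.v3 as iio
        import json

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        names = []
        for i, frame in enumerate(self.frames):
            name = f"frame_{i:03d}.png"
            iio.imwrite(directory / name, frame)
            names.append(name)
        (directory / "capture.json").write_text(
            json.dumps({"frames": names, "kinds": self.kinds, "config": self.config},
                       indent=2)
        )
        if write_depth:
            import tifffile

            depth = self.depth_map.astype(np.float32)
            tifffile.imwrite(directory / "depth.tiff", depth)


def render_stack(scene: SceneConfig, patterns) -> CapturedStack:
    """Render every frame of a pattern stack with shared geometry.

    Per-frame noise streams derive deterministically from ``scene.rng_seed``,
    so equal configurations produce bitwise-identical stacks.
    """
    geom = compute_geometry(scene)
    sigma = _coc_sigma_px(scene, geom.depth_native)
    frames = []
    for i, pattern in enumerate(patterns.frames):
        rng = np.random.default_rng([int(scene.rng_seed) & 0x7FFFFFFF, i])
        img = _sensor_stage(_raw_image(scene, geom, pattern), scene, sigma, rng)
        frames.append(img)
    snapshot = {
        "supersample": scene.supersample,
        "focus_distance": scene.focus_distance,
        "aperture_diameter": scene.aperture_diameter,
        "rng_seed": int(scene.rng_seed),
        "gain": scene.photometrics.gain,
        "n_frames": len(frames),
    }
    return CapturedStack(
        frames=np.stack(frames),
        kinds=list(patterns.kinds),
        depth_map=geom.depth_native,
        config=snapshot,
    )
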