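"""Camera / projector calibration from a rendered circle-grid board.

The board is a bright plane carrying a grid of dark dots: small 2.5 mm dots
everywhere plus four 5 mm fiducial dots arranged in an asymmetric "L" that
resolves the grid's orientation from any viewpoint.  Calibration renders the
board at ~20 poses, detects sub-pixel dot centers (intensity-weighted
centroids of the coverage deficit), and estimates a full 3x4 projection
matrix by normalized DLT with nonlinear reprojection refinement.

The projector cannot observe the board; its correspondences come from the
standard inverse-camera scheme: each pose is also scanned with vertical and
horizontal fringe sequences, and the absolute phase at a detected dot center
yields the projector column / row that illuminated it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.ndimage import binary_fill_holes
from scipy.optimize import least_squares
from scipy.spatial import cKDTree
from skimage.measure import label, regionprops

__all__ = [
    "CalibBoard",
    "ProjectionMatrix",
    "CorrespondenceSet",
    "DetectionError",
    "DegenerateGeometryError",
    "board_mesh_and_albedo",
    "make_board_poses",
    "detect_circle_centers",
    "estimate_projection_matrix",
    "projector_pixel_from_phase",
    "reprojection_error",
    "sample_map_subpixel",
]


class DetectionError(RuntimeError):
    """Dot detection failed (missing dots or ambiguous orientation)."""


class DegenerateGeometryError(RuntimeError):
    """Correspondences insufficient for a full 3x4 estimate."""


@dataclass
class CalibBoard:
    """Circle-grid calibration board specification.

    ``large_grid_positions`` are (row, col) grid nodes carrying the 5 mm
    fiducial dots; the default "L" constellation has no 180-degree symmetry.
    """

    rows: int = 9
    cols: int = 11
    spacing: float = 16.0           # mm between neighboring dot centers
    small_dot_diameter: float = 2.5
    large_dot_diameter: float = 5.0
    large_grid_positions: tuple = ((4, 4), (4, 5), (4, 6), (5, 4))
    background_albedo: float = 0.95
    dot_albedo: float = 0.12
    margin: float = 16.0            # board border beyond the outer dots, mm

    def __post_init__(self):
        large = set(self.large_grid_positions)
        rot = {(self.rows - 1 - r, self.cols - 1 - c) for r, c in large}
        if rot == large:
            raise ValueError("fiducial constellation must not be 180-degree symmetric")

    def grid_indices(self):
        return [(r, c) for r in range(self.rows) for c in range(self.cols)]

    def centers_local(self) -> np.ndarray:
        """Dot centers in the board frame (mm, z = 0), row-major order."""
        out = []
        for r, c in self.grid_indices():
            out.append([
                (c - (self.cols - 1) / 2) * self.spacing,
                (r - (self.rows - 1) / 2) * self.spacing,
            ])
        return np.asarray(out)

    def is_large(self) -> np.ndarray:
        large = set(self.large_grid_positions)
        return np.array([(r, c) in large for r, c in self.grid_indices()])

    @property
    def extent(self):
        w = (self.cols - 1) * self.spacing + 2 * self.margin
        h = (self.rows - 1) * self.spacing + 2 * self.margin
        return w, h


def board_mesh_and_albedo(board: CalibBoard, pose: np.ndarray):
    """Board plane mesh under a 4x4 local->world pose, plus its albedo map.

    Returns ``(mesh, albedo_fn, world_centers)`` where ``albedo_fn`` maps
    world points to albedo (dark inside dots) and ``world_centers`` are the
    dot centers in world coordinates, row-major grid order.
    """
    w, h = board.extent
    verts_local = np.array([
        [-w / 2, -h / 2, 0], [w / 2, -h / 2, 0], [w / 2, h / 2, 0], [-w / 2, h / 2, 0],
    ])
    faces = np.array([[0, 1, 2], [0, 2, 3]])
    pose = np.asarray(pose, dtype=float)
    R, t = pose[:3, :3], pose[:3, 3]
    verts = verts_local @ R.T + t
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)

    centers = board.centers_local()
    radii = np.where(
        board.is_large(), board.large_dot_diameter / 2, board.small_dot_diameter / 2
    )
    tree = cKDTree(centers)
    rmax = radii.max()

    def albedo_fn(points_world):
        local = (np.asarray(points_world) - t) @ R
        xy = local[:, :2]
        dist, idx = tree.query(xy, distance_upper_bound=rmax + 1.0)
        inside = np.isfinite(dist) & (dist < radii[np.minimum(idx, len(radii) - 1)])
        return np.where(inside, board.dot_albedo, board.background_albedo)

    world_centers = np.column_stack([centers, np.zeros(len(centers))]) @ R.T + t
    return mesh, albedo_fn, world_centers


def make_board_poses(n_poses: int = 20, seed: int = 0,
                     z_range=(-80.0, 220.0), tilt_deg: float = 22.0,
                     lateral: float = 50.0) -> list:
    """Deterministic spread of board poses (4x4 local->world transforms).

    Poses vary stand-off (``z_range`` relative to the world origin, i.e.
    camera distances spanning roughly L - z_hi .. L - z_lo), tilt about both
    in-plane axes, in-plane rotation, and lateral offset -- the varied
    distances/angles a practitioner uses for a well-conditioned calibration.
    """
    rng = np.random.default_rng(seed)
    poses = []
    for _ in range(n_poses):
        rx = np.deg2rad(rng.uniform(-tilt_deg, tilt_deg))
        ry = np.deg2rad(rng.uniform(-tilt_deg, tilt_deg))
        rz = np.deg2rad(rng.uniform(-30.0, 30.0))
        cx, sx = np.cos(rx), np.sin(rx)
        cy, sy = np.cos(ry), np.sin(ry)
        cz, sz = np.cos(rz), np.sin(rz)
        Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        T = np.eye(4)
        T[:3, :3] = Rx @ Ry @ Rz
        T[:3, 3] = [
            rng.uniform(-lateral, lateral),
            rng.uniform(-lateral, lateral),
            rng.uniform(*z_range),
        ]
        poses.append(T)
    return poses


# ---------------------------------------------------------------------------
# dot detection
# ---------------------------------------------------------------------------

def _weighted_centroid(img, region_mask, bbox, pad, quant_margin=2.0 / 255.0):
    """Centroid of the local intensity deficit around one dot."""
    r0, c0, r1, c1 = bbox
    r0 = max(r0 - pad, 0)
    c0 = max(c0 - pad, 0)
    r1 = min(r1 + pad, img.shape[0])
    c1 = min(c1 + pad, img.shape[1])
    patch = img[r0:r1, c0:c1]
    in_region = region_mask[r0:r1, c0:c1]
    bg_pixels = patch[~in_region]
    if bg_pixels.size == 0:
        return None
    bg = np.median(bg_pixels)
    w = np.clip(bg - patch - quant_margin, 0.0, None)
    mass = w.sum()
    if mass <= 0:
        return None
    vv, uu = np.mgrid[r0:r1, c0:c1]
    return np.array([(w * uu).sum() / mass, (w * vv).sum() / mass]), mass


def _fit_dot_center(img, origin, u0: float, v0: float, J_inv, r_mm: float,
                    amp0: float, bg0: float, tau: float = 0.08, sub: int = 8):
    """Refine one dot center by fitting a rendered-dot model to the patch.

    Model: ``I(px) = bg - amp * C(px)`` where ``C`` is the pixel's coverage
    by the dot, evaluated by mapping subpixel sample points back to the
    board plane through the local inverse Jacobian ``J_inv`` (px -> mm) and
    testing them against the dot's known physical radius ``r_mm`` with a
    sigmoid edge of width ``tau`` mm (keeps the model smooth for the
    finite-difference Jacobian).  Fixing the dot's shape from the board
    homography removes the radius/amplitude degeneracy that makes free-form
    fits (and plain centroids) alias for dots spanning about a pixel.

    ``img`` may be the full frame or a re-rendered patch; in the latter case
    ``origin=(row0, col0)`` places it in frame coordinates.
    """
    patch = np.asarray(img, dtype=float)
    if patch.max() > 1.5:
        patch = patch / 255.0
    row0, col0 = origin
    vv, uu = np.mgrid[row0:row0 + patch.shape[0], col0:col0 + patch.shape[1]]
    offs = (np.arange(sub) + 0.5) / sub - 0.5
    du, dv = np.meshgrid(offs, offs)
    sx = (uu[..., None] + du.ravel()).ravel()
    sy = (vv[..., None] + dv.ravel()).ravel()
    Jinv = np.asarray(J_inv, dtype=float)

    def model(p):
        cx, cy, amp, bg = p
        dx = sx - cx
        dy = sy - cy
        ex = Jinv[0, 0] * dx + Jinv[0, 1] * dy
        ey = Jinv[1, 0] * dx + Jinv[1, 1] * dy
        d = np.hypot(ex, ey)  # mm in the board plane
        cov = 1.0 / (1.0 + np.exp(np.clip((d - r_mm) / tau, -40, 40)))
        cov = cov.reshape(patch.shape + (sub * sub,)).mean(axis=-1)
        return bg - amp * cov

    def residuals(p):
        return (model(p) - patch).ravel()

    p0 = np.array([u0, v0, amp0, bg0])
    try:
        sol = least_squares(residuals, p0, method="lm", xtol=1e-14, ftol=1e-14,
                            max_nfev=200)
    except Exception:
        return None
    cx, cy, amp, _ = sol.x
    if amp <= 0 or abs(cx - u0) > 2 or abs(cy - v0) > 2:
        return None
    return float(cx), float(cy)


def _collinear_triple(pts: np.ndarray):
    """Index triple of the most collinear 3 of 4 points, plus the leftover."""
    best = None
    from itertools import combinations

    for combo in combinations(range(4), 3):
        p = pts[list(combo)]
        centered = p - p.mean(axis=0)
        sv = np.linalg.svd(centered, compute_uv=False)
        resid = sv[-1]
        if best is None or resid < best[0]:
            rest = ({0, 1, 2, 3} - set(combo)).pop()
            best = (resid, combo, rest)
    return best[1], best[2]


def _fit_homography(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """2-D homography src->dst by normalized DLT."""

    def normalizer(x):
        c = x.mean(axis=0)
        s = np.sqrt(2) / np.mean(np.linalg.norm(x - c, axis=1))
        T = np.array([[s, 0, -s * c[0]], [0, s, -s * c[1]], [0, 0, 1]])
        return T

    Ts, Td = normalizer(src), normalizer(dst)
    sh = np.column_stack([src, np.ones(len(src))]) @ Ts.T
    dh = np.column_stack([dst, np.ones(len(dst))]) @ Td.T
    A = []
    for (x, y, _), (u, v, _) in zip(sh, dh):
        A.append([x, y, 1, 0, 0, 0, -u * x, -u * y, -u])
        A.append([0, 0, 0, x, y, 1, -v * x, -v * y, -v])
    _, _, Vt = np.linalg.svd(np.asarray(A))
    H = Vt[-1].reshape(3, 3)
    H = np.linalg.inv(Td) @ H @ Ts
    return H / H[2, 2]


def _apply_homography(H, pts):
    ph = np.column_stack([pts, np.ones(len(pts))]) @ H.T
    return ph[:, :2] / ph[:, 2:3]


def detect_circle_centers(image, board: CalibBoard, refine_patch=None):
    """Detect and grid-order the board's dot centers in one image.

    Returns sub-pixel centers (rows*cols, 2) in row-major grid order.
    Raises :class:`DetectionError` when dots are missing or the fiducial
    constellation cannot be resolved.

    ``refine_patch``, when given, is a callable ``(row0, row1, col0, col1)
    -> patch`` returning a re-rendered (or re-captured) window used for the
    final per-dot model fit -- e.g. a higher-supersampling render that
    eliminates the coverage staircase of the full frame.
    """
    from scipy.ndimage import binary_erosion, uniform_filter

    img = np.asarray(image, dtype=float)
    if img.dtype == np.uint8 or img.max() > 1.5:
        img = img / 255.0
    bright = img[img > 0.5 * img.max()]
    if bright.size == 0:
        raise DetectionError("image contains no board surface")
    board_level = np.median(bright)
    # board region, eroded so the antialiased outline cannot masquerade as dots
    region = binary_fill_holes(img > 0.6 * board_level)
    core = binary_erosion(region, iterations=3)
    # local background level (dots dilute it by only a few percent)
    num = uniform_filter(np.where(region, img, 0.0), size=21)
    den = uniform_filter(region.astype(float), size=21)
    with np.errstate(invalid="ignore", divide="ignore"):
        local_bg = np.where(den > 0.3, num / np.maximum(den, 1e-9), board_level)
    holes = core & (img < 0.85 * local_bg)
    lab = label(holes)
    regions = [r for r in regionprops(lab) if r.area >= 1]
    centers, masses = [], []
    for r in regions:
        got = _weighted_centroid(img, lab == r.label, r.bbox, pad=3)
        if got is None:
            continue
        centers.append(got[0])
        masses.append(got[1])
    centers = np.asarray(centers)
    masses = np.asarray(masses)
    n_expected = board.rows * board.cols
    if len(centers) < n_expected:
        raise DetectionError(
            f"found {len(centers)} dots, expected {n_expected}"
        )

    # fiducials: the four heaviest deficits (5 mm dots have ~4x the mass)
    order = np.argsort(masses)[::-1]
    large_idx = order[:4]
    med_small = np.median(masses[order[4:]])
    if masses[large_idx].min() < 2.0 * med_small:
        raise DetectionError("could not separate fiducial dots by size")
    large_pts = centers[large_idx]
    (i_tri), i_rest = _collinear_triple(large_pts)
    tri = large_pts[list(i_tri)]
    d_pt = large_pts[i_rest]
    # middle of the collinear triple
    dists = [np.linalg.norm(tri[(k + 1) % 3] - tri[(k + 2) % 3]) for k in range(3)]
    mid = int(np.argmax(dists))
    ends = [k for k in range(3) if k != mid]
    a_end = min(ends, key=lambda k: np.linalg.norm(tri[k] - d_pt))
    c_end = ({0, 1, 2} - {mid, a_end}).pop()
    A_img, B_img, D_img = tri[a_end], tri[mid], d_pt

    # grid positions of the fiducials: three collinear dots along one row
    # (cols c0, c0+1, c0+2) with the arm dot one row below the first
    large = list(board.large_grid_positions)
    rows_of: dict = {}
    for r, c in large:
        rows_of.setdefault(r, []).append(c)
    line_row = max(rows_of, key=lambda r: len(rows_of[r]))
    line_cols = sorted(rows_of[line_row])
    arm = [(r, c) for r, c in large if r != line_row][0]
    if len(line_cols) != 3 or arm[1] not in (line_cols[0], line_cols[-1]):
        raise ValueError("unsupported fiducial constellation")
    A_grid = (line_row, arm[1])
    B_grid = (line_row, line_cols[1])
    D_grid = arm

    col_step = (B_img - A_img) / (B_grid[1] - A_grid[1])
    row_step = (D_img - A_img) / (D_grid[0] - A_grid[0])

    # predicted positions -> nearest-detection assignment -> homography refine
    local = board.centers_local()
    gi = np.array(board.grid_indices(), dtype=float)
    pred = (
        A_img[None, :]
        + (gi[:, 1] - A_grid[1])[:, None] * col_step[None, :]
        + (gi[:, 0] - A_grid[0])[:, None] * row_step[None, :]
    )
    # grow the grid assignment from confident matches: the affine prediction
    # from the fiducials is only locally accurate under perspective, so fit a
    # homography to whatever matches confidently and re-predict
    tree = cKDTree(centers)
    tol = 0.4 * min(np.linalg.norm(col_step), np.linalg.norm(row_step))
    idx = None
    H = None
    for _ in range(6):
        dist, idx = tree.query(pred)
        good = dist < max(tol, 2.0)
        if good.sum() < 6:
            raise DetectionError("too few confident grid matches")
        H = _fit_homography(local[good], centers[idx[good]])
        pred = _apply_homography(H, local)
    dist, idx = tree.query(pred)
    if len(np.unique(idx)) != n_expected:
        raise DetectionError("ambiguous grid assignment of detected dots")
    if dist.max() > max(tol, 2.0):
        raise DetectionError(
            f"grid assignment residual too large ({dist.max():.2f} px)"
        )
    assigned = centers[idx]
    H = _fit_homography(local, assigned)

    # model-fit refinement of every assigned center; the homography Jacobian
    # fixes each dot's pixel-space shape from its known physical radius
    refined = assigned.copy()
    is_large = board.is_large()
    for i, (u0, v0) in enumerate(assigned):
        x, y = local[i]
        w = H[2, 0] * x + H[2, 1] * y + H[2, 2]
        un = H[0, 0] * x + H[0, 1] * y + H[0, 2]
        vn = H[1, 0] * x + H[1, 1] * y + H[1, 2]
        J = np.array([
            [(H[0, 0] * w - un * H[2, 0]) / w ** 2, (H[0, 1] * w - un * H[2, 1]) / w ** 2],
            [(H[1, 0] * w - vn * H[2, 0]) / w ** 2, (H[1, 1] * w - vn * H[2, 1]) / w ** 2],
        ])
        try:
            J_inv = np.linalg.inv(J)
        except np.linalg.LinAlgError:
            continue
        r_mm = (board.large_dot_diameter if is_large[i] else board.small_dot_diameter) / 2
        ru0 = np.linalg.norm(J[0]) * r_mm
        rv0 = np.linalg.norm(J[1]) * r_mm
        ui, vi = int(round(u0)), int(round(v0))
        lo_r, hi_r = max(vi - 2, 0), min(vi + 3, img.shape[0])
        lo_c, hi_c = max(ui - 2, 0), min(ui + 3, img.shape[1])
        amp0 = max(board_level - img[lo_r:hi_r, lo_c:hi_c].min(), 0.05)
        half = int(np.ceil(max(ru0, rv0))) + 3
        r0p = max(vi - half, 0)
        r1p = min(vi + half + 1, img.shape[0])
        c0p = max(ui - half, 0)
        c1p = min(ui + half + 1, img.shape[1])
        patch = (refine_patch(r0p, r1p, c0p, c1p) if refine_patch is not None
                 else img[r0p:r1p, c0p:c1p])
        got = _fit_dot_center(patch, (r0p, c0p), u0, v0, J_inv, r_mm,
                              amp0, board_level)
        if got is not None:
            refined[i] = got
    return refined


# ---------------------------------------------------------------------------
# projection-matrix estimation
# ---------------------------------------------------------------------------

@dataclass
class CorrespondenceSet:
    """3-D world points paired with observed pixels for one device."""

    world_points: np.ndarray
    pixels: np.ndarray
    view_index: np.ndarray | None = None

    def __post_init__(self):
        self.world_points = np.asarray(self.world_points, dtype=float)
        self.pixels = np.asarray(self.pixels, dtype=float)
        if len(self.world_points) != len(self.pixels):
            raise ValueError("world/pixel count mismatch")
        if self.view_index is not None:
            self.view_index = np.asarray(self.view_index)


@dataclass
class ProjectionMatrix:
    """Estimated 3x4 world->pixel mapping plus calibration diagnostics."""

    matrix: np.ndarray
    role: str = "camera"
    rms_reprojection: float = np.nan
    mean_reprojection: float = np.nan
    max_reprojection: float = np.nan
    n_points: int = 0
    per_view: list = field(default_factory=list)

    def project(self, points):
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        ph = np.column_stack([pts, np.ones(len(pts))]) @ self.matrix.T
        return ph[:, :2] / ph[:, 2:3]


def _check_nondegenerate(world: np.ndarray):
    if len(world) < 6:
        raise DegenerateGeometryError(
            f"need >= 6 correspondences for a 3x4 estimate, got {len(world)}"
        )
    centered = world - world.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[2] < 1e-6 * max(sv[0], 1.0):
        raise DegenerateGeometryError(
            "world points are coplanar; a single board pose cannot constrain "
            "a full 3x4 projection matrix -- use multiple tilted poses"
        )


def estimate_projection_matrix(correspondences: CorrespondenceSet,
                               role: str = "camera",
                               refine: bool = True) -> ProjectionMatrix:
    """Normalized DLT + nonlinear reprojection refinement.

    The matrix is normalized to ``a34 = 1``.  Raises
    :class:`DegenerateGeometryError` for coplanar-world or undersized inputs.
    """
    world = correspondences.world_points
    pix = correspondences.pixels
    _check_nondegenerate(world)

    cw = world.mean(axis=0)
    sw = np.sqrt(3) / np.mean(np.linalg.norm(world - cw, axis=1))
    Tw = np.eye(4)
    Tw[:3, :3] *= sw
    Tw[:3, 3] = -sw * cw
    cp = pix.mean(axis=0)
    sp = np.sqrt(2) / np.mean(np.linalg.norm(pix - cp, axis=1))
    Tp = np.array([[sp, 0, -sp * cp[0]], [0, sp, -sp * cp[1]], [0, 0, 1]])

    wh = np.column_stack([world, np.ones(len(world))]) @ Tw.T
    ph = np.column_stack([pix, np.ones(len(pix))]) @ Tp.T
    n = len(world)
    A = np.zeros((2 * n, 12))
    A[0::2, 0:4] = wh
    A[0::2, 8:12] = -ph[:, 0:1] * wh
    A[1::2, 4:8] = wh
    A[1::2, 8:12] = -ph[:, 1:2] * wh
    _, _, Vt = np.linalg.svd(A)
    P = Vt[-1].reshape(3, 4)
    P = np.linalg.inv(Tp) @ P @ Tw
    if abs(P[2, 3]) < 1e-12:
        raise DegenerateGeometryError("estimated a34 ~ 0; cannot normalize")
    P = P / P[2, 3]
    # a depth-positive convention: world centroid should project with s > 0
    if (P[2] @ np.append(cw, 1.0)) < 0:
        P = -P

    if refine:
        def residuals(p11):
            M = np.append(p11, 1.0).reshape(3, 4)
            ph = np.column_stack([world, np.ones(n)]) @ M.T
            proj = ph[:, :2] / ph[:, 2:3]
            return (proj - pix).ravel()

        sol = least_squares(residuals, P.ravel()[:11], method="lm", xtol=1e-15,
                            ftol=1e-15)
        P = np.append(sol.x, 1.0).reshape(3, 4)

    pm = ProjectionMatrix(matrix=P, role=role, n_points=n)
    stats = reprojection_error(pm, correspondences)
    pm.rms_reprojection = stats["rms"]
    pm.mean_reprojection = stats["mean"]
    pm.max_reprojection = stats["max"]
    pm.per_view = stats["per_view"]
    return pm


def projector_pixel_from_phase(Phi, pixels_per_period: float,
                               phase_offset: float = 0.0) -> np.ndarray:
    """Absolute phase -> projector coordinate along the fringe axis.

    ``up = (Phi - phase_offset) / (2 pi) * pixels_per_period``; with a single
    period spanning the full width this reduces to the textbook
    ``up = Phi / (2 pi) * W``.
    """
    return (np.asarray(Phi, dtype=float) - phase_offset) / (2 * np.pi) * pixels_per_period


def reprojection_error(matrix: ProjectionMatrix, correspondences: CorrespondenceSet):
    """Per-point reprojection residuals with mean/rms/max and per-view stats."""
    proj = matrix.project(correspondences.world_points)
    res = np.linalg.norm(proj - correspondences.pixels, axis=1)
    per_view = []
    if correspondences.view_index is not None:
        for v in np.unique(correspondences.view_index):
            sel = res[correspondences.view_index == v]
            per_view.append(
                {"view": int(v), "mean": float(sel.mean()),
                 "rms": float(np.sqrt((sel ** 2).mean())), "max": float(sel.max()),
                 "n": int(sel.size)}
            )
    return {
        "residuals": res,
        "mean": float(res.mean()),
        "rms": float(np.sqrt((res ** 2).mean())),
        "max": float(res.max()),
        "per_view": per_view,
    }


def sample_map_subpixel(map2d, weights, u: float, v: float, half: int = 4):
    """Weighted local-plane fit of a raster, evaluated at a sub-pixel point.

    Fits ``value ~ a + b du + c dv`` over a (2*half+1)^2 window with the given
    per-pixel weights (e.g. fringe modulation) and returns the value at
    ``(u, v)``, or None when the window holds too little weight.
    """
    H, W = map2d.shape
    ui, vi = int(round(u)), int(round(v))
    r0, r1 = max(vi - half, 0), min(vi + half + 1, H)
    c0, c1 = max(ui - half, 0), min(ui + half + 1, W)
    patch = map2d[r0:r1, c0:c1].ravel()
    w = np.asarray(weights[r0:r1, c0:c1], dtype=float).ravel()
    vv, uu = np.mgrid[r0:r1, c0:c1]
    du = uu.ravel() - u
    dv = vv.ravel() - v
    ok = w > 0
    if ok.sum() < 8:
        return None
    Amat = np.column_stack([np.ones(ok.sum()), du[ok], dv[ok]])
    Wd = w[ok]
    AtW = Amat.T * Wd
    try:
        coef = np.linalg.solve(AtW @ Amat, AtW @ patch[ok])
    except np.linalg.LinAlgError:
        return None
    return float(coef[0])
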