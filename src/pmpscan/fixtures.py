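"""Benchmark geometries and mesh / point-cloud I/O.

The scan targets used throughout the experiments: a frustum ("regular
trapezoid") whose flat faces and sharp edges expose edge artifacts, a smooth
torso-like body standing in for a patient surface, and a flat slab standing
in for a treatment bed.  All generators return watertight, consistently
wound ``trimesh.Trimesh`` objects in mm.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import trimesh

__all__ = [
    "make_frustum",
    "make_torso",
    "make_slab",
    "read_mesh",
    "write_mesh",
    "read_pointcloud",
    "write_pointcloud",
]

# Default frustum dimensions: tall enough for section cuts at z = 20 and
# 70 mm, with sub-100 mm height typical of phantom studies.
FRUSTUM_DEFAULTS = dict(base_w=120.0, base_d=120.0, top_w=60.0, top_d=60.0, height=80.0)


def make_frustum(base_w: float = 120.0, base_d: float = 120.0,
                 top_w: float = 60.0, top_d: float = 60.0,
                 height: float = 80.0) -> trimesh.Trimesh:
    """Right rectangular frustum, base on ``z = 0``, centered on the z axis.

    ``base == top`` degenerates to a box, which is allowed.
    """
    for name, val in [("base_w", base_w), ("base_d", base_d), ("top_w", top_w),
                      ("top_d", top_d), ("height", height)]:
        if val <= 0:
            raise ValueError(f"{name} must be positive, got {val}")
    if top_w > base_w or top_d > base_d:
        raise ValueError("top dimensions must not exceed base dimensions")
    bw, bd = base_w / 2, base_d / 2
    tw, td = top_w / 2, top_d / 2
    vertices = np.array([
        [-bw, -bd, 0], [bw, -bd, 0], [bw, bd, 0], [-bw, bd, 0],      # base
        [-tw, -td, height], [tw, -td, height], [tw, td, height], [-tw, td, height],
    ])
    faces = np.array([
        [0, 2, 1], [0, 3, 2],              # bottom (normal -z)
        [4, 5, 6], [4, 6, 7],              # top (+z)
        [0, 1, 5], [0, 5, 4],              # front (-y)
        [1, 2, 6], [1, 6, 5],              # right (+x)
        [2, 3, 7], [2, 7, 6],              # back (+y)
        [3, 0, 4], [3, 4, 7],              # left (-x)
    ])
    mesh = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    assert mesh.volume > 0
    return mesh


def make_torso(length: float = 500.0, width: float = 320.0, depth: float = 200.0,
               smoothness: float = 2.5, subdivisions: int = 3,
               back_flatten: float = 0.35) -> trimesh.Trimesh:
    """Smooth torso-like superellipsoid body lying along the y axis.

    A subdivided icosphere is remapped to a superellipsoid with exponent
    ``2/smoothness`` cross-sections (``smoothness > 2`` gives the flattened,
    chest-like curvature), then the ``z < 0`` half (the patient's back) is
    compressed by ``back_flatten`` so the body rests near the couch plane.
    Bilateral (x -> -x) mirror symmetry is preserved.
    """
    if min(length, width, depth) <= 0:
        raise ValueError("dimensions must be positive")
    sphere = trimesh.creation.icosphere(subdivisions=subdivisions)
    p = sphere.vertices.copy()
    e = 2.0 / smoothness

    def shape(c):
        return np.sign(c) * np.abs(c) ** e

    v = np.column_stack([shape(p[:, 0]), shape(p[:, 1]), shape(p[:, 2])])
    # renormalize onto the superellipsoid surface implied by |.|^smoothness
    norm = (np.abs(v) ** smoothness).sum(axis=1) ** (1.0 / smoothness)
    v /= norm[:, None]
    v[:, 0] *= width / 2
    v[:, 1] *= length / 2
    v[:, 2] *= depth / 2
    v[:, 2] = np.where(v[:, 2] < 0, v[:, 2] * back_flatten, v[:, 2])
    mesh = trimesh.Trimesh(vertices=v, faces=sphere.faces, process=False)
    assert mesh.volume > 0
    return mesh


def make_slab(width: float = 500.0, depth: float = 2000.0,
              thickness: float = 60.0) -> trimesh.Trimesh:
    """Treatment-bed stand-in: a flat box with its top face on ``z = 0``."""
    box = trimesh.creation.box(extents=[width, depth, thickness])
    box.apply_translation([0, 0, -thickness / 2])
    return box


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_MESH_EXT = {".obj", ".ply", ".stl"}


def read_mesh(path) -> trimesh.Trimesh:
    path = Path(path)
    if path.suffix.lower() not in _MESH_EXT:
        raise ValueError(f"unsupported mesh format: {path.suffix}")
    mesh = trimesh.load(path, force="mesh", process=False)
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise ValueError(f"no triangle geometry in {path}")
    return mesh


def write_mesh(mesh: trimesh.Trimesh, path) -> None:
    path = Path(path)
    if path.suffix.lower() not in _MESH_EXT:
        raise ValueError(f"unsupported mesh format: {path.suffix}")
    mesh.export(path)


def write_pointcloud(points, path) -> None:
    """Write points (N, 3 mm) as binary little-endian PLY or XYZ text."""
    path = Path(path)
    pts = np.asarray(points, dtype=np.float64)
    if hasattr(points, "points"):  # PointCloud dataclass
        pts = np.asarray(points.points, dtype=np.float64)
    if path.suffix.lower() == ".ply":
        # hand-rolled header: trimesh exports float32, which would truncate
        # sub-micrometre coordinates; doubles keep the round trip bit-exact
        header = (
            "ply\nformat binary_little_endian 1.0\n"
            f"element vertex {len(pts)}\n"
            "property double x\nproperty double y\nproperty double z\n"
            "end_header\n"
        )
        with open(path, "wb") as fh:
            fh.write(header.encode("ascii"))
            fh.write(np.ascontiguousarray(pts, dtype="<f8").tobytes())
    elif path.suffix.lower() == ".xyz":
        np.savetxt(path, pts, fmt="%.8f")
    else:
        raise ValueError(f"unsupported point-cloud format: {path.suffix}")


def read_pointcloud(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() == ".ply":
        cloud = trimesh.load(path)
        return np.asarray(cloud.vertices, dtype=np.float64)
    if path.suffix.lower() == ".xyz":
        return np.loadtxt(path, dtype=np.float64).reshape(-1, 3)
    raise ValueError(f"unsupported point-cloud format: {path.suffix}")
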