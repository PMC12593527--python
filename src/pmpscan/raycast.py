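"""Vectorized triangle-mesh ray casting (Moller-Trumbore).

Meshes in this package are small (tens to a few thousand faces) while ray
counts are large (one per camera subpixel), so the intersection kernel is a
chunked rays-by-faces broadcast in numpy rather than a BVH traversal.
"""

from __future__ import annotations

import numpy as np

__all__ = ["RayCaster"]

_EPS = 1e-9


class RayCaster:
    """Nearest-hit and occlusion queries against one triangle mesh."""

    def __init__(self, vertices, faces, chunk_pairs: int = 4_000_000):
        self.vertices = np.asarray(vertices, dtype=float)
        self.faces = np.asarray(faces, dtype=np.int64)
        if self.faces.size == 0:
            raise ValueError("mesh has no faces")
        self.v0 = self.vertices[self.faces[:, 0]]
        self.e1 = self.vertices[self.faces[:, 1]] - self.v0
        self.e2 = self.vertices[self.faces[:, 2]] - self.v0
        n = np.cross(self.e1, self.e2)
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        self.face_normals = n / norm
        self.chunk_pairs = int(chunk_pairs)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def _chunk_size(self) -> int:
        return max(1, self.chunk_pairs // self.n_faces)

    def intersect(self, origins, directions, t_min: float = 1e-6, t_max: float = np.inf):
        """Nearest intersection along each ray.

        ``origins`` may be a single point (broadcast) or one per ray.
        Returns ``(t, face_index)`` with ``t = inf`` and index ``-1`` for
        misses.
        """
        directions = np.asarray(directions, dtype=float)
        origins = np.asarray(origins, dtype=float)
        single_origin = origins.ndim == 1
        n_rays = len(directions)
        t_out = np.full(n_rays, np.inf)
        f_out = np.full(n_rays, -1, dtype=np.int64)
        # cheap AABB slab pre-test: most rays in a sparse scene miss entirely
        cand = self._aabb_hits(origins, directions, t_min, t_max)
        idx = np.nonzero(cand)[0]
        if idx.size == 0:
            return t_out, f_out
        step = self._chunk_size()
        for lo in range(0, idx.size, step):
            sel = idx[lo:lo + step]
            d = directions[sel]
            o = origins if single_origin else origins[sel]
            t, fi = self._intersect_chunk(o, d, t_min, t_max)
            t_out[sel] = t
            f_out[sel] = fi
        return t_out, f_out

    def _aabb_hits(self, origins, directions, t_min, t_max):
        lo = self.vertices.min(axis=0) - 1e-9
        hi = self.vertices.max(axis=0) + 1e-9
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = 1.0 / directions
            t0 = (lo[None, :] - origins.reshape(-1, 3)) * inv
            t1 = (hi[None, :] - origins.reshape(-1, 3)) * inv
        near = np.minimum(t0, t1)
        far = np.maximum(t0, t1)
        # axis-parallel rays: replace NaNs from 0 * inf
        near = np.where(np.isnan(near), -np.inf, near)
        far = np.where(np.isnan(far), np.inf, far)
        t_enter = near.max(axis=1)
        t_exit = far.min(axis=1)
        return (t_exit >= t_enter) & (t_exit > t_min) & (t_enter < t_max)

    def _intersect_chunk(self, origins, d, t_min, t_max):
        # rays (R,3) x faces (F,3) broadcast
        h = np.cross(d[:, None, :], self.e2[None, :, :])            # (R,F,3)
        a = np.einsum("fk,rfk->rf", self.e1, h)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv_a = 1.0 / a
        if origins.ndim == 1:
            s = origins[None, None, :] - self.v0[None, :, :]
        else:
            s = origins[:, None, :] - self.v0[None, :, :]
        u = np.einsum("rfk,rfk->rf", s, h) * inv_a
        q = np.cross(s, self.e1[None, :, :])
        v = np.einsum("rk,rfk->rf", d, q) * inv_a
        t = np.einsum("fk,rfk->rf", self.e2, q) * inv_a
        with np.errstate(invalid="ignore"):
            ok = (
                (np.abs(a) > _EPS)
                & (u >= -1e-9)
                & (v >= -1e-9)
                & (u + v <= 1 + 1e-9)
                & (t > t_min)
                & (t < t_max)
            )
        t = np.where(ok, t, np.inf)
        fi = np.argmin(t, axis=1)
        tbest = t[np.arange(len(d)), fi]
        fi = np.where(np.isfinite(tbest), fi, -1)
        return tbest, fi

    def occluded(self, origins, targets, t_min: float = 1e-4) -> np.ndarray:
        """True where the open segment origin->target is blocked by the mesh.

        ``t_min`` (and the matching end-shrink) avoids self-intersection with
        the surface the segment starts from.
        """
        origins = np.asarray(origins, dtype=float)
        targets = np.asarray(targets, dtype=float)
        seg = targets - origins
        dist = np.linalg.norm(seg, axis=-1)
        dist[dist == 0] = 1.0
        dirs = seg / dist[:, None]
        t, _ = self.intersect(origins, dirs, t_min=t_min, t_max=np.inf)
        return t < dist - 1e-4
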