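"""Triangle-mesh ray casting and closest-point queries.

The sealing analysis attributes each skirt element to the anatomy element
found along its outward normal, so the central primitive is a first-hit
ray/triangle-mesh intersection.  It is implemented as a vectorized
Moller-Trumbore test of one ray against every triangle of the mesh; at the
mesh sizes used here (~10^4 triangles) this brute-force form is fast, exact,
and trivially deterministic, and it doubles as the reference against which
accelerated libraries can be compared.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-12


class MeshRayCaster:
    """Precomputed Moller-Trumbore tester for repeated queries on one mesh."""

    def __init__(self, vertices: np.ndarray, faces: np.ndarray):
        self.vertices = np.asarray(vertices, dtype=float)
        self.faces = np.asarray(faces, dtype=int)
        self._v0 = self.vertices[self.faces[:, 0]]
        self._e1 = self.vertices[self.faces[:, 1]] - self._v0
        self._e2 = self.vertices[self.faces[:, 2]] - self._v0

    def first_hit(
        self,
        origin: np.ndarray,
        direction: np.ndarray,
        max_ray_length: float = np.inf,
    ) -> tuple[float, int]:
        """First intersection; ``(inf, -1)`` if nothing is hit in range."""
        direction = np.asarray(direction, dtype=float)
        norm = np.linalg.norm(direction)
        if not norm > _EPS:
            raise ValueError("degenerate ray direction")
        d = direction / norm

        v0, e1, e2 = self._v0, self._e1, self._e2
        pvec = np.cross(d[None, :], e2)
        det = np.einsum("ij,ij->i", e1, pvec)
        ok = np.abs(det) > _EPS
        inv_det = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)

        tvec = origin - v0
        u = np.einsum("ij,ij->i", tvec, pvec) * inv_det
        qvec = np.cross(tvec, e1)
        v = np.einsum("j,ij->i", d, qvec) * inv_det
        t = np.einsum("ij,ij->i", e2, qvec) * inv_det

        hit = ok & (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1.0 + 1e-9)
        hit &= (t >= -1e-9) & (t <= max_ray_length)
        if not hit.any():
            return np.inf, -1
        idx = np.flatnonzero(hit)
        best = idx[np.argmin(t[idx])]
        return float(max(t[best], 0.0)), int(best)


def ray_mesh_first_hit(
    origin: np.ndarray,
    direction: np.ndarray,
    vertices: np.ndarray,
    faces: np.ndarray,
    max_ray_length: float = np.inf,
) -> tuple[float, int]:
    """First intersection of a ray with a triangle mesh.

    One-shot form of :class:`MeshRayCaster`; the returned distance is in
    units of ``|direction|`` (pass a unit vector to obtain mm).  Returns
    ``(inf, -1)`` if no triangle is hit within ``max_ray_length``.
    """
    return MeshRayCaster(vertices, faces).first_hit(origin, direction, max_ray_length)


def _segment_distances(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    denom = np.maximum(np.einsum("ij,ij->i", ab, ab), 1e-300)
    t = np.clip(np.einsum("ij,ij->i", p - a, ab) / denom, 0.0, 1.0)
    return np.linalg.norm(a + t[:, None] * ab - p, axis=1)


def closest_point_on_mesh(
    point: np.ndarray, vertices: np.ndarray, faces: np.ndarray
) -> tuple[float, int]:
    """Distance from ``point`` to the nearest point on the mesh surface.

    Per triangle, the distance is the unsigned plane distance when the
    normal projection of the point falls inside the triangle, and the
    minimum distance to the three edge segments otherwise.  Returns
    ``(distance, face_index)``.
    """
    p = np.asarray(point, dtype=float)
    a = vertices[faces[:, 0]]
    b = vertices[faces[:, 1]]
    c = vertices[faces[:, 2]]

    n = np.cross(b - a, c - a)
    nn = np.linalg.norm(n, axis=1, keepdims=True)
    n = n / np.maximum(nn, 1e-300)
    d_plane = np.einsum("ij,ij->i", p - a, n)
    proj = p - d_plane[:, None] * n
    s1 = np.einsum("ij,ij->i", np.cross(b - a, proj - a), n)
    s2 = np.einsum("ij,ij->i", np.cross(c - b, proj - b), n)
    s3 = np.einsum("ij,ij->i", np.cross(a - c, proj - c), n)
    inside = (s1 >= -1e-12) & (s2 >= -1e-12) & (s3 >= -1e-12)

    pp = np.broadcast_to(p, a.shape)
    d_edges = np.minimum.reduce([
        _segment_distances(pp, a, b),
        _segment_distances(pp, b, c),
        _segment_distances(pp, c, a),
    ])
    dist = np.where(inside, np.abs(d_plane), d_edges)
    best = int(np.argmin(dist))
    return float(dist[best]), best


def radial_hits(
    thetas: np.ndarray,
    zs: np.ndarray,
    vertices: np.ndarray,
    faces: np.ndarray,
    max_ray_length: float = np.inf,
) -> tuple[np.ndarray, np.ndarray]:
    """Cast horizontal rays from the z-axis outward at (theta, z) pairs.

    Returns ``(radii, face_indices)``; radius is inf (index -1) for misses.
    Used to sample the luminal wall radius seen by each frame node.
    """
    thetas = np.asarray(thetas, dtype=float).ravel()
    zs = np.asarray(zs, dtype=float).ravel()
    radii = np.full(thetas.shape, np.inf)
    hits = np.full(thetas.shape, -1, dtype=int)
    caster = MeshRayCaster(vertices, faces)
    for i, (th, z) in enumerate(zip(thetas, zs)):
        origin = np.array([0.0, 0.0, z])
        direction = np.array([np.cos(th), np.sin(th), 0.0])
        radii[i], hits[i] = caster.first_hit(origin, direction, max_ray_length)
    return radii, hits
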