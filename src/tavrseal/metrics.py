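"""Cross-section measurements of deployed frames and predicted-vs-observed
comparison statistics.

Deployed frames are measured at four device levels (ventricular end, nadir,
central coaptation, commissures) by intersecting the node lattice with a
horizontal plane and quantifying the resulting polygon: maximum diameter
(max pairwise vertex distance), minimum diameter (minimum width of the
convex hull via rotating calipers), perimeter and area (shoelace).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.spatial import ConvexHull

#: default level heights as fractions of total frame height
DEFAULT_LEVEL_FRACTIONS = {
    "ventricular_end": 0.02,
    "nadir": 0.15,
    "central_coaptation": 0.45,
    "commissures": 0.70,
}

MEASUREMENT_NAMES = ("dmax", "dmin", "perimeter", "area")


@dataclass(frozen=True)
class CrossSectionMeasurement:
    level: str
    dmax: float
    dmin: float
    perimeter: float
    area: float

    def __post_init__(self) -> None:
        if self.dmin > self.dmax + 1e-9:
            raise ValueError("dmin exceeds dmax")


def _min_width_convex(hull_pts: np.ndarray) -> float:
    """Minimum width of a convex polygon (rotating calipers over edges)."""
    n = len(hull_pts)
    best = np.inf
    for i in range(n):
        e = hull_pts[(i + 1) % n] - hull_pts[i]
        norm = np.linalg.norm(e)
        if norm < 1e-12:
            continue
        u = e / norm
        normal = np.array([-u[1], u[0]])
        d = (hull_pts - hull_pts[i]) @ normal
        width = d.max() - d.min()
        best = min(best, width)
    return float(best)


def _is_simple(poly: np.ndarray) -> bool:
    from shapely.geometry import Polygon

    return Polygon(poly).is_valid


def polygon_measure(poly: np.ndarray, level: str = "") -> CrossSectionMeasurement:
    """Measure a simple planar polygon given as an (n, 2) vertex array."""
    poly = np.asarray(poly, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
        raise ValueError("polygon must be an (n>=3, 2) array")
    if not _is_simple(poly):
        raise ValueError("polygon is degenerate or self-intersecting")
    hull = ConvexHull(poly)
    hull_pts = poly[hull.vertices]
    diff = hull_pts[:, None, :] - hull_pts[None, :, :]
    dmax = float(np.sqrt((diff**2).sum(-1)).max())
    dmin = _min_width_convex(hull_pts)
    closed = np.vstack([poly, poly[:1]])
    perimeter = float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())
    x, y = poly[:, 0], poly[:, 1]
    area = float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)
    return CrossSectionMeasurement(level, dmax, dmin, perimeter, area)


def cross_section(frame, z: float) -> np.ndarray:
    """Ordered polygon of the frame lattice intersected with the plane at z.

    Node positions are interpolated linearly between the two bracketing node
    levels per sector and ordered by angle about the section centroid.
    """
    nodes = frame.nodes  # (L, S, 3)
    zl = nodes[:, 0, 2]
    if z < zl.min() - 1e-9 or z > zl.max() + 1e-9:
        raise ValueError(f"z={z} outside frame axial extent [{zl.min()}, {zl.max()}]")
    i = int(np.clip(np.searchsorted(zl, z) - 1, 0, len(zl) - 2))
    z0, z1 = zl[i], zl[i + 1]
    t = 0.0 if z1 == z0 else (z - z0) / (z1 - z0)
    pts = (1 - t) * nodes[i, :, :2] + t * nodes[i + 1, :, :2]
    c = pts.mean(axis=0)
    ang = np.arctan2(pts[:, 1] - c[1], pts[:, 0] - c[0])
    return pts[np.argsort(ang)]


def measure(frame, level_fractions: dict[str, float] | None = None):
    """Measure the frame cross-section at each named device level."""
    fractions = dict(level_fractions or DEFAULT_LEVEL_FRACTIONS)
    zl = frame.nodes[:, 0, 2]
    z0, height = zl.min(), zl.max() - zl.min()
    out = []
    for name, frac in fractions.items():
        poly = cross_section(frame, z0 + frac * height)
        m = polygon_measure(poly, level=name)
        out.append(m)
    return out


def perturb_measurements(
    measurements, bias: float = 0.0, noise_sd: float = 0.0, rng=None
):
    """Synthetic 'post-operative' measurements: predicted + bias + seeded noise.

    Stand-in for CT-derived observations, which are not available here.
    """
    rng = np.random.default_rng(rng)
    out = []
    for m in measurements:
        dmax = m.dmax + bias + rng.normal(0, noise_sd)
        dmin = m.dmin + bias + rng.normal(0, noise_sd)
        dmax, dmin = max(dmax, dmin), min(dmax, dmin)  # noise cannot reorder
        out.append(
            CrossSectionMeasurement(
                m.level,
                dmax,
                dmin,
                m.perimeter + bias + rng.normal(0, noise_sd),
                m.area + bias + rng.normal(0, noise_sd),
            )
        )
    return out


def compare_frames(predicted, observed) -> dict[str, dict[str, float]]:
    """Per-measurement mean difference (observed - predicted), SD and R^2."""
    if len(predicted) != len(observed):
        raise ValueError("paired lists must have equal length")
    if len(predicted) < 3:
        raise ValueError("need at least 3 paired measurements")
    result = {}
    for name in MEASUREMENT_NAMES:
        p = np.array([getattr(m, name) for m in predicted], dtype=float)
        o = np.array([getattr(m, name) for m in observed], dtype=float)
        diff = o - p
        if np.std(p) == 0 or np.std(o) == 0:
            r2 = 1.0 if np.allclose(diff, diff[0]) else float("nan")
        else:
            r2 = float(sps.pearsonr(o, p).statistic ** 2)
        result[name] = {
            "mean_diff": float(diff.mean()),
            "sd_diff": float(diff.std(ddof=1)),
            "r_squared": r2,
        }
    return result
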