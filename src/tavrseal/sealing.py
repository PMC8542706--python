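"""Skirt apposition/malapposition analysis.

For every element of the deployed device skirt, the anatomy element in the
element's outward normal direction is found by ray casting; the distance to
it classifies the element as apposed (< 1 mm) or malapposed (>= 1 mm,
strict threshold semantics).  Apposed and malapposed areas are accumulated
per anatomical region -- LVOT, leaflets, interleaflet triangles -- on the
deformed three-dimensional skirt elements; the ascending aorta is
quantified separately and excluded from all percentages.  A 2D unrolled
skirt map is produced for reporting only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import anatomy as ana
from .deployment import DeployedState
from .raycast import MeshRayCaster, closest_point_on_mesh

UNRESOLVED = "UNRESOLVED"

#: the three regions entering the sealing totals
CORE_REGIONS = (ana.LVOT, ana.LEAFLET, ana.INTERLEAFLET_TRIANGLE)

#: default apposition distance threshold (mm)
DEFAULT_THRESHOLD = 1.0

#: default malapposition-% thresholds for the surrogate PVL grading;
#: calibration defaults, exposed as configuration
DEFAULT_PVL_THRESHOLDS = (10.0, 25.0)

PVL_GRADES = ("none_or_trace", "mild", "moderate")


@dataclass
class SkirtElementRecord:
    element_id: int
    centroid: np.ndarray  # (3,) mm
    area: float  # mm^2
    region: str
    distance: float  # mm; inf when unresolved
    apposed: bool = False
    via_fallback: bool = False  # nearest-point fallback used (no ray hit)

    @property
    def theta(self) -> float:
        return float(np.mod(np.arctan2(self.centroid[1], self.centroid[0]), 2 * np.pi))


def element_distance(
    centroid: np.ndarray,
    normal: np.ndarray,
    anatomy: ana.AorticRootMesh,
    max_ray_length: float = 15.0,
    caster: MeshRayCaster | None = None,
) -> tuple[float, str, str, bool]:
    """Distance from a skirt element to the anatomy along its outward normal.

    Returns ``(distance, region, material, via_fallback)``.  If no anatomy
    triangle lies on the ray within ``max_ray_length``, the nearest-point
    distance is used instead (flagged); if even that exceeds
    ``max_ray_length`` the element is UNRESOLVED.
    """
    n = np.asarray(normal, dtype=float)
    nn = np.linalg.norm(n)
    if not nn > 1e-12:
        raise ValueError("degenerate element normal")
    n = n / nn
    caster = caster or MeshRayCaster(anatomy.vertices, anatomy.triangles)
    dist, tri = caster.first_hit(np.asarray(centroid, float), n, max_ray_length)
    if tri >= 0:
        return dist, str(anatomy.region_label[tri]), str(anatomy.material_id[tri]), False
    dist, tri = closest_point_on_mesh(
        np.asarray(centroid, float), anatomy.vertices, anatomy.triangles
    )
    if dist <= max_ray_length:
        return dist, str(anatomy.region_label[tri]), str(anatomy.material_id[tri]), True
    return np.inf, UNRESOLVED, "", True


def _element_geometry(corners: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """Centroid, area and outward unit normal of a quadrilateral element."""
    centroid = corners.mean(axis=0)
    a1 = 0.5 * np.linalg.norm(np.cross(corners[1] - corners[0], corners[2] - corners[0]))
    a2 = 0.5 * np.linalg.norm(np.cross(corners[2] - corners[0], corners[3] - corners[0]))
    normal = np.cross(corners[2] - corners[0], corners[3] - corners[1])
    nn = np.linalg.norm(normal)
    normal = normal / nn if nn > 1e-12 else np.array([1.0, 0.0, 0.0])
    radial = np.array([centroid[0], centroid[1], 0.0])
    if np.dot(normal, radial) < 0:
        normal = -normal
    return centroid, float(a1 + a2), normal


def skirt_records(
    state: DeployedState, max_ray_length: float = 15.0
) -> list[SkirtElementRecord]:
    """Build one record per skirt element of a deployed frame."""
    frame = state.frame
    nodes = frame.nodes.reshape(-1, 3)
    caster = MeshRayCaster(state.anatomy.vertices, state.anatomy.triangles)
    records = []
    for eid, quad in enumerate(frame.skirt_elements):
        corners = nodes[quad]
        centroid, area, normal = _element_geometry(corners)
        dist, region, _mat, fb = element_distance(
            centroid, normal, state.anatomy, max_ray_length, caster
        )
        records.append(
            SkirtElementRecord(eid, centroid, area, region, dist, via_fallback=fb)
        )
    return records


def classify(
    records: list[SkirtElementRecord], threshold: float = DEFAULT_THRESHOLD
) -> list[SkirtElementRecord]:
    """Set the apposed flag: apposed iff distance strictly below threshold.

    A distance of exactly the threshold counts as malapposed.
    """
    for rec in records:
        rec.apposed = bool(rec.distance < threshold)
    return records


@dataclass
class SealingSummary:
    """Per-region apposed/malapposed skirt areas and derived percentages.

    The ascending aorta is reported separately and excluded from the total
    skirt area and from all percentages.
    """

    apposed_area: dict[str, float]  # per core region, mm^2
    malapposed_area: dict[str, float]
    ascending_apposed_area: float = 0.0
    ascending_malapposed_area: float = 0.0
    n_unresolved: int = 0
    unresolved_fraction: float = 0.0

    @property
    def total_skirt_area(self) -> float:
        return sum(self.apposed_area.values()) + sum(self.malapposed_area.values())

    @property
    def total_apposed_area(self) -> float:
        return sum(self.apposed_area.values())

    @property
    def total_malapposed_area(self) -> float:
        return sum(self.malapposed_area.values())

    @property
    def malapposition_total_pct(self) -> float:
        total = self.total_skirt_area
        return 100.0 * self.total_malapposed_area / total if total > 0 else 0.0

    def malapposition_pct(self, region: str) -> float:
        total = self.total_skirt_area
        return 100.0 * self.malapposed_area[region] / total if total > 0 else 0.0

    def apposition_contribution_pct(self, region: str) -> float:
        apposed = self.total_apposed_area
        return 100.0 * self.apposed_area[region] / apposed if apposed > 0 else 0.0

    def as_row(self) -> dict[str, float]:
        """Flat record with the sealing-table row names."""
        row = {
            "total_skirt_area": self.total_skirt_area,
            "malapposition_total_pct": self.malapposition_total_pct,
            "apposition_total_pct": 100.0 - self.malapposition_total_pct,
        }
        short = {ana.LVOT: "lvot", ana.LEAFLET: "leaflet",
                 ana.INTERLEAFLET_TRIANGLE: "triangle"}
        for region, name in short.items():
            row[f"apposed_area_{name}"] = self.apposed_area[region]
            row[f"malapposed_area_{name}"] = self.malapposed_area[region]
            row[f"malapposition_pct_{name}"] = self.malapposition_pct(region)
            row[f"apposition_contribution_pct_{name}"] = (
                self.apposition_contribution_pct(region)
            )
        row["ascending_apposed_area"] = self.ascending_apposed_area
        row["ascending_malapposed_area"] = self.ascending_malapposed_area
        row["unresolved_fraction"] = self.unresolved_fraction
        return row

    @classmethod
    def from_areas(
        cls,
        apposed: dict[str, float],
        malapposed: dict[str, float],
        ascending: tuple[float, float] = (0.0, 0.0),
    ) -> "SealingSummary":
        return cls(
            {r: float(apposed.get(r, 0.0)) for r in CORE_REGIONS},
            {r: float(malapposed.get(r, 0.0)) for r in CORE_REGIONS},
            ascending[0],
            ascending[1],
        )


def summarize(records: list[SkirtElementRecord]) -> SealingSummary:
    """Accumulate classified element areas into a sealing summary.

    Unresolved elements are counted into the nearest resolved region by
    angular proximity and their fraction is reported.
    """
    if not records:
        raise ValueError("no skirt element records to summarize")
    resolved = [r for r in records if r.region != UNRESOLVED]
    unresolved = [r for r in records if r.region == UNRESOLVED]
    if not resolved:
        raise ValueError("all skirt elements are unresolved")
    apposed = {r: 0.0 for r in CORE_REGIONS}
    malapposed = {r: 0.0 for r in CORE_REGIONS}
    asc = [0.0, 0.0]

    def add(region: str, rec: SkirtElementRecord) -> None:
        if region == ana.ASCENDING_AORTA:
            asc[0 if rec.apposed else 1] += rec.area
        else:
            (apposed if rec.apposed else malapposed)[region] += rec.area

    for rec in resolved:
        add(rec.region, rec)
    res_theta = np.array([r.theta for r in resolved])
    res_z = np.array([r.centroid[2] for r in resolved])
    for rec in unresolved:
        d_ang = np.abs((res_theta - rec.theta + np.pi) % (2 * np.pi) - np.pi)
        score = d_ang + 0.01 * np.abs(res_z - rec.centroid[2])
        nearest = resolved[int(np.argmin(score))]
        add(nearest.region, rec)

    summary = SealingSummary(
        apposed,
        malapposed,
        asc[0],
        asc[1],
        n_unresolved=len(unresolved),
        unresolved_fraction=len(unresolved) / len(records),
    )
    return summary


def analyze(
    state: DeployedState,
    threshold: float = DEFAULT_THRESHOLD,
    max_ray_length: float = 15.0,
) -> tuple[SealingSummary, list[SkirtElementRecord]]:
    """Full sealing analysis of a deployed state."""
    records = classify(skirt_records(state, max_ray_length), threshold)
    return summarize(records), records


def project_2d(
    state: DeployedState, records: list[SkirtElementRecord]
) -> tuple[list[np.ndarray], float]:
    """Unroll the skirt onto (theta * r_ref, z); reporting only.

    Returns one (4, 2) polygon per skirt element and the reference radius.
    """
    frame = state.frame
    nodes = frame.nodes.reshape(-1, 3)
    skirt_nodes = np.unique(frame.skirt_elements.ravel())
    r_ref = float(np.linalg.norm(nodes[skirt_nodes, :2], axis=1).mean())
    polys = []
    for quad in frame.skirt_elements:
        corners = nodes[quad]
        th = np.arctan2(corners[:, 1], corners[:, 0])
        th = np.unwrap(th)
        polys.append(np.column_stack([th * r_ref, corners[:, 2]]))
    return polys, r_ref


def sealing_map_figure(polys, records: list[SkirtElementRecord]):
    """Two-panel unrolled skirt map (region, apposition); returns a Figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.collections import PolyCollection

    region_colors = {
        ana.LVOT: "#92c5de",
        ana.LEAFLET: "#fddbc7",
        ana.INTERLEAFLET_TRIANGLE: "#d6604d",
        ana.ASCENDING_AORTA: "#bababa",
        UNRESOLVED: "#ffffff",
    }
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for ax, mode in zip(axes, ("region", "apposition")):
        if mode == "region":
            colors = [region_colors.get(r.region, "#ffffff") for r in records]
            ax.set_title("anatomical region")
        else:
            colors = ["#2166ac" if r.apposed else "#b2182b" for r in records]
            ax.set_title("apposed (blue) / malapposed (red)")
        ax.add_collection(PolyCollection(polys, facecolors=colors, edgecolors="none"))
        ax.autoscale()
        ax.set_xlabel("unrolled circumference (mm)")
    axes[0].set_ylabel("height (mm)")
    fig.tight_layout()
    return fig


def pvl_surrogate(
    summary: "SealingSummary | float",
    grade_thresholds: tuple[float, float] = DEFAULT_PVL_THRESHOLDS,
) -> str:
    """Surrogate PVL grade from total skirt malapposition percentage.

    Grade is none_or_trace below t1 %, mild below t2 %, moderate otherwise.
    """
    t1, t2 = grade_thresholds
    if not t1 < t2:
        raise ValueError("grade thresholds must satisfy t1 < t2")
    pct = summary.malapposition_total_pct if isinstance(summary, SealingSummary) else float(summary)
    if pct < t1:
        return "none_or_trace"
    if pct < t2:
        return "mild"
    return "moderate"
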