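"""Parametric, region-labeled aortic-root surfaces and synthetic cohorts.

The aortic root is modeled as an open tube around the z-axis (annular plane
at z = 0, +z toward the aorta) whose inner surface carries per-triangle
anatomical region labels -- left ventricular outflow tract (LVOT), leaflets,
interleaflet triangles, ascending aorta -- and material assignments (wall,
leaflet tissue, calcium).  Native leaflets are represented as part of the
tube surface (a slightly in-bulged band between the annulus and the
commissure level): the downstream sealing analysis only needs the innermost
surface the device skirt can face.

Morphologies
------------
* TAV: three leaflets, three interleaflet triangles at 120 degrees.
* BAV type 0 (Sievers): two leaflets, two interleaflet triangles at 180
  degrees; one triangle is congenitally absent.
* BAV type 1: three developmental leaflets of which two are fused by a
  raphe; the corresponding interleaflet triangle is effaced and relabeled as
  leaflet tissue, leaving two functional triangles.

Interleaflet triangles are modeled as outward wall recesses (the wall
between leaflet attachment lines sits outside the leaflet surface); the
recess depth is a per-patient dysmorphism parameter, deeper for bicuspid
roots whose remaining triangles are underdeveloped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.stats import truncnorm

from .metrics import polygon_measure

# region labels
LVOT = "LVOT"
LEAFLET = "LEAFLET"
INTERLEAFLET_TRIANGLE = "INTERLEAFLET_TRIANGLE"
ASCENDING_AORTA = "ASCENDING_AORTA"
REGIONS = (LVOT, LEAFLET, INTERLEAFLET_TRIANGLE, ASCENDING_AORTA)

# material ids
WALL = "WALL"
LEAFLET_TISSUE = "LEAFLET_TISSUE"
CALCIUM = "CALCIUM"

MORPHOLOGIES = ("TAV", "BAV0", "BAV1")

DEVICE_SIZES = (23, 26, 29, 32)


@dataclass(frozen=True)
class CalciumDeposit:
    """A calcific nodule on the leaflet (or raphe) surface.

    ``volume`` is the target deposit volume in mm^3; ``protrusion`` the
    maximum inward displacement of the leaflet surface.  ``extent_*`` give
    the nominal angular/axial footprint half-window used to seed the
    placement.
    """

    center_angle: float  # rad
    center_height: float  # mm above the annular plane
    extent_angle: float  # rad, half-extent
    extent_height: float  # mm, half-extent
    volume: float  # mm^3
    protrusion: float  # mm

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("calcium deposit volume must be positive")
        if self.protrusion < 0:
            raise ValueError("calcium protrusion must be non-negative")


@dataclass(frozen=True)
class RootParams:
    """Parameters of a synthetic aortic root. All lengths in mm."""

    morphology: str
    annulus_dmax: float
    annulus_dmin: float
    lvot_height: float = 16.0
    sinus_radius_factor: float = 1.2
    commissure_height: float = 18.0
    stj_height: float = 22.0
    ascending_height: float = 15.0
    raphe_present: bool = False
    raphe_height_fraction: float = 0.0
    calcium_deposits: tuple[CalciumDeposit, ...] = ()
    mesh_resolution: tuple[int, int] = (96, 60)
    # dysmorphism / shape extensions (defaulted; not part of the minimal schema)
    triangle_recess: float = 1.0  # peak outward recess of interleaflet triangles, mm
    leaflet_bulge: float = 0.4  # peak inward belly of the leaflet band, mm
    raphe_depth: float = 2.0  # inward ridge height of the raphe, mm
    ellipse_phase: float = 0.0  # rotation of the annular ellipse axes, rad

    def __post_init__(self) -> None:
        if self.morphology not in MORPHOLOGIES:
            raise ValueError(f"unknown morphology {self.morphology!r}")
        if self.annulus_dmin > self.annulus_dmax:
            raise ValueError("annulus_dmin must not exceed annulus_dmax")
        if not (self.commissure_height < self.stj_height):
            raise ValueError("commissure_height must lie below the sinotubular junction")
        if self.sinus_radius_factor < 1:
            raise ValueError("sinus_radius_factor must be >= 1")
        if self.morphology == "BAV0" and self.raphe_present:
            raise ValueError("BAV type 0 has no raphe")
        if self.morphology == "BAV1" and not self.raphe_present:
            raise ValueError("BAV type 1 requires a raphe")
        if not 0 <= self.raphe_height_fraction <= 1:
            raise ValueError("raphe_height_fraction must lie in [0, 1]")
        circ, axial = self.mesh_resolution
        if circ < 24 or axial < 12:
            raise ValueError("mesh resolution must be at least 24 x 12")

    @property
    def commissure_angles(self) -> np.ndarray:
        """Angular positions of the developmental commissures."""
        n = 2 if self.morphology == "BAV0" else 3
        return np.arange(n) * 2 * np.pi / n

    @property
    def active_commissure_angles(self) -> np.ndarray:
        """Commissures flanked by a real interleaflet triangle.

        For BAV type 1 the commissure at theta = 0 is fused by the raphe and
        its triangle is effaced.
        """
        ang = self.commissure_angles
        if self.morphology == "BAV1":
            return ang[1:]
        return ang


@dataclass
class AorticRootMesh:
    """Triangulated inner surface of the aortic root.

    Open tube: two boundary loops (ventricular inlet, aortic outlet).
    ``region_label`` and ``material_id`` are per-triangle string arrays.
    """

    vertices: np.ndarray  # (n, 3) mm
    triangles: np.ndarray  # (m, 3) int
    region_label: np.ndarray  # (m,) str
    material_id: np.ndarray  # (m,) str

    def __post_init__(self) -> None:
        m = len(self.triangles)
        if len(self.region_label) != m or len(self.material_id) != m:
            raise ValueError("per-triangle label arrays must match triangle count")

    def copy(self) -> "AorticRootMesh":
        return AorticRootMesh(
            self.vertices.copy(),
            self.triangles.copy(),
            self.region_label.copy(),
            self.material_id.copy(),
        )

    def triangle_areas(self) -> np.ndarray:
        a = self.vertices[self.triangles[:, 0]]
        b = self.vertices[self.triangles[:, 1]]
        c = self.vertices[self.triangles[:, 2]]
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def triangle_centroids(self) -> np.ndarray:
        return self.vertices[self.triangles].mean(axis=1)

    def region_areas(self) -> dict[str, float]:
        areas = self.triangle_areas()
        return {r: float(areas[self.region_label == r].sum()) for r in REGIONS}

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.triangles, process=False
        )


def _ellipse_radius(theta: np.ndarray, a: float, b: float) -> np.ndarray:
    """Polar radius of an ellipse with semi-axes a (x) and b (y)."""
    return a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)


def ellipse_perimeter(a: float, b: float) -> float:
    """Ramanujan's second approximation (exact to ~1e-9 for these aspect ratios)."""
    h = ((a - b) / (a + b)) ** 2 if a + b > 0 else 0.0
    return np.pi * (a + b) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h)))


def _angular_distance(theta: np.ndarray, anchor: float) -> np.ndarray:
    d = np.abs((theta - anchor + np.pi) % (2 * np.pi) - np.pi)
    return d


def _axial_rings(params: RootParams) -> np.ndarray:
    """Ring heights covering LVOT -> annulus -> sinus -> ascending aorta.

    Rings are placed so that exact rings exist at the annular plane (z = 0)
    and at the commissure and sinotubular-junction levels.
    """
    _, axial = params.mesh_resolution
    z_lo = -params.lvot_height
    z_top = params.stj_height + params.ascending_height
    joints = [z_lo, 0.0, params.commissure_height, params.stj_height, z_top]
    total = z_top - z_lo
    rings: list[np.ndarray] = []
    for lo, hi in zip(joints[:-1], joints[1:]):
        n = max(2, int(round(axial * (hi - lo) / total)))
        seg = np.linspace(lo, hi, n + 1)
        rings.append(seg if not rings else seg[1:])
    return np.concatenate(rings)


def _radius_field(params: RootParams, theta: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Inner-surface radius at (theta, z) grid points (broadcasting arrays)."""
    a = params.annulus_dmax / 2.0
    b = params.annulus_dmin / 2.0
    ch = params.commissure_height
    e0 = _ellipse_radius(theta - params.ellipse_phase, a, b)
    # the root circularizes above the annulus: elliptical LVOT/annulus,
    # near-circular at the commissure level and above (area-preserving)
    r_circ = np.sqrt(a * b)
    blend = np.clip(z / ch, 0, 1)
    e = e0 * (1 - blend) + r_circ * blend
    r = np.array(np.broadcast_to(e, np.broadcast(theta, z).shape), dtype=float)

    band = (z >= 0) & (z < ch)
    if np.any(band):
        zf = np.clip(z / ch, 0, 1)
        # recesses plateau over most of the band (dysmorphic triangles are
        # effaced along their whole height, not only at mid-band)
        axial_shape = np.clip(2.0 * np.sin(np.pi * zf), 0, 1)
        # interleaflet triangle wedges: outward recesses narrowing toward the apex
        n_dev = len(params.commissure_angles)
        w_base = 0.35 * np.pi / n_dev
        tri_w = np.zeros(r.shape)
        for ang in params.active_commissure_angles:
            d = _angular_distance(theta, float(ang))
            hw = w_base * (1 - zf) + np.deg2rad(2.0)
            # near-uniform recess across the wedge width, tapered at the rim
            w = np.clip(3.0 * (1 - d / hw), 0, 1)
            tri_w = np.maximum(tri_w, np.broadcast_to(w, r.shape))
        r = np.where(
            band,
            r
            + params.triangle_recess * axial_shape * tri_w
            - params.leaflet_bulge * axial_shape * (1 - tri_w),
            r,
        )
        # raphe ridge on the fused commissure (BAV1)
        if params.raphe_present and params.raphe_height_fraction > 0:
            rh = params.raphe_height_fraction * ch
            d0 = _angular_distance(theta, float(params.commissure_angles[0]))
            ridge = (
                params.raphe_depth
                * np.clip(1 - z / rh, 0, 1)
                * np.clip(1 - d0 / np.deg2rad(12.0), 0, 1)
            )
            r = np.where(band, r - ridge, r)

    sinus = (z >= ch) & (z < params.stj_height)
    if np.any(sinus):
        sf = np.sin(np.pi * np.clip((z - ch) / (params.stj_height - ch), 0, 1))
        r = np.where(sinus, e * (1 + (params.sinus_radius_factor - 1) * sf), r)

    asc = z >= params.stj_height
    if np.any(asc):
        taper = 1 - 0.05 * np.clip((z - params.stj_height) / 5.0, 0, 1)
        r = np.where(asc, e * taper, r)
    return r


def build_root(params: RootParams) -> AorticRootMesh:
    """Build the region-labeled parametric aortic-root surface mesh."""
    circ, _ = params.mesh_resolution
    n_dev = len(params.commissure_angles)
    if circ < 12 * n_dev:
        raise ValueError(
            f"circumferential resolution {circ} too coarse to represent "
            f"{n_dev} leaflets (need at least {12 * n_dev})"
        )

    theta = np.arange(circ) * 2 * np.pi / circ
    zs = _axial_rings(params)
    th_grid = theta[None, :]
    z_grid = zs[:, None]
    r = _radius_field(params, th_grid, z_grid)

    nv = len(zs) * circ
    vertices = np.empty((nv, 3))
    vertices[:, 0] = (r * np.cos(th_grid)).ravel()
    vertices[:, 1] = (r * np.sin(th_grid)).ravel()
    vertices[:, 2] = np.broadcast_to(z_grid, r.shape).ravel()

    tris = []
    for i in range(len(zs) - 1):
        for j in range(circ):
            j1 = (j + 1) % circ
            v00 = i * circ + j
            v01 = i * circ + j1
            v10 = (i + 1) * circ + j
            v11 = (i + 1) * circ + j1
            tris.append((v00, v01, v11))
            tris.append((v00, v11, v10))
    triangles = np.array(tris, dtype=int)

    cent = vertices[triangles].mean(axis=1)
    zc = cent[:, 2]
    thc = np.mod(np.arctan2(cent[:, 1], cent[:, 0]), 2 * np.pi)
    ch = params.commissure_height

    region = np.full(len(triangles), LEAFLET, dtype="U24")
    region[zc < 0] = LVOT
    region[zc >= ch] = ASCENDING_AORTA
    band = (zc >= 0) & (zc < ch)
    n_dev = len(params.commissure_angles)
    w_base = 0.35 * np.pi / n_dev
    in_tri = np.zeros(len(triangles), dtype=bool)
    zf = np.clip(zc / ch, 0, 1)
    hw = w_base * (1 - zf) + np.deg2rad(2.0)
    for ang in params.active_commissure_angles:
        in_tri |= _angular_distance(thc, float(ang)) <= hw
    region[band & in_tri] = INTERLEAFLET_TRIANGLE

    material = np.where(region == LEAFLET, LEAFLET_TISSUE, WALL).astype("U24")
    return AorticRootMesh(vertices, triangles, region, material)


def count_region_patches(mesh: AorticRootMesh, label: str) -> int:
    """Number of edge-connected patches of triangles carrying ``label``."""
    idx = np.flatnonzero(mesh.region_label == label)
    if len(idx) == 0:
        return 0
    tri = mesh.triangles[idx]
    edges = {}
    rows, cols = [], []
    for local, t in enumerate(tri):
        for k in range(3):
            e = tuple(sorted((int(t[k]), int(t[(k + 1) % 3]))))
            if e in edges:
                rows.append(edges[e])
                cols.append(local)
            else:
                edges[e] = local
    n = len(idx)
    adj = sparse.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    ncomp, _ = connected_components(adj, directed=False)
    return int(ncomp)


def _cross_section_polygon(mesh: AorticRootMesh, z: float = 0.0) -> np.ndarray:
    """Ordered (k, 2) polygon of the mesh cross-section at height z."""
    tm = mesh.to_trimesh()
    path = tm.section(plane_origin=[0, 0, z], plane_normal=[0, 0, 1])
    if path is None:
        raise ValueError(f"plane z={z} does not intersect the mesh")
    loops = path.discrete
    if not loops:
        raise ValueError(f"plane z={z} does not intersect the mesh")
    loop = max(loops, key=len)
    poly = np.asarray(loop)[:, :2]
    # discrete loops repeat the first point at the end
    if np.allclose(poly[0], poly[-1]):
        poly = poly[:-1]
    return poly


def annulus_metrics(
    mesh: AorticRootMesh, z: float = 0.0
) -> tuple[float, float, float, float]:
    """(dmax, dmin, perimeter-derived diameter, area-derived diameter) at z.

    Perimeter-derived diameter is P/pi; area-derived is 2*sqrt(A/pi).
    """
    poly = _cross_section_polygon(mesh, z)
    m = polygon_measure(poly)
    return (
        m.dmax,
        m.dmin,
        m.perimeter / np.pi,
        2.0 * np.sqrt(m.area / np.pi),
    )


def place_calcium(
    mesh: AorticRootMesh, deposits: list[CalciumDeposit] | tuple[CalciumDeposit, ...]
) -> AorticRootMesh:
    """Assign calcific deposits to leaflet triangles.

    For each deposit, leaflet triangles nearest the deposit center (in the
    normalized angular/axial footprint metric) are selected until their
    summed area reaches volume/protrusion, then displaced inward by a
    uniform depth volume/area so that footprint-area x depth reproduces the
    requested volume.  Selected triangles are relabeled material CALCIUM.
    """
    out = mesh.copy()
    if not deposits:
        return out
    for dep in deposits:
        cent = out.triangle_centroids()
        thc = np.mod(np.arctan2(cent[:, 1], cent[:, 0]), 2 * np.pi)
        zc = cent[:, 2]
        # deposits are distinct nodules: footprints never overlap; a window
        # already claimed by an earlier deposit grows onto the nearest free
        # leaflet triangles instead
        on_leaflet = (out.region_label == LEAFLET) & (out.material_id != CALCIUM)
        d_ang = _angular_distance(thc, dep.center_angle) / max(dep.extent_angle, 1e-9)
        d_ax = np.abs(zc - dep.center_height) / max(dep.extent_height, 1e-9)
        score = np.sqrt(d_ang**2 + d_ax**2)
        if not ((out.region_label == LEAFLET) & (score <= 1.0)).any():
            raise ValueError(
                "calcium deposit footprint does not overlap any leaflet triangle"
            )
        if not on_leaflet.any():
            raise ValueError("no uncalcified leaflet surface left for deposit")
        areas = out.triangle_areas()
        if dep.protrusion <= 0:
            sel = np.flatnonzero(on_leaflet & (score <= 1.0))
        else:
            target_area = dep.volume / dep.protrusion
            order = np.argsort(np.where(on_leaflet, score, np.inf))
            cum = np.cumsum(areas[order])
            n_sel = int(np.searchsorted(cum, target_area) + 1)
            n_sel = min(n_sel, int(on_leaflet.sum()))
            sel = order[:n_sel]
        out.material_id[sel] = CALCIUM
        if dep.protrusion > 0:
            sel_area = float(areas[sel].sum())
            depth = dep.volume / sel_area
            verts = np.unique(out.triangles[sel].ravel())
            xy = out.vertices[verts, :2]
            rr = np.linalg.norm(xy, axis=1)
            shrink = np.clip((rr - depth) / np.where(rr > 0, rr, 1.0), 0, None)
            out.vertices[verts, 0] *= shrink
            out.vertices[verts, 1] *= shrink
    return out


# ---------------------------------------------------------------------------
# synthetic cohort
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CovariateSpec:
    mean: float
    sd: float
    lo: float
    hi: float

    def sample(self, rng: np.random.Generator) -> float:
        if self.sd <= 0:
            return float(np.clip(self.mean, self.lo, self.hi))
        a = (self.lo - self.mean) / self.sd
        b = (self.hi - self.mean) / self.sd
        return float(truncnorm.rvs(a, b, loc=self.mean, scale=self.sd, random_state=rng))


def _default_covariates() -> dict[str, dict[str, CovariateSpec]]:
    """Group-wise covariate distributions of the emulated study population."""
    return {
        "TAV": {
            "age": CovariateSpec(79.4, 6.2, 60, 95),
            "annulus_dmax": CovariateSpec(27.4, 3.2, 21, 36),
            "annulus_dmin": CovariateSpec(21.1, 2.3, 17, 30),
            "calcium_volume": CovariateSpec(781.8, 576.6, 100, 2500),
            "depth": CovariateSpec(7.4, 3.1, 0, 14),
            "triangle_recess": CovariateSpec(0.5, 0.3, 0.0, 1.2),
        },
        "BAV0": {
            "age": CovariateSpec(77.8, 5.6, 60, 95),
            "annulus_dmax": CovariateSpec(27.4, 3.5, 21, 36),
            "annulus_dmin": CovariateSpec(21.7, 3.5, 17, 30),
            "calcium_volume": CovariateSpec(1210.7, 778.0, 100, 2500),
            "depth": CovariateSpec(6.2, 3.3, 0, 14),
            "triangle_recess": CovariateSpec(2.0, 0.5, 0.8, 3.5),
        },
        "BAV1": {
            "age": CovariateSpec(75.4, 8.1, 60, 95),
            "annulus_dmax": CovariateSpec(29.6, 3.0, 21, 36),
            "annulus_dmin": CovariateSpec(22.7, 3.4, 17, 30),
            "calcium_volume": CovariateSpec(1213.5, 676.6, 100, 2500),
            "depth": CovariateSpec(6.1, 4.2, 0, 14),
            "triangle_recess": CovariateSpec(2.0, 0.5, 0.8, 3.5),
        },
    }


@dataclass(frozen=True)
class CohortSpec:
    """A seeded synthetic cohort emulating the study population."""

    n_tav: int = 17
    n_bav0: int = 11
    n_bav1: int = 15
    seed: int = 0
    sizing_target: float = 1.0  # smallest size with size/perimeter-diam >= target
    covariates: dict[str, dict[str, CovariateSpec]] = field(
        default_factory=_default_covariates
    )
    mesh_resolution: tuple[int, int] = (96, 60)

    def __post_init__(self) -> None:
        if min(self.n_tav, self.n_bav0, self.n_bav1) < 0:
            raise ValueError("group counts must be non-negative")
        for group in self.covariates.values():
            for cov in group.values():
                if cov.sd < 0:
                    raise ValueError("covariate SD must be non-negative")
                if cov.lo > cov.hi:
                    raise ValueError("infeasible covariate bounds")


def select_device_size(perimeter_diam: float, target: float = 1.0) -> int:
    """Smallest device size whose sizing index meets the target, else 32."""
    for size in DEVICE_SIZES:
        if size / perimeter_diam >= target:
            return size
    return DEVICE_SIZES[-1]


def _sample_deposits(
    rng: np.random.Generator, params_angles: np.ndarray, total_volume: float, ch: float
) -> tuple[CalciumDeposit, ...]:
    # heavy calcium burdens split into more nodules so that no single
    # deposit becomes thick enough to obstruct the crimped device
    n = max(int(rng.integers(1, 4)), int(np.ceil(total_volume / 850.0)))
    weights = rng.uniform(0.7, 1.3, n)
    weights = weights / weights.sum()
    # leaflet mid-angles lie between adjacent commissures
    ang = np.sort(params_angles)
    mids = (ang + np.diff(np.append(ang, ang[0] + 2 * np.pi)) / 2) % (2 * np.pi)
    mids = rng.permutation(mids)  # spread deposits over distinct leaflets
    deposits = []
    for k in range(n):
        center = float(mids[k % len(mids)] + rng.normal(0, 0.15))
        volume = float(max(total_volume * weights[k], 10.0))
        # cap each nodule's footprint at ~350 mm^2 so deposits never exhaust
        # the leaflet surface (thicker nodules for larger volumes)
        protrusion = max(float(rng.uniform(1.2, 2.5)), volume / 350.0)
        deposits.append(
            CalciumDeposit(
                center_angle=center % (2 * np.pi),
                center_height=float(rng.uniform(0.3, 0.7) * ch),
                extent_angle=float(rng.uniform(0.5, 1.1)),
                extent_height=float(rng.uniform(5.0, 9.0)),
                volume=volume,
                protrusion=protrusion,
            )
        )
    return tuple(deposits)


def sample_cohort(spec: CohortSpec) -> list[tuple[RootParams, dict]]:
    """Draw a seeded synthetic cohort; deterministic under a fixed seed.

    Returns one (RootParams, covariate record) pair per patient; records
    carry the cohort-table columns (patient_id, morphology, annulus metrics,
    calcium volume, device size, sizing index, implantation depth, age).
    """
    plan = (
        [("TAV", i) for i in range(spec.n_tav)]
        + [("BAV0", i) for i in range(spec.n_bav0)]
        + [("BAV1", i) for i in range(spec.n_bav1)]
    )
    streams = np.random.SeedSequence(spec.seed).spawn(len(plan))
    out = []
    for pid, ((morph, k), ss) in enumerate(zip(plan, streams)):
        rng = np.random.default_rng(ss)
        cov = spec.covariates[morph]
        dmax = cov["annulus_dmax"].sample(rng)
        dmin = min(cov["annulus_dmin"].sample(rng), dmax - 0.5)
        calcium = cov["calcium_volume"].sample(rng)
        depth = cov["depth"].sample(rng)
        recess = cov["triangle_recess"].sample(rng)
        age = cov["age"].sample(rng)

        a, b = dmax / 2.0, dmin / 2.0
        perim_diam = ellipse_perimeter(a, b) / np.pi
        area_diam = 2.0 * np.sqrt(a * b)
        size = select_device_size(perim_diam, spec.sizing_target)
        sizing_index = size / perim_diam

        raphe = morph == "BAV1"
        params = RootParams(
            morphology=morph,
            annulus_dmax=dmax,
            annulus_dmin=dmin,
            raphe_present=raphe,
            raphe_height_fraction=float(rng.uniform(0.3, 0.7)) if raphe else 0.0,
            mesh_resolution=spec.mesh_resolution,
            triangle_recess=recess,
            ellipse_phase=float(rng.uniform(0, 2 * np.pi)),
        )
        deposits = _sample_deposits(
            rng, params.commissure_angles, calcium, params.commissure_height
        )
        params = replace(params, calcium_deposits=deposits)
        record = {
            "patient_id": f"{morph}{k + 1:02d}",
            "morphology": morph,
            "annulus_dmax": round(dmax, 6),
            "annulus_dmin": round(dmin, 6),
            "perimeter_diam": round(perim_diam, 6),
            "area_diam": round(area_diam, 6),
            "calcium_volume": round(calcium, 6),
            "device_size": size,
            "sizing_index": round(sizing_index, 6),
            "depth": round(depth, 6),
            "age": round(age, 6),
            "triangle_recess": round(recess, 6),
        }
        out.append((params, record))
    return out
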