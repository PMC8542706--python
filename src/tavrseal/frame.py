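"""Parametric self-expanding frame models with a sealing skirt.

The frame is a diamond-cell node lattice (levels x sectors) following a
flared nominal radius profile; a fabric skirt covers the lattice cells of
the lower (inflow) portion.  The proprietary strut geometry of commercial
devices is not reproduced: the downstream analyses depend only on the
deployed outer surface and the skirt, so a generic lattice with a
configurable profile stands in.

Radial response uses a per-level linear hoop-spring law,

    F(d) = k * sum_levels max(0, (R_level - d/2) / R_level),

with a multiplicative factor < 1 on release (unloading), giving the
loading/unloading hysteresis seen on a radial-force bench.  Stiffness and
hysteresis are configuration, not calibrated constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

FRAME_SIZES = (23, 26, 29, 32)

#: total frame height used for all sizes (mm); desk-scale simplification
FRAME_HEIGHT = 50.0

#: skirt covers the lower fraction of the frame height by default
DEFAULT_SKIRT_FRACTION = 0.4


def default_profile(size: int) -> tuple[tuple[float, float], ...]:
    """Nominal (height, radius) profile: inflow flare -> waist -> outflow.

    The maximum nominal diameter equals the size label at the inflow; the
    flare extends over the annular sealing zone covered by the skirt.
    """
    r = size / 2.0
    return (
        (0.0, r),
        (10.0, r),
        (20.0, 0.95 * r),  # skirted sealing zone stays near-cylindrical
        (32.0, 0.85 * r),  # waist above the skirt (coronary access)
        (42.0, 0.88 * r),
        (FRAME_HEIGHT, 0.90 * r),
    )


@dataclass(frozen=True)
class FrameParams:
    size_label: int = 26
    nominal_profile: tuple[tuple[float, float], ...] = ()
    n_levels: int = 24
    n_sectors: int = 32
    circumferential_stiffness: float = 20.0  # N per level at unit hoop strain
    inter_level_stiffness: float = 0.02  # MPa/mm coupling between adjacent levels
    sector_coupling_stiffness: float = 0.15  # MPa/mm ring-bending proxy between sectors
    skirt_height: float = DEFAULT_SKIRT_FRACTION * FRAME_HEIGHT  # mm
    hysteresis_factor: float = 0.85  # unloading force multiplier, in (0, 1]

    def __post_init__(self) -> None:
        if self.size_label not in FRAME_SIZES:
            raise ValueError(f"size_label must be one of {FRAME_SIZES}")
        if not self.nominal_profile:
            object.__setattr__(self, "nominal_profile", default_profile(self.size_label))
        heights = [h for h, _ in self.nominal_profile]
        radii = [r for _, r in self.nominal_profile]
        if any(r <= 0 for r in radii):
            raise ValueError("profile radii must be positive")
        if any(h1 <= h0 for h0, h1 in zip(heights[:-1], heights[1:])):
            raise ValueError("profile heights must be strictly increasing")
        if self.n_sectors % 2:
            raise ValueError("n_sectors must be even (diamond cells)")
        if not 0 < self.hysteresis_factor <= 1:
            raise ValueError("hysteresis_factor must lie in (0, 1]")
        if self.skirt_height > heights[-1]:
            raise ValueError("skirt_height exceeds frame height")

    @property
    def height(self) -> float:
        return self.nominal_profile[-1][0]

    @property
    def nominal_diameter(self) -> float:
        """Largest nominal diameter (at the inflow; equals the size label)."""
        return 2.0 * max(r for _, r in self.nominal_profile)

    @property
    def min_nominal_diameter(self) -> float:
        return 2.0 * min(r for _, r in self.nominal_profile)

    def level_heights(self) -> np.ndarray:
        return np.linspace(0.0, self.height, self.n_levels)

    def level_radii(self) -> np.ndarray:
        hs = np.array([h for h, _ in self.nominal_profile])
        rs = np.array([r for _, r in self.nominal_profile])
        return np.interp(self.level_heights(), hs, rs)


@dataclass
class FrameMesh:
    """Node lattice of a frame with strut connectivity and skirt elements.

    ``nodes`` is an (n_levels, n_sectors, 3) array; ``struts`` an (s, 2)
    array of flattened node indices (index = level * n_sectors + sector);
    ``skirt_elements`` an (e, 4) array of flattened node quadruples
    (counter-clockwise cell corners).  ``reference_state`` keeps the nominal
    node positions and is never modified by crimping or deployment.
    """

    params: FrameParams
    nodes: np.ndarray
    struts: np.ndarray
    skirt_elements: np.ndarray
    reference_state: np.ndarray

    @property
    def n_levels(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_sectors(self) -> int:
        return self.nodes.shape[1]

    def copy(self) -> "FrameMesh":
        return FrameMesh(
            self.params,
            self.nodes.copy(),
            self.struts,
            self.skirt_elements,
            self.reference_state,
        )

    def node_radii(self) -> np.ndarray:
        return np.linalg.norm(self.nodes[:, :, :2], axis=2)

    def node_angles(self) -> np.ndarray:
        return np.mod(np.arctan2(self.nodes[:, :, 1], self.nodes[:, :, 0]), 2 * np.pi)

    def element_count(self) -> int:
        return len(self.struts) + len(self.skirt_elements)

    def restore_reference(self) -> "FrameMesh":
        out = self.copy()
        out.nodes = self.reference_state.copy()
        return out


def build_frame(params: FrameParams) -> FrameMesh:
    """Build the nominal frame lattice with its skirt."""
    L, S = params.n_levels, params.n_sectors
    zs = params.level_heights()
    rs = params.level_radii()
    theta = np.arange(S) * 2 * np.pi / S

    nodes = np.empty((L, S, 3))
    nodes[:, :, 0] = rs[:, None] * np.cos(theta)[None, :]
    nodes[:, :, 1] = rs[:, None] * np.sin(theta)[None, :]
    nodes[:, :, 2] = zs[:, None]

    def nid(level: int, sector: int) -> int:
        return level * S + sector % S

    struts = []
    for l in range(L):
        for s in range(S):
            struts.append((nid(l, s), nid(l, s + 1)))  # circumferential
            if l + 1 < L:
                struts.append((nid(l, s), nid(l + 1, s + 1)))  # diagonals
                struts.append((nid(l, s), nid(l + 1, s - 1)))

    skirt = []
    for l in range(L - 1):
        if zs[l + 1] <= params.skirt_height + 1e-9:
            for s in range(S):
                skirt.append((nid(l, s), nid(l, s + 1), nid(l + 1, s + 1), nid(l + 1, s)))

    return FrameMesh(
        params,
        nodes,
        np.array(struts, dtype=int),
        np.array(skirt, dtype=int),
        nodes.copy(),
    )


def crimp(frame: FrameMesh, target_diameter: float) -> FrameMesh:
    """Crimp the frame onto a cylinder: radius-only, angles/heights kept."""
    if not 0 < target_diameter < frame.params.min_nominal_diameter:
        raise ValueError(
            f"crimp target {target_diameter} mm must lie in "
            f"(0, {frame.params.min_nominal_diameter}) mm"
        )
    out = frame.copy()
    r = target_diameter / 2.0
    theta = frame.node_angles()
    out.nodes[:, :, 0] = r * np.cos(theta)
    out.nodes[:, :, 1] = r * np.sin(theta)
    return out


def radial_force(params: FrameParams, diameter: float, phase: str = "unloading") -> float:
    """Radial force (N) exerted at a crimper diameter, per the hoop-spring law."""
    if phase not in ("loading", "unloading"):
        raise ValueError("phase must be 'loading' or 'unloading'")
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    if diameter > params.nominal_diameter + 1e-9:
        raise ValueError("diameter exceeds nominal diameter")
    r = diameter / 2.0
    radii = params.level_radii()
    strain = np.clip((radii - r) / radii, 0.0, None)
    force = params.circumferential_stiffness * float(strain.sum())
    if phase == "unloading":
        force *= params.hysteresis_factor
    return force


@dataclass(frozen=True)
class RadialForceCurve:
    """Bench-test sweep: nominal -> min (loading) -> nominal (unloading)."""

    diameters: tuple[float, ...]  # descending grid
    loading_force: tuple[float, ...]
    unloading_force: tuple[float, ...]


def virtual_bench_test(
    params: FrameParams, min_diameter: float, n_steps: int = 20
) -> RadialForceCurve:
    """Virtual radial-force bench: crimp (loading) then release (unloading)."""
    if n_steps < 2:
        raise ValueError("n_steps must be at least 2")
    if not 0 < min_diameter < params.nominal_diameter:
        raise ValueError("min_diameter must lie below the nominal diameter")
    diameters = np.linspace(params.nominal_diameter, min_diameter, n_steps)
    loading = [radial_force(params, d, "loading") for d in diameters]
    unloading = [radial_force(params, d, "unloading") for d in diameters]
    return RadialForceCurve(
        tuple(float(d) for d in diameters),
        tuple(loading),
        tuple(unloading),
    )
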