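"""Mesh and state serialization.

Root surfaces travel as STL (binary or ASCII) or PLY through trimesh; STL
and PLY carry no attribute channels, so per-triangle region and material
labels are written to a JSON sidecar (``<mesh>.labels.json``, triangle
index order).  Frames and deployed states are stored as JSON (node grids
are small).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import trimesh

from .anatomy import AorticRootMesh
from .deployment import DeployedState
from .frame import FrameMesh, FrameParams

UNRESOLVED = "UNRESOLVED"


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".labels.json")


def write_mesh(mesh: AorticRootMesh, path: str | Path, ascii_stl: bool = False) -> Path:
    """Write an aortic-root mesh as STL/PLY plus a label sidecar."""
    path = Path(path)
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.triangles, process=False)
    suffix = path.suffix.lower()
    if suffix == ".stl":
        tm.export(path, file_type="stl_ascii" if ascii_stl else "stl")
    elif suffix == ".ply":
        tm.export(path, file_type="ply")
    else:
        raise ValueError(f"unsupported mesh format {suffix!r} (use .stl or .ply)")
    sidecar = _sidecar_path(path)
    sidecar.write_text(
        json.dumps(
            {
                "region_label": mesh.region_label.tolist(),
                "material_id": mesh.material_id.tolist(),
            }
        )
    )
    return path


def read_mesh(path: str | Path) -> AorticRootMesh:
    """Read an STL/PLY mesh with its label sidecar.

    STL stores a triangle soup; duplicate vertices are merged on load to
    recover shared connectivity.  A missing sidecar degrades to UNRESOLVED
    labels with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    tm = trimesh.load(path, process=False)
    if not isinstance(tm, trimesh.Trimesh):
        raise ValueError(f"{path} did not contain a single triangle mesh")
    if path.suffix.lower() == ".stl":
        tm.merge_vertices()
    m = len(tm.faces)
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        labels = json.loads(sidecar.read_text())
        region = np.array(labels["region_label"], dtype="U24")
        material = np.array(labels["material_id"], dtype="U24")
        if len(region) != m:
            raise ValueError(
                f"sidecar {sidecar} labels {len(region)} triangles, mesh has {m}"
            )
    else:
        warnings.warn(f"no label sidecar beside {path}; labels set to UNRESOLVED")
        region = np.full(m, UNRESOLVED, dtype="U24")
        material = np.full(m, UNRESOLVED, dtype="U24")
    return AorticRootMesh(
        np.asarray(tm.vertices, float), np.asarray(tm.faces, int), region, material
    )


def frame_to_dict(frame: FrameMesh) -> dict:
    p = frame.params
    return {
        "params": {
            "size_label": p.size_label,
            "nominal_profile": [list(pair) for pair in p.nominal_profile],
            "n_levels": p.n_levels,
            "n_sectors": p.n_sectors,
            "circumferential_stiffness": p.circumferential_stiffness,
            "inter_level_stiffness": p.inter_level_stiffness,
            "sector_coupling_stiffness": p.sector_coupling_stiffness,
            "skirt_height": p.skirt_height,
            "hysteresis_factor": p.hysteresis_factor,
        },
        "nodes": frame.nodes.tolist(),
        "struts": frame.struts.tolist(),
        "skirt_elements": frame.skirt_elements.tolist(),
        "reference_state": frame.reference_state.tolist(),
    }


def frame_from_dict(data: dict) -> FrameMesh:
    params = FrameParams(
        size_label=int(data["params"]["size_label"]),
        nominal_profile=tuple(tuple(p) for p in data["params"]["nominal_profile"]),
        n_levels=int(data["params"]["n_levels"]),
        n_sectors=int(data["params"]["n_sectors"]),
        circumferential_stiffness=float(data["params"]["circumferential_stiffness"]),
        inter_level_stiffness=float(data["params"]["inter_level_stiffness"]),
        sector_coupling_stiffness=float(
            data["params"].get("sector_coupling_stiffness", 0.15)
        ),
        skirt_height=float(data["params"]["skirt_height"]),
        hysteresis_factor=float(data["params"]["hysteresis_factor"]),
    )
    return FrameMesh(
        params,
        np.array(data["nodes"], float),
        np.array(data["struts"], int),
        np.array(data["skirt_elements"], int),
        np.array(data["reference_state"], float),
    )


def write_frame(frame: FrameMesh, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(frame_to_dict(frame)))
    return path


def read_frame(path: str | Path) -> FrameMesh:
    return frame_from_dict(json.loads(Path(path).read_text()))


def write_deployed_state(state: DeployedState, stem: str | Path) -> dict[str, Path]:
    """Persist a deployed state as <stem>.frame.json / .anatomy.stl / .contact.json."""
    stem = Path(stem)
    paths = {
        "frame": write_frame(state.frame, stem.with_suffix(".frame.json")),
        "anatomy": write_mesh(state.anatomy, stem.with_suffix(".anatomy.stl")),
    }
    contact = {
        "depth": state.depth,
        "gap": state.gap.tolist(),
        "contact_region": state.contact_region.tolist(),
        "contact_material": state.contact_material.tolist(),
        "wall_radius": np.where(
            np.isfinite(state.wall_radius), state.wall_radius, -1.0
        ).tolist(),
        "iterations": state.iterations,
        "final_residual": state.final_residual,
    }
    cpath = stem.with_suffix(".contact.json")
    cpath.write_text(json.dumps(contact))
    paths["contact"] = cpath
    return paths


def read_deployed_state(stem: str | Path) -> DeployedState:
    stem = Path(stem)
    frame = read_frame(stem.with_suffix(".frame.json"))
    anatomy = read_mesh(stem.with_suffix(".anatomy.stl"))
    contact = json.loads(stem.with_suffix(".contact.json").read_text())
    wall = np.array(contact["wall_radius"], float)
    wall[wall < 0] = np.inf
    return DeployedState(
        frame=frame,
        anatomy=anatomy,
        depth=float(contact["depth"]),
        gap=np.array(contact["gap"], float),
        contact_region=np.array(contact["contact_region"], dtype="U24"),
        contact_material=np.array(contact["contact_material"], dtype="U24"),
        wall_radius=wall,
        iterations=int(contact["iterations"]),
        final_residual=float(contact["final_residual"]),
    )
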