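"""Pipeline configuration with lossless YAML round-tripping."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .metrics import DEFAULT_LEVEL_FRACTIONS
from .sealing import DEFAULT_PVL_THRESHOLDS, DEFAULT_THRESHOLD


@dataclass
class MaterialConfig:
    elastic_modulus: float
    thickness: float
    yield_stress: float | None = None


def _default_materials() -> dict[str, "MaterialConfig"]:
    wall = MaterialConfig(2.0, 2.0)
    return {
        "LVOT": wall,
        "INTERLEAFLET_TRIANGLE": MaterialConfig(2.0, 2.0),
        "ASCENDING_AORTA": MaterialConfig(2.0, 2.0),
        "LEAFLET": MaterialConfig(0.6, 1.5),
        "CALCIUM": MaterialConfig(4.0, 2.0, 0.6),
    }


@dataclass
class PipelineConfig:
    # cohort
    n_tav: int = 17
    n_bav0: int = 11
    n_bav1: int = 15
    seed: int = 0
    sizing_target: float = 1.0
    mesh_resolution: tuple[int, int] = (96, 60)
    # device / deployment
    crimp_diameter: float = 8.0  # mm
    friction_coefficient: float = 0.7
    residual_tol: float = 1e-6
    max_iterations: int = 2000
    max_ray_length: float = 15.0
    materials: dict[str, MaterialConfig] = field(default_factory=_default_materials)
    # sealing / grading / metrics
    sealing_threshold: float = DEFAULT_THRESHOLD
    pvl_thresholds: tuple[float, float] = DEFAULT_PVL_THRESHOLDS
    level_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LEVEL_FRACTIONS)
    )
    # bookkeeping
    out_dir: str = "results"
    verbosity: str = "info"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mesh_resolution"] = list(self.mesh_resolution)
        d["pvl_thresholds"] = list(self.pvl_thresholds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "mesh_resolution" in d:
            d["mesh_resolution"] = tuple(d["mesh_resolution"])
        if "pvl_thresholds" in d:
            d["pvl_thresholds"] = tuple(d["pvl_thresholds"])
        if "materials" in d:
            d["materials"] = {
                k: MaterialConfig(**v) if isinstance(v, dict) else v
                for k, v in d["materials"].items()
            }
        return cls(**d)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
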