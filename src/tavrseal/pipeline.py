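"""End-to-end orchestration: cohort -> deployment -> sealing -> metrics -> stats.

Each patient is processed independently (failures are caught, logged and
counted; summary reports aggregate the successful cases).  All randomness
derives from the single master seed in the configuration; per-patient
streams are spawned deterministically, so a rerun with the same
configuration reproduces byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, anatomy, frame as frame_mod, metrics, sealing, stats
from .config import PipelineConfig
from .deployment import ContactParams, TissueMaterial, deploy
from .sealing import pvl_surrogate

log = logging.getLogger("tavrseal")

COHORT_COLUMNS = [
    "patient_id", "morphology", "annulus_dmax", "annulus_dmin", "perimeter_diam",
    "area_diam", "calcium_volume", "device_size", "sizing_index", "depth",
]

SCREEN_CANDIDATES = [
    "age", "annulus_dmax", "annulus_dmin", "perimeter_diam", "calcium_volume",
    "sizing_index", "depth", "bav",
]


def materials_from_config(config: PipelineConfig) -> dict[str, TissueMaterial]:
    return {
        key: TissueMaterial(m.elastic_modulus, m.thickness, m.yield_stress)
        for key, m in config.materials.items()
    }


def contact_from_config(config: PipelineConfig) -> ContactParams:
    return ContactParams(
        friction_coefficient=config.friction_coefficient,
        max_ray_length=config.max_ray_length,
        residual_tol=config.residual_tol,
        max_iterations=config.max_iterations,
    )


@dataclass
class PatientResult:
    record: dict
    summary: sealing.SealingSummary | None = None
    grade: str | None = None
    measurements: list = field(default_factory=list)
    error: str | None = None


def run_patient(
    params: anatomy.RootParams, record: dict, config: PipelineConfig
) -> PatientResult:
    """Deploy and analyze a single synthetic patient."""
    try:
        root = anatomy.build_root(params)
        root = anatomy.place_calcium(root, params.calcium_deposits)
        fparams = frame_mod.FrameParams(size_label=int(record["device_size"]))
        dev = frame_mod.crimp(frame_mod.build_frame(fparams), config.crimp_diameter)
        state = deploy(
            dev, root, float(record["depth"]),
            contact_from_config(config), materials_from_config(config),
        )
        summary, _records = sealing.analyze(
            state, config.sealing_threshold, config.max_ray_length
        )
        grade = pvl_surrogate(summary, config.pvl_thresholds)
        measurements = metrics.measure(state.frame, config.level_fractions)
        return PatientResult(record, summary, grade, measurements)
    except Exception as exc:  # failures isolated per patient
        log.warning("patient %s failed: %s", record.get("patient_id"), exc)
        return PatientResult(record, error=str(exc))


def _frame_comparison(results: list[PatientResult], seed: int) -> dict:
    """Predicted-vs-'observed' frame dimensions across the cohort.

    Observed frames are synthetic perturbations of the predicted frames
    (small constant bias + seeded noise): a stand-in for post-operative CT.
    """
    predicted = [m for r in results if r.error is None for m in r.measurements]
    if len(predicted) < 3:
        return {}
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7919]))
    observed = metrics.perturb_measurements(predicted, bias=0.2, noise_sd=0.8, rng=rng)
    return metrics.compare_frames(predicted, observed)


def build_cohort_table(results: list[PatientResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        if res.error is not None:
            continue
        row = dict(res.record)
        row.update(res.summary.as_row())
        row["pvl_grade"] = res.grade
        row["bav"] = int(row["morphology"] != "TAV")
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full analysis; returns the manifest (with attached tables)."""
    t0 = time.time()
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    spec = anatomy.CohortSpec(
        n_tav=config.n_tav, n_bav0=config.n_bav0, n_bav1=config.n_bav1,
        seed=config.seed, sizing_target=config.sizing_target,
        mesh_resolution=config.mesh_resolution,
    )
    cohort = anatomy.sample_cohort(spec)
    results = [run_patient(p, rec, config) for p, rec in cohort]
    n_failed = sum(1 for r in results if r.error is not None)

    table = build_cohort_table(results)
    artifacts: dict[str, Path] = {}

    cohort_df = pd.DataFrame([rec for _, rec in cohort])
    artifacts["cohort"] = out / "cohort.csv"
    cohort_df[COHORT_COLUMNS].to_csv(artifacts["cohort"], index=False)

    artifacts["sealing"] = out / "sealing.csv"
    table.to_csv(artifacts["sealing"], index=False)

    reports: dict[str, object] = {}
    if len(table):
        seal_vars = [
            "apposed_area_lvot", "malapposed_area_lvot",
            "apposed_area_triangle", "malapposed_area_triangle",
            "apposed_area_leaflet", "malapposed_area_leaflet",
            "malapposition_total_pct", "malapposition_pct_lvot",
            "malapposition_pct_triangle", "malapposition_pct_leaflet",
            "apposition_contribution_pct_lvot",
            "apposition_contribution_pct_triangle",
            "apposition_contribution_pct_leaflet",
        ]
        group = stats.group_summary(table, seal_vars)
        reports["group_summary"] = group
        artifacts["group_summary"] = out / "group_summary.csv"
        group.to_csv(artifacts["group_summary"], index=False)

        # surrogate PVL grade vs malapposition (box-plot style summary)
        grade_rows = []
        for grade in sealing.PVL_GRADES:
            sub = table[table["pvl_grade"] == grade]["malapposition_total_pct"]
            grade_rows.append({
                "grade": grade, "n": len(sub),
                "mean": float(sub.mean()) if len(sub) else float("nan"),
                "sd": float(sub.std(ddof=1)) if len(sub) > 1 else float("nan"),
            })
        grades = pd.DataFrame(grade_rows)
        reports["grades"] = grades
        artifacts["grades"] = out / "pvl_grades.csv"
        grades.to_csv(artifacts["grades"], index=False)

        retained, pvals, reasons = stats.univariate_screen(
            table, "malapposition_pct_triangle", SCREEN_CANDIDATES
        )
        model = (
            stats.stepwise_lm(table, "malapposition_pct_triangle", retained)
            if retained else stats.StepwiseModel([], {}, {})
        )
        regression = {
            "screen_p_values": pvals,
            "screen_retained": retained,
            "screen_excluded": reasons,
            "stepwise_terms": model.terms,
            "stepwise_coefficients": model.coefficients,
            "stepwise_p_values": model.p_values,
        }
        reports["regression"] = regression
        artifacts["regression"] = out / "regression.json"
        artifacts["regression"].write_text(json.dumps(regression, indent=2))

    comparison = _frame_comparison(results, config.seed)
    reports["frame_comparison"] = comparison
    artifacts["frame_comparison"] = out / "frame_comparison.csv"
    pd.DataFrame(comparison).T.to_csv(artifacts["frame_comparison"])

    config_json = json.dumps(config.to_dict(), sort_keys=True)
    checksums = {
        name: hashlib.sha256(path.read_bytes()).hexdigest()
        for name, path in artifacts.items()
    }
    manifest = {
        "config_hash": hashlib.sha256(config_json.encode()).hexdigest(),
        "seed": config.seed,
        "version": __version__,
        "n_patients": len(results),
        "n_failed": n_failed,
        "checksums": checksums,
        "elapsed_s": round(time.time() - t0, 3),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    manifest["tables"] = {"cohort": cohort_df, "sealing": table, **reports}
    return manifest
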