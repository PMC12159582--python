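"""End-to-end orchestration: synthesize, reconstruct, quantify, validate.

One case runs: pathological surface -> shape-model native estimate ->
acetabular frame -> ray-cast defect extraction -> regional ADV/RDV/DD ->
validation against the case's ground truth.  A batch is the standard
synthetic suite (three defect-size classes, several subjects each), and
``batch_summary`` aggregates per-class means and standard deviations in the
regions-as-column-groups layout used for reporting regional bone loss.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import defect_reconstruction as dre
from . import regional_metrics as rm
from . import synthetic_anatomy as syn
from . import validation_metrics as vm
from .config import RunConfig
from .errors import StageError
from .shape_model import ShapeModel, build_shape_model


@dataclass
class CaseReport:
    """Everything measured for one case."""

    case_id: str
    size_class: str
    config_hash: str
    frame: dict
    defect_volume_cm3: float
    truth_volume_cm3: float
    regional: rm.RegionalMetrics
    validation: vm.ValidationReport
    timings_s: dict = field(default_factory=dict)
    failure: str | None = None

    def to_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "size_class": self.size_class,
            "config_hash": self.config_hash,
            "frame": self.frame,
            "defect_volume_cm3": self.defect_volume_cm3,
            "truth_volume_cm3": self.truth_volume_cm3,
            "regional": None if self.regional is None else self.regional.to_dict(),
            "validation": None if self.validation is None
            else self.validation.to_dict(),
            "timings_s": self.timings_s,
            "failure": self.failure,
        }


def build_suite_model(config: RunConfig, population_seed: int | None = None
                      ) -> ShapeModel:
    """Train the hemipelvis shape model on the synthetic population."""
    seed = config.seed + 9001 if population_seed is None else population_seed
    meshes, _ = syn.sample_population(config.n_training, seed=seed % (2**31 - 1))
    return build_shape_model(meshes)


def run_case(case: syn.SyntheticCase, model: ShapeModel, config: RunConfig,
             case_id: str = "case", size_class: str = "") -> CaseReport:
    """Reconstruct and quantify one pathological surface."""
    timings = {}
    t0 = time.perf_counter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = dre.reconstruct_defect(
            case.pathological_mesh, model,
            angular_spacing=config.angular_spacing_deg,
            n_modes=config.n_modes,
            cluster_min_size=config.cluster_min_size,
            min_interval_thickness=config.min_interval_thickness_mm,
            densify_step=config.densify_step_mm,
            boolean_pitch=config.boolean_pitch_mm,
            body_axes_hint=config.body_axes_hint,
            allow_scale=config.allow_scale,
            min_component_cm3=config.min_component_cm3)
    timings["reconstruct"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    regional = rm.compute_regional_metrics(
        res.defect.mesh, res.native_estimate, res.frame,
        ray_data=res.records.region_ray_data(), pitch=config.metrics_pitch_mm)
    timings["regional_metrics"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    validation = vm.validate_against_truth(res.defect.mesh, case,
                                           pitch=config.dice_pitch_mm)
    timings["validation"] = time.perf_counter() - t0

    return CaseReport(case_id=case_id, size_class=size_class,
                      config_hash=config.config_hash,
                      frame=res.frame.to_dict(),
                      defect_volume_cm3=res.defect.volume_cm3,
                      truth_volume_cm3=case.truth_defect_volume_cm3,
                      regional=regional, validation=validation,
                      timings_s=timings)


def run_pipeline(config: RunConfig | None = None, model: ShapeModel | None = None,
                 cases=None, progress=None):
    """Run the standard synthetic suite (or supplied cases) end to end.

    Per-case failures are recorded in the report (with the failing stage)
    and the batch continues.  Returns a list of CaseReport.
    """
    config = (config or RunConfig()).validate()
    if model is None:
        model = build_suite_model(config)
    if cases is None:
        cases = syn.standard_suite(config.seed, n_per_size=config.n_per_size,
                                   pitch=config.truth_pitch_mm,
                                   mesh_pitch=config.mesh_pitch_mm)
    reports = []
    for case_id, size_class, case in cases:
        if progress:
            progress(case_id)
        try:
            reports.append(run_case(case, model, config,
                                    case_id=case_id, size_class=size_class))
        except Exception as exc:
            stage = exc.stage if isinstance(exc, StageError) else "unknown"
            reports.append(CaseReport(
                case_id=case_id, size_class=size_class,
                config_hash=config.config_hash, frame=None,
                defect_volume_cm3=float("nan"),
                truth_volume_cm3=case.truth_defect_volume_cm3,
                regional=None, validation=None,
                failure=f"{stage}: {exc}"))
    return reports


def batch_summary(reports) -> pd.DataFrame:
    """Mean +- SD of ADV/RDV/DD per defect-size class, regions as columns.

    Layout mirrors regional bone-loss tables: one row per (class,
    statistic), column groups per region.
    """
    if not len(list(reports)):
        raise ValueError("batch_summary needs at least one report")
    rows = []
    for rep in reports:
        if rep.failure or rep.regional is None:
            continue
        for region in rep.regional.table.index:
            r = rep.regional.table.loc[region]
            rows.append({
                "case_id": rep.case_id, "class": rep.size_class,
                "region": region, "adv_cm3": r["adv_cm3"],
                "rdv_pct": r["rdv_pct"], "dd_mm": r["dd_mm"],
            })
    long = pd.DataFrame(rows)
    if long.empty:
        raise ValueError("no successful case reports to summarize")
    agg = long.groupby(["class", "region"])[["adv_cm3", "rdv_pct", "dd_mm"]] \
        .agg(["mean", "std"])
    wide = agg.unstack("region")
    wide.columns = [f"{region}_{metric}_{stat}"
                    for (metric, stat, region) in wide.columns]
    return wide.sort_index(axis=1)


def save_reports(reports, path):
    with open(path, "w") as fh:
        json.dump([r.to_dict() for r in reports], fh, indent=2, default=float)
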