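"""End-to-end orchestration: files in, tables out.

``run_pipeline`` wires the stages together — load, mask resampling,
ventricular metrics, TKE maps, global energetics, pathline tracing and
classification, per-component energetics, QC — and collects everything in a
:class:`ResultBundle` that can be written as CSV/JSON. Stage failures
propagate with the stage name attached; datasets failing QC are flagged in
the bundle, never silently dropped. All stages are deterministic for a fixed
configuration seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .component_energetics import compute_component_energetics
from .config import AnalysisConfig
from .datamodel import (
    FlowDataset,
    LVMaskSeries,
    VentricularMetrics,
    compute_ventricular_metrics,
    resample_mask_series,
)
from .energetics import EnergeticsSeries, compute_global_energetics
from .errors import DegenerateInputError, StageError
from .io import load_flow_dataset, load_mask_series
from .pathlines import PathlineSet, QCReport, classify, component_volumes, qc, trace_pathlines
from .turbulence import TurbulenceMaps, compute_turbulence_maps


@dataclass
class ResultBundle:
    config: AnalysisConfig
    metrics: VentricularMetrics | None
    turbulence: TurbulenceMaps
    energetics: EnergeticsSeries
    pathlines: PathlineSet
    labels: np.ndarray
    component_volumes: pd.DataFrame
    component_energetics: pd.DataFrame
    qc: QCReport
    notes: list[str]

    def series_frame(self) -> pd.DataFrame:
        e = self.energetics
        return pd.DataFrame(
            {
                "frame": np.arange(e.frame_times.size),
                "time_s": e.frame_times,
                "lv_volume_ml": e.lv_volume_ml,
                "mke_total_J": e.mke_total,
                "tke_total_J": e.tke_total,
                "mke_v_Jm3": e.mke_v,
                "tke_v_Jm3": e.tke_v,
            }
        )

    def summary_dict(self) -> dict:
        e = self.energetics
        out = {
            "e_frame": int(e.e_frame),
            "a_frame": int(e.a_frame),
            "diastole_frames": [int(f) for f in e.diastole],
            "mke_v_peak_e_Jm3": float(e.mke_v[e.e_frame]),
            "mke_v_peak_a_Jm3": float(e.mke_v[e.a_frame]),
            "tke_v_peak_e_Jm3": float(e.tke_v[e.e_frame]),
            "tke_v_peak_a_Jm3": float(e.tke_v[e.a_frame]),
            "mke_v_integral_Jsm3": float(e.mke_v_integral),
            "tke_v_integral_Jsm3": float(e.tke_v_integral),
            "tke_ke_peak_e": float(e.tke_ke_peak_e),
            "tke_ke_peak_a": float(e.tke_ke_peak_a),
            "tke_ke_integral": float(e.tke_ke_integral),
            "qc": {
                "np_percent": self.qc.np_percent,
                "inflow_volume_ml": self.qc.inflow_volume_ml,
                "outflow_volume_ml": self.qc.outflow_volume_ml,
                "io_discrepancy_percent": self.qc.io_discrepancy_percent,
                "excluded": self.qc.excluded,
                "reasons": self.qc.reasons,
            },
            "notes": self.notes,
            "config": self.config.to_dict(),
        }
        if self.metrics is not None:
            out["ventricular_metrics"] = dataclasses.asdict(self.metrics)
        return out

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write per-frame series, component tables, QC and summary JSON."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "series": out / "series.csv",
            "component_volumes": out / "component_volumes.csv",
            "component_energetics": out / "component_energetics.csv",
            "summary": out / "summary.json",
        }
        self.series_frame().to_csv(paths["series"], index=False, float_format="%.10g")
        self.component_volumes.to_csv(
            paths["component_volumes"], float_format="%.10g"
        )
        self.component_energetics.to_csv(
            paths["component_energetics"], float_format="%.10g"
        )
        paths["summary"].write_text(
            json.dumps(self.summary_dict(), indent=1, sort_keys=True)
        )
        return paths


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(name, exc) from exc
            return False

    return _Ctx()


def run_analysis(
    flow: FlowDataset,
    masks: LVMaskSeries,
    config: AnalysisConfig | None = None,
) -> ResultBundle:
    """Run the full in-memory analysis on a loaded dataset."""
    cfg = config or AnalysisConfig()
    notes: list[str] = []

    with _stage("mask_resampling"):
        masks = resample_mask_series(masks, flow)

    metrics = None
    with _stage("ventricular_metrics"):
        try:
            metrics = compute_ventricular_metrics(masks)
        except DegenerateInputError:
            notes.append(
                "volume curve is constant: ventricular metrics undefined; "
                "using the explicit ED/ES frames of the mask series"
            )
            if masks.ed_frame is None:
                raise

    with _stage("turbulence"):
        turb = compute_turbulence_maps(
            flow, rho=cfg.rho, median_filter=cfg.median_filter
        )

    with _stage("global_energetics"):
        energ = compute_global_energetics(
            flow, masks, turb, rho=cfg.rho,
            a_wave_fallback_fraction=cfg.a_wave_fallback_fraction,
        )

    with _stage("pathlines"):
        pset = trace_pathlines(flow, masks, substeps=cfg.rk4_substeps_per_frame)
        labels = classify(pset, masks, check_np_transits=cfg.check_np_transits)
        volumes = component_volumes(labels, pset.voxel_volume_ml)
        report = qc(
            labels, pset.voxel_volume_ml,
            np_threshold=cfg.np_exclusion_threshold,
            io_threshold=cfg.io_discrepancy_threshold,
        )
        if report.excluded:
            notes.append("QC exclusion gates triggered: " + "; ".join(report.reasons))

    with _stage("component_energetics"):
        comp = compute_component_energetics(
            pset, labels, turb.tke_density, flow, rho=cfg.rho,
            e_frame=energ.e_frame, a_frame=energ.a_frame,
            gaussian=cfg.gaussian_weight_sampling,
        )

    return ResultBundle(
        config=cfg,
        metrics=metrics,
        turbulence=turb,
        energetics=energ,
        pathlines=pset,
        labels=labels,
        component_volumes=volumes,
        component_energetics=comp,
        qc=report,
        notes=notes,
    )


def run_pipeline(
    config: AnalysisConfig,
    velocity_paths,
    sidecar_path,
    mask_path,
    mask_sidecar_path,
    magnitude_paths=None,
    out_dir: str | Path | None = None,
) -> ResultBundle:
    """File-based entry point: load, analyze, optionally write outputs."""
    with _stage("load"):
        flow = load_flow_dataset(velocity_paths, sidecar_path, magnitude_paths)
        masks = load_mask_series(mask_path, mask_sidecar_path)
    bundle = run_analysis(flow, masks, config)
    if out_dir is not None:
        with _stage("write"):
            bundle.write(out_dir)
    return bundle
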