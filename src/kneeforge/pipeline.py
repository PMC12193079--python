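"""End-to-end orchestration: segment -> fit -> landmarks -> design.

One subject's planning run takes hip/knee/ankle volumes (or pre-segmented
meshes) plus trained shape-model containers for both bones, executes every
stage, and emits a machine-readable report with per-stage status, metric
values, timings, the configuration hash and all seeds — a failure in one
stage is recorded and its downstream stages skipped, never raised through.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as kio
from ._mesh import SurfaceQuery
from .config import config_hash, default_config
from .fitting import FitResult, PartialObservation, fit_partial
from .implant import DesignResult, design_implants
from .metrics import dice, surface_distance
from .morpho import propagate_landmarks, refine_landmarks, secondary_parameters
from .segment import SegmentationResult, default_slice_predictor, segment_volume
from .ssm import ShapeModel, load_model
from .types import CTVolume, LandmarkSet


class ConfigurationError(ValueError):
    pass


@dataclass
class WorkflowReport:
    stages: dict = field(default_factory=dict)  # name -> {status, reason}
    metrics: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)
    config_hash: str = ""
    seeds: dict = field(default_factory=dict)

    def record(self, stage: str, status: str, reason: str = "") -> None:
        self.stages[stage] = {"status": status, "reason": reason}

    def ok(self, stage: str) -> bool:
        return self.stages.get(stage, {}).get("status") == "ok"

    def to_dict(self) -> dict:
        return {
            "stages": self.stages,
            "metrics": self.metrics,
            "timings_s": self.timings_s,
            "config_hash": self.config_hash,
            "seeds": self.seeds,
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))


@dataclass
class WorkflowOutputs:
    report: WorkflowReport
    segmentations: dict[str, SegmentationResult] = field(default_factory=dict)
    fits: dict[str, FitResult] = field(default_factory=dict)
    landmarks: dict[str, LandmarkSet] = field(default_factory=dict)
    design: DesignResult | None = None


def _as_model(m) -> ShapeModel:
    if isinstance(m, ShapeModel):
        return m
    p = Path(m)
    if not p.exists():
        raise ConfigurationError(f"model file not found: {p}")
    return load_model(p)


def _as_volume(v) -> CTVolume:
    return v if isinstance(v, CTVolume) else kio.load_volume(v)


def run_workflow(
    volumes: dict[str, CTVolume | str],
    models: dict[str, ShapeModel | str],
    config: dict | None = None,
    out_dir: str | Path | None = None,
) -> WorkflowOutputs:
    """Execute the full planning workflow for one subject.

    ``volumes`` maps acquisitions (hip/knee/ankle) to CT volumes or NIfTI
    paths; ``models`` maps bone kind to shape models or HDF5 paths.
    Missing model files raise a :class:`ConfigurationError` before any
    stage executes.
    """
    cfg = config or default_config()
    report = WorkflowReport(config_hash=config_hash(cfg))
    out = WorkflowOutputs(report=report)

    for kind in ("femur", "tibia"):
        if kind not in models:
            raise ConfigurationError(f"missing shape model for {kind}")
    models = {k: _as_model(m) for k, m in models.items()}
    volumes = {k: _as_volume(v) for k, v in volumes.items()}

    # 1. segmentation
    predictor = default_slice_predictor(cfg["segment"]["threshold_hu"])
    t0 = time.perf_counter()
    for acq, vol in volumes.items():
        try:
            res = segment_volume(
                vol,
                predictor,
                acq,
                smoothing_iters=cfg["segment"]["smoothing_iters"],
                prob_threshold=cfg["segment"]["prob_threshold"],
                min_area_mm2=cfg["segment"]["min_area_mm2"],
                marker_min_separation_mm=cfg["segment"]["marker_min_separation_mm"],
            )
            out.segmentations[acq] = res
            if res.empty:
                report.record(f"segment:{acq}", "failed", "empty mask")
            else:
                report.record(f"segment:{acq}", "ok")
        except Exception as e:  # recorded, not raised
            report.record(f"segment:{acq}", "failed", str(e))
    report.timings_s["segment"] = round(time.perf_counter() - t0, 3)

    # 2. assemble partial observations and fit
    pieces = {
        "femur": ("hip", "knee"),
        "tibia": ("knee", "ankle"),
    }
    t0 = time.perf_counter()
    for kind, (prox_acq, dist_acq) in pieces.items():
        sp = out.segmentations.get(prox_acq)
        sd = out.segmentations.get(dist_acq)
        prox = sp.meshes.get(kind) if sp else None
        dist = sd.meshes.get(kind) if sd else None
        if prox is None or dist is None:
            report.record(f"fit:{kind}", "skipped", "missing segmented extremity")
            continue
        # drop the flat caps the bounded fields of view leave on the meshes
        from .segment import strip_boundary_caps

        prox = strip_boundary_caps(prox, sp.mask)
        dist = strip_boundary_caps(dist, sd.mask)
        try:
            fcfg = cfg["fitting"]
            fit = fit_partial(
                models[kind],
                PartialObservation(prox, dist, kind),
                ridge=fcfg["ridge"],
                trim_frac=fcfg["trim_frac"],
                iters=fcfg["iters"],
                end_frac=fcfg["end_frac"],
                max_match_dist_mm=fcfg["max_match_dist_mm"],
                min_matches=fcfg["min_matches"],
            )
            out.fits[kind] = fit
            report.record(f"fit:{kind}", "ok")
            report.metrics[f"fit_residual_rmse_mm:{kind}"] = round(
                fit.residual_rmse, 4
            )
            report.metrics[f"fit_inlier_fraction:{kind}"] = round(
                fit.inlier_fraction, 4
            )
        except Exception as e:
            report.record(f"fit:{kind}", "failed", str(e))
    report.timings_s["fit"] = round(time.perf_counter() - t0, 3)

    # 3. landmarks (propagate from fit, refine on segmented surfaces)
    t0 = time.perf_counter()
    for kind in ("femur", "tibia"):
        if kind not in out.fits:
            report.record(f"landmarks:{kind}", "skipped", "no fit")
            continue
        try:
            lms = propagate_landmarks(out.fits[kind], cfg["morpho"])
            seg_meshes = [
                s.meshes[kind]
                for s in out.segmentations.values()
                if kind in s.meshes
            ]
            if seg_meshes:
                combined = seg_meshes[0]
                for m in seg_meshes[1:]:
                    combined = combined + m
                lms = refine_landmarks(
                    lms, combined, max_shift=cfg["morpho"]["max_shift_mm"]
                )
            out.landmarks[kind] = lms
            report.record(f"landmarks:{kind}", "ok")
        except Exception as e:
            report.record(f"landmarks:{kind}", "failed", str(e))
    report.timings_s["landmarks"] = round(time.perf_counter() - t0, 3)

    # 4. implant design
    t0 = time.perf_counter()
    if "femur" in out.landmarks and "tibia" in out.landmarks:
        try:
            sp = secondary_parameters(out.landmarks["femur"], out.landmarks["tibia"])
            design = design_implants(
                sp,
                out.fits["femur"].reconstructed,
                out.fits["tibia"].reconstructed,
                cfg["implant"],
                femoral_lms=out.landmarks["femur"],
            )
            out.design = design
            if design.failures:
                report.record(
                    "design", "failed", "; ".join(design.failures)
                )
            else:
                report.record("design", "ok")
            if design.femoral_coverage:
                report.metrics["coverage_rmse_mm:femur"] = round(
                    design.femoral_coverage.rmse, 4
                )
                report.metrics["coverage_hd_mm:femur"] = round(
                    design.femoral_coverage.hausdorff, 4
                )
            if design.tibial_coverage:
                report.metrics["coverage_rmse_mm:tibia"] = round(
                    design.tibial_coverage.rmse, 4
                )
                report.metrics["coverage_hd_mm:tibia"] = round(
                    design.tibial_coverage.hausdorff, 4
                )
        except Exception as e:
            report.record("design", "failed", str(e))
    else:
        report.record("design", "skipped", "missing landmarks")
    report.timings_s["design"] = round(time.perf_counter() - t0, 3)

    if out_dir is not None:
        _write_outputs(out, Path(out_dir))
    return out


def _write_outputs(out: WorkflowOutputs, d: Path) -> None:
    d.mkdir(parents=True, exist_ok=True)
    (d / "segmentation").mkdir(exist_ok=True)
    (d / "landmarks").mkdir(exist_ok=True)
    (d / "design").mkdir(exist_ok=True)
    for acq, seg in out.segmentations.items():
        kio.save_mask(seg.mask, d / "segmentation" / f"{acq}_labels.nii.gz")
        for kind, mesh in seg.meshes.items():
            kio.save_mesh(mesh, d / "segmentation" / f"{acq}_{kind}.stl")
    for kind, fit in out.fits.items():
        kio.save_mesh(fit.reconstructed, d / f"{kind}_reconstructed.stl")
        (d / f"{kind}_fit.json").write_text(
            json.dumps(
                {
                    "scale": fit.scale.tolist(),
                    "rotation": fit.rotation.tolist(),
                    "translation": fit.translation.tolist(),
                    "b": fit.b.tolist(),
                    "residual_rmse_mm": fit.residual_rmse,
                    "inlier_fraction": fit.inlier_fraction,
                },
                indent=1,
            )
        )
    for kind, lms in out.landmarks.items():
        lms.save_json(d / "landmarks" / f"{kind}.json")
    if out.design is not None:
        payload = {"failures": out.design.failures}
        if out.design.femoral is not None:
            payload["femoral"] = out.design.femoral.to_dict()
        if out.design.baseplate is not None:
            payload["baseplate"] = out.design.baseplate.to_dict()
            payload["keel"] = out.design.keel.to_dict()
        if out.design.insert is not None:
            payload["insert"] = out.design.insert.to_dict()
        (d / "design" / "design.json").write_text(
            json.dumps(payload, indent=1, sort_keys=True)
        )
    out.report.save_json(d / "report.json")


def evaluate_against_truth(
    run_dir: str | Path, truth_dir: str | Path
) -> WorkflowReport:
    """Append ground-truth metrics to a finished run's report.

    ``truth_dir`` holds the generator's reference data: per-acquisition
    label masks (``{acq}_labels.nii.gz``) and per-bone directories
    (``{kind}/mesh.stl``, ``{kind}/landmarks.json``).
    """
    run_dir = Path(run_dir)
    truth_dir = Path(truth_dir)
    report_path = run_dir / "report.json"
    if not report_path.exists():
        raise FileNotFoundError(f"no report.json under {run_dir}")
    payload = json.loads(report_path.read_text())
    report = WorkflowReport(**payload)

    ref_candidates = [truth_dir / f"{a}_labels.nii.gz" for a in ("hip", "knee", "ankle")]
    ref_candidates += [truth_dir / k / "mesh.stl" for k in ("femur", "tibia")]
    ref_candidates += [truth_dir / k / "landmarks.json" for k in ("femur", "tibia")]
    if not any(p.exists() for p in ref_candidates):
        raise FileNotFoundError(
            "truth directory holds no reference data; expected any of: "
            + ", ".join(str(p) for p in ref_candidates)
        )

    expected = []
    for acq in ("hip", "knee", "ankle"):
        pred = run_dir / "segmentation" / f"{acq}_labels.nii.gz"
        ref = truth_dir / f"{acq}_labels.nii.gz"
        if pred.exists() and ref.exists():
            pm, rm = kio.load_mask(pred), kio.load_mask(ref)
            for label, kind in ((1, "femur"), (2, "tibia")):
                if (rm.labels == label).any():
                    report.metrics[f"dice:{acq}:{kind}"] = round(
                        dice(pm, rm, label), 4
                    )
        elif ref.exists():
            expected.append(str(pred))
    found_any = False
    for kind in ("femur", "tibia"):
        mesh_p = run_dir / f"{kind}_reconstructed.stl"
        truth_mesh = truth_dir / kind / "mesh.stl"
        if mesh_p.exists() and truth_mesh.exists():
            found_any = True
            rep = surface_distance(kio.load_mesh(mesh_p), kio.load_mesh(truth_mesh))
            report.metrics[f"reconstruction_rmse_mm:{kind}"] = round(rep.rmse, 4)
            report.metrics[f"reconstruction_hd_mm:{kind}"] = round(rep.hausdorff, 4)
        elif truth_mesh.exists():
            expected.append(str(mesh_p))
        lm_p = run_dir / "landmarks" / f"{kind}.json"
        truth_lm = truth_dir / kind / "landmarks.json"
        if lm_p.exists() and truth_lm.exists():
            found_any = True
            pred = LandmarkSet.load_json(lm_p)
            ref = LandmarkSet.load_json(truth_lm)
            common = [n for n in pred.names if n in ref]
            if common:
                err = np.mean(
                    [
                        np.linalg.norm(pred[n].point - ref[n].point)
                        for n in common
                    ]
                )
                report.metrics[f"landmark_mean_error_mm:{kind}"] = round(
                    float(err), 4
                )
        elif truth_lm.exists():
            expected.append(str(lm_p))
    if not found_any and not report.metrics:
        raise FileNotFoundError(
            "no comparable artifacts; expected files: " + ", ".join(expected)
        )
    if expected:
        report.metrics["missing_artifacts"] = expected
    report.save_json(report_path)
    return report
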