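"""Anatomical landmark extraction and morphometric parameters.

Landmarks are propagated from a fitted shape model (whose shape vector
carries the landmark coordinates alongside the surface) and then refined
against the actually segmented surface.  The refinement is weighted by a
per-landmark osteophyte-risk weight: landmarks that sit on joint margins
prone to osteophyte growth (epicondyles, wear points) keep most of the
model's prediction, while landmarks on reliable cortical surface are
pulled onto the segmented mesh.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from ._mesh import SurfaceQuery
from .config import DEFAULTS
from .fitting import FitResult
from .types import InvalidArgumentError, LandmarkSet


class MissingLandmarksError(KeyError):
    def __init__(self, names: list[str]):
        super().__init__(f"missing required landmarks: {', '.join(names)}")
        self.names = names


def default_risk_weights(names, cfg: dict | None = None) -> dict[str, float]:
    m = cfg or DEFAULTS["morpho"]
    prone = set(m["osteophyte_prone_names"])
    return {
        n: m["osteophyte_prone_weight"] if n in prone else m["default_risk_weight"]
        for n in names
    }


def propagate_landmarks(fit: FitResult, cfg: dict | None = None) -> LandmarkSet:
    """Landmarks of the deformed model in patient space, with risk weights."""
    lms = fit.landmarks
    return lms.with_weights(default_risk_weights(lms.names, cfg))


def refine_landmarks(
    landmarks: LandmarkSet,
    segmented_mesh: trimesh.Trimesh,
    max_shift: float = 5.0,
    query: SurfaceQuery | None = None,
) -> LandmarkSet:
    """Adjust landmarks toward the segmented surface, weighted by risk.

    Each point moves by ``w * clamp(proj(p) - p, max_shift)`` where proj
    is the closest point on the mesh and w the landmark's risk weight
    (w = 0: keep the model prediction, w = 1: full projection).
    """
    if len(segmented_mesh.vertices) == 0:
        raise InvalidArgumentError("segmented mesh is empty")
    if max_shift <= 0:
        raise InvalidArgumentError("max_shift must be positive")
    q = query or SurfaceQuery(segmented_mesh)
    pts = landmarks.points
    proj, _ = q.closest(pts)
    step = proj - pts
    norm = np.linalg.norm(step, axis=1, keepdims=True)
    over = norm > max_shift
    step = np.where(over, step * (max_shift / np.maximum(norm, 1e-12)), step)
    new = pts + landmarks.weights[:, None] * step
    return landmarks.with_points(new)


@dataclass
class SecondaryParams:
    """Derived axes, sizes and reference points for resection planning."""

    femoral_mech_axis: tuple[np.ndarray, np.ndarray]  # head centre -> knee centre
    tibial_mech_axis: tuple[np.ndarray, np.ndarray]  # knee centre -> ankle centre
    knee_center: np.ndarray
    ap_direction: np.ndarray  # unit, posterior -> anterior
    ap_size: float  # mm
    ap_size_medial: float  # mm, per-condyle
    ap_size_lateral: float  # mm
    ml_width: float  # mm, epicondyle to epicondyle
    ml_direction: np.ndarray  # unit, medial -> lateral
    condylar_line: tuple[np.ndarray, np.ndarray]  # tibial condyle centres
    sulcus_angle_deg: float
    distal_reference_point: np.ndarray  # most distal condyle point
    posterior_reference_point: np.ndarray  # most posterior condyle point
    wear_reference_point: np.ndarray  # higher tibial wear point

    def __post_init__(self) -> None:
        for a, b in (self.femoral_mech_axis, self.tibial_mech_axis):
            if np.linalg.norm(np.asarray(b) - np.asarray(a)) < 1e-9:
                raise InvalidArgumentError("degenerate mechanical axis")
        if not 0.0 < self.sulcus_angle_deg < 180.0:
            raise InvalidArgumentError("sulcus angle outside (0, 180)")

    def to_dict(self) -> dict:
        return {
            "femoral_mech_axis_mm": [p.tolist() for p in self.femoral_mech_axis],
            "tibial_mech_axis_mm": [p.tolist() for p in self.tibial_mech_axis],
            "knee_center_mm": self.knee_center.tolist(),
            "ap_direction": self.ap_direction.tolist(),
            "ap_size_mm": self.ap_size,
            "ap_size_medial_mm": self.ap_size_medial,
            "ap_size_lateral_mm": self.ap_size_lateral,
            "ml_width_mm": self.ml_width,
            "ml_direction": self.ml_direction.tolist(),
            "condylar_line_mm": [p.tolist() for p in self.condylar_line],
            "sulcus_angle_deg": self.sulcus_angle_deg,
        }


_REQ_FEMORAL = [
    "Femoral Head Center", "Top Notch", "Top Groove", "AP Sizing Point",
    "Medial Posterior", "Lateral Posterior", "Medial Anterior",
    "Lateral Anterior", "Medial Distal", "Lateral Distal",
    "Medial Epicondyle", "Lateral Epicondyle",
]
_REQ_TIBIAL = [
    "Knee Center", "Ankle Joint Center", "Medial Wear Point",
    "Lateral Wear Point", "Medial Condyle Center", "Lateral Condyle Center",
]


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise InvalidArgumentError("zero-length direction")
    return v / n


def secondary_parameters(
    femoral_lms: LandmarkSet, tibial_lms: LandmarkSet
) -> SecondaryParams:
    """Compute the derived parameter set from the primary landmarks.

    Femoral mechanical axis: femoral head centre to the femoral knee
    centre (Top Notch derived); tibial: tibial knee centre to the ankle
    joint centre.  The AP direction is the head-to-notch-orthogonalized
    direction from the posterior condyle midpoint to the AP sizing point,
    so every quantity is invariant under global rigid motion.
    """
    missing = [n for n in _REQ_FEMORAL if n not in femoral_lms]
    missing += [n for n in _REQ_TIBIAL if n not in tibial_lms]
    if missing:
        raise MissingLandmarksError(missing)

    f = {n: femoral_lms[n].point for n in _REQ_FEMORAL}
    t = {n: tibial_lms[n].point for n in _REQ_TIBIAL}

    knee_center_f = f["Top Notch"]
    fem_axis = (f["Femoral Head Center"], knee_center_f)
    tib_axis = (t["Knee Center"], t["Ankle Joint Center"])
    axis_dir = _unit(knee_center_f - f["Femoral Head Center"])  # points distal

    mid_post = 0.5 * (f["Medial Posterior"] + f["Lateral Posterior"])
    ap_raw = f["AP Sizing Point"] - mid_post
    ap_dir = _unit(ap_raw - (ap_raw @ axis_dir) * axis_dir)
    ap_size = float(ap_raw @ ap_dir)
    ap_med = float((f["Medial Anterior"] - f["Medial Posterior"]) @ ap_dir)
    ap_lat = float((f["Lateral Anterior"] - f["Lateral Posterior"]) @ ap_dir)

    ml_vec = f["Lateral Epicondyle"] - f["Medial Epicondyle"]
    ml_width = float(np.linalg.norm(ml_vec))
    ml_dir = _unit(ml_vec)

    cline = (t["Medial Condyle Center"], t["Lateral Condyle Center"])
    if np.linalg.norm(cline[1] - cline[0]) < 1e-9:
        raise InvalidArgumentError("coincident condyle centres")

    va = f["Medial Anterior"] - f["Top Groove"]
    vb = f["Lateral Anterior"] - f["Top Groove"]
    cosang = np.clip(
        va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb)), -1.0, 1.0
    )
    sulcus = float(np.degrees(np.arccos(cosang)))

    # most distal = largest projection along the distal-pointing axis
    dist_ref = max(
        (f["Medial Distal"], f["Lateral Distal"]), key=lambda p: p @ axis_dir
    )
    post_ref = min(
        (f["Medial Posterior"], f["Lateral Posterior"]), key=lambda p: p @ ap_dir
    )
    prox_dir = _unit(t["Knee Center"] - t["Ankle Joint Center"])
    wear_ref = max(
        (t["Medial Wear Point"], t["Lateral Wear Point"]),
        key=lambda p: p @ prox_dir,
    )
    return SecondaryParams(
        femoral_mech_axis=fem_axis,
        tibial_mech_axis=tib_axis,
        knee_center=knee_center_f,
        ap_direction=ap_dir,
        ap_size=ap_size,
        ap_size_medial=ap_med,
        ap_size_lateral=ap_lat,
        ml_width=ml_width,
        ml_direction=ml_dir,
        condylar_line=cline,
        sulcus_angle_deg=sulcus,
        distal_reference_point=dist_ref,
        posterior_reference_point=post_ref,
        wear_reference_point=wear_ref,
    )


def condylar_line_error(
    pred_edge_pts: tuple[np.ndarray, np.ndarray],
    ref_edge_pts: tuple[np.ndarray, np.ndarray],
) -> float:
    """Angular error (deg) of the condylar line from plateau edge points.

    Each argument is (medial edge points, lateral edge points); a condyle
    centre is the centroid of its >= 3 edge points, and the error is the
    angle between the predicted and reference centre-to-centre lines,
    folded into [0, 90] (the line is undirected).
    """
    def centre_line(pair):
        med, lat = (np.asarray(p, dtype=float).reshape(-1, 3) for p in pair)
        if len(med) < 3 or len(lat) < 3:
            raise InvalidArgumentError("need >= 3 edge points per plateau")
        v = lat.mean(axis=0) - med.mean(axis=0)
        if np.linalg.norm(v) < 1e-9:
            raise InvalidArgumentError("coincident condyle centres")
        return v / np.linalg.norm(v)

    a = centre_line(pred_edge_pts)
    b = centre_line(ref_edge_pts)
    ang = float(np.degrees(np.arccos(np.clip(abs(a @ b), -1.0, 1.0))))
    return ang
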