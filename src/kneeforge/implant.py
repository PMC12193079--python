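"""Medial-pivot implant parameterization at desk scale.

The implant is represented in 2.5D: planar resection contours plus
parametric profiles.  The femoral component's posterior geometry follows
the medial-pivot concept — each condyle's sagittal curvature is a single
circle whose radius is a fixed fraction of that condyle's antero-posterior
size, placed tangent to the distal and posterior resection planes; the
tibial baseplate is an inward offset of the resected plateau contour with
an extra posterior retreat (to avoid muscle impingement); the insert
excavates the medial pivot sphere and carries a lowly congruent convex
lateral surface.

Coverage is scored as over/under-hang: contour-to-contour distances
outside configured ignore zones (posterior tibial retreat, femoral
intercondylar notch, femoral anterior proximal flange).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from shapely.geometry import Polygon, Point, box

from .config import DEFAULTS
from .metrics import DistanceReport, contour_distance
from .morpho import SecondaryParams
from .types import DesignFailureError, InvalidArgumentError, PlanarContour


class EmptySectionError(ValueError):
    pass


@dataclass
class Plane:
    point: np.ndarray  # (3,) mm
    normal: np.ndarray  # unit
    e1: np.ndarray  # in-plane, medial -> lateral sense
    e2: np.ndarray  # in-plane, posterior -> anterior sense

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float).reshape(3)
        self.normal = np.asarray(self.normal, dtype=float).reshape(3)
        n = np.linalg.norm(self.normal)
        if abs(n - 1.0) > 1e-8:
            raise InvalidArgumentError("plane normal must be unit length")


def _plane_frame(point, normal, ml_dir, ap_dir) -> Plane:
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    e1 = ml_dir - (ml_dir @ normal) * normal
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    if e2 @ ap_dir < 0:  # anterior must be +e2
        e1, e2 = -e1, -e2
    return Plane(point, normal, e1, e2)


@dataclass
class ResectionPlan:
    femoral_distal: Plane
    femoral_posterior: Plane
    tibial_proximal: Plane
    distal_cut_mm: float
    posterior_cut_mm: float
    tibial_cut_mm: float
    tibial_slope_deg: float


def _rotate_about(v: np.ndarray, axis: np.ndarray, deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    th = np.radians(deg)
    return (
        v * np.cos(th)
        + np.cross(axis, v) * np.sin(th)
        + axis * (axis @ v) * (1.0 - np.cos(th))
    )


def plan_resections(sp: SecondaryParams, config: dict | None = None) -> ResectionPlan:
    """Resection planes from the secondary parameters.

    femoral_distal: perpendicular to the femoral mechanical axis,
    ``distal_cut`` proximal to the more distal condyle point;
    femoral_posterior: perpendicular to the AP direction, ``posterior_cut``
    anterior to the most posterior condyle point; tibial_proximal:
    perpendicular to the tibial mechanical axis tilted posteriorly by the
    slope, ``tibial_cut`` below the higher wear point.
    """
    cfg = config or DEFAULTS["implant"]
    axis_dir = sp.femoral_mech_axis[1] - sp.femoral_mech_axis[0]
    axis_dir = axis_dir / np.linalg.norm(axis_dir)  # points distal
    fd_point = sp.distal_reference_point - cfg["distal_cut_mm"] * axis_dir
    fd = _plane_frame(fd_point, -axis_dir, sp.ml_direction, sp.ap_direction)

    fp_point = sp.posterior_reference_point + cfg["posterior_cut_mm"] * sp.ap_direction
    fp = _plane_frame(fp_point, sp.ap_direction, sp.ml_direction, -axis_dir)

    prox_dir = sp.tibial_mech_axis[0] - sp.tibial_mech_axis[1]
    prox_dir = prox_dir / np.linalg.norm(prox_dir)
    n_tib = _rotate_about(prox_dir, sp.ml_direction, cfg["tibial_slope_deg"])
    tp_point = sp.wear_reference_point - cfg["tibial_cut_mm"] * prox_dir
    # anchor the frame origin on the tibial mechanical axis
    a0, a1 = sp.tibial_mech_axis
    axis_v = a1 - a0
    denom = axis_v @ n_tib
    if abs(denom) > 1e-9:
        lam = ((tp_point - a0) @ n_tib) / denom
        tp_point = a0 + lam * axis_v
    tp = _plane_frame(tp_point, n_tib, sp.ml_direction, sp.ap_direction)
    return ResectionPlan(
        femoral_distal=fd,
        femoral_posterior=fp,
        tibial_proximal=tp,
        distal_cut_mm=cfg["distal_cut_mm"],
        posterior_cut_mm=cfg["posterior_cut_mm"],
        tibial_cut_mm=cfg["tibial_cut_mm"],
        tibial_slope_deg=cfg["tibial_slope_deg"],
    )


def section_contour(mesh: trimesh.Trimesh, plane: Plane) -> PlanarContour:
    """Largest closed mesh-plane intersection loop, in the plane frame."""
    try:
        path = mesh.section(plane_origin=plane.point, plane_normal=plane.normal)
    except Exception:
        path = None
    if path is None:
        raise EmptySectionError("plane does not intersect the mesh")
    best = None
    best_area = 0.0
    for loop in path.discrete:
        if len(loop) < 3:
            continue
        pts2 = (loop - plane.point) @ np.column_stack([plane.e1, plane.e2])
        if np.linalg.norm(pts2[0] - pts2[-1]) > 1e-6:
            continue  # open fragment
        x, y = pts2[:-1, 0], pts2[:-1, 1]
        area = abs(
            0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
        )
        if area > best_area:
            best_area = area
            best = pts2[:-1]
    if best is None or len(best) < 8:
        raise EmptySectionError("no closed section loop found")
    return PlanarContour(
        plane.point, np.vstack([plane.e1, plane.e2]), best
    ).canonicalized()


def pivot_radius(ap_size: float, ratio: float = 0.33) -> float:
    """Medial-pivot sphere radius as a linear law of the AP size."""
    if ap_size <= 0 or ratio <= 0:
        raise InvalidArgumentError("ap_size and ratio must be positive")
    return ratio * ap_size


# ---------------------------------------------------------------------------
# component designs


@dataclass
class KeelSpec:
    position: np.ndarray  # (2,) in the tibial plane frame
    stem_length_mm: float

    def to_dict(self) -> dict:
        return {
            "position_mm": np.asarray(self.position).tolist(),
            "stem_length_mm": self.stem_length_mm,
        }


def _poly_of(contour: PlanarContour) -> Polygon:
    poly = Polygon(contour.points)
    if not poly.is_valid:
        poly = poly.buffer(0)
    return poly


def _contour_from_poly(poly: Polygon, ref: PlanarContour) -> PlanarContour:
    if poly.is_empty or poly.geom_type != "Polygon":
        raise DesignFailureError("offset collapsed the contour")
    pts = np.asarray(poly.exterior.coords)[:-1]
    if len(pts) < 8:
        raise DesignFailureError("offset left a degenerate contour")
    return PlanarContour(ref.origin, ref.axes, pts).canonicalized()


def design_tibial_baseplate(
    resected_contour: PlanarContour, config: dict | None = None
) -> tuple[PlanarContour, KeelSpec]:
    """Baseplate contour: rim offset + posterior retreat + fillets.

    The plateau contour is inset by ``rim_offset`` everywhere and by an
    additional ``posterior_retreat`` over the posterior
    ``posterior_extent_frac`` of the AP extent; the step between the two
    offsets is filleted.  The keel sits between the contour centroid and
    the mechanical-axis piercing point (the frame origin); stem length
    scales with the plateau's ML extent.
    """
    cfg = config or DEFAULTS["implant"]
    poly = _poly_of(resected_contour)
    if poly.is_empty:
        raise DesignFailureError("empty resected contour")
    rim = cfg["rim_offset_mm"]
    retreat = cfg["posterior_retreat_mm"]
    fil = cfg["fillet_radius_mm"]
    xmin, ymin, xmax, ymax = poly.bounds
    p1 = poly.buffer(-rim, join_style=1)
    inner = p1
    if retreat > 0:
        p2 = poly.buffer(-(rim + retreat), join_style=1)
        if p2.is_empty or p1.is_empty:
            raise DesignFailureError("offset collapsed the contour")
        y_thr = ymin + cfg["posterior_extent_frac"] * (ymax - ymin)
        anterior = box(xmin - 10, y_thr, xmax + 10, ymax + 10)
        inner = p1.intersection(anterior).union(p2)
        # fillet the offset step: morphological closing with the fillet radius
        inner = inner.buffer(fil, join_style=1).buffer(-fil, join_style=1)
    if inner.is_empty or inner.geom_type != "Polygon":
        raise DesignFailureError("offset collapsed the contour")
    out = _contour_from_poly(inner, resected_contour)

    centroid = np.asarray(inner.centroid.coords[0])
    keel_pos = 0.6 * centroid  # pulled toward the diaphysis (frame origin)
    if not inner.contains(Point(*keel_pos)):
        keel_pos = centroid
    stem = cfg["stem_scale"] * (xmax - xmin)
    return out, KeelSpec(position=keel_pos, stem_length_mm=float(stem))


@dataclass
class CondyleArc:
    radius_mm: float
    center: np.ndarray  # (2,) sagittal frame: (ap, proximal) from the cut corner
    tangency_residual_mm: float
    rollback_cut_deg: float


@dataclass
class ImplantProfile:
    """Femoral component parameterization (2.5D)."""

    medial_arc: CondyleArc
    lateral_arc: CondyleArc
    sulcus_angle_deg: float
    anterior_flange_points: np.ndarray  # (3, 3): medial/groove/lateral anchors
    contour: PlanarContour  # outline in the distal resection plane
    ml_extent_mm: float
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "medial_radius_mm": self.medial_arc.radius_mm,
            "lateral_radius_mm": self.lateral_arc.radius_mm,
            "medial_center_mm": self.medial_arc.center.tolist(),
            "lateral_center_mm": self.lateral_arc.center.tolist(),
            "rollback_cut_deg": self.medial_arc.rollback_cut_deg,
            "sulcus_angle_deg": self.sulcus_angle_deg,
            "ml_extent_mm": self.ml_extent_mm,
            "contour": self.contour.to_dict(),
            "warnings": list(self.warnings),
        }


def design_femoral_profile(
    sp: SecondaryParams,
    distal_contour: PlanarContour,
    posterior_contour: PlanarContour,
    config: dict | None = None,
    femoral_lms=None,
) -> ImplantProfile:
    """Condylar arcs tangent to both resections + clamped flange outline.

    Each condyle's sagittal circle has radius ``pivot_ratio x that
    condyle's AP size`` and is placed tangent to the distal and posterior
    resection planes (centre at (r, r) from their intersection corner, in
    the sagittal frame).  The component outline in the distal plane is the
    resected contour inset by a small rim so no overhang can occur by
    construction.
    """
    cfg = config or DEFAULTS["implant"]
    r_med = pivot_radius(sp.ap_size_medial, cfg["pivot_ratio"])
    r_lat = pivot_radius(sp.ap_size_lateral, cfg["pivot_ratio"])
    warnings: list[str] = []

    # feasibility: the arc must fit between the two cuts
    half_ap = 0.5 * min(sp.ap_size_medial, sp.ap_size_lateral)
    if r_med > sp.ap_size_medial or r_lat > sp.ap_size_lateral:
        raise DesignFailureError("pivot radius inconsistent with condyle size")
    if r_med < 1.0 or r_lat < 1.0:
        raise DesignFailureError("pivot radius degenerate")
    if half_ap < 2.0:
        warnings.append("very small condyle AP size")

    rollback = cfg["rollback_angle_deg"]
    med = CondyleArc(r_med, np.array([r_med, r_med]), 0.0, rollback)
    lat = CondyleArc(r_lat, np.array([r_lat, r_lat]), 0.0, rollback)

    poly = _poly_of(distal_contour)
    inner = poly.buffer(-cfg["femoral_rim_offset_mm"], join_style=1)
    if inner.is_empty or inner.geom_type != "Polygon":
        raise DesignFailureError("femoral rim offset collapsed the contour")
    contour = _contour_from_poly(inner, distal_contour)

    if femoral_lms is not None:
        flange = np.stack(
            [
                femoral_lms["Medial Anterior"].point,
                femoral_lms["Top Groove"].point,
                femoral_lms["Lateral Anterior"].point,
            ]
        )
    else:
        flange = np.zeros((3, 3))
    xmin, _, xmax, _ = inner.bounds
    return ImplantProfile(
        medial_arc=med,
        lateral_arc=lat,
        sulcus_angle_deg=sp.sulcus_angle_deg,
        anterior_flange_points=flange,
        contour=contour,
        ml_extent_mm=float(xmax - xmin),
        warnings=warnings,
    )


@dataclass
class InsertProfile:
    socket_radius_mm: float  # medial, congruent with the pivot sphere
    lateral_radius_mm: float  # convex, lowly congruent
    anterior_cut_y_mm: float  # in the tibial plane frame
    outline: PlanarContour
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "socket_radius_mm": self.socket_radius_mm,
            "lateral_radius_mm": self.lateral_radius_mm,
            "anterior_cut_y_mm": self.anterior_cut_y_mm,
            "outline": self.outline.to_dict(),
            "warnings": list(self.warnings),
        }


def design_insert_profile(
    femoral: ImplantProfile,
    baseplate: PlanarContour,
    config: dict | None = None,
) -> InsertProfile:
    """Insert: medial socket, lateral convex surface, anterior cut."""
    cfg = config or DEFAULTS["implant"]
    clearance = cfg["clearance_mm"]
    if clearance < 0:
        raise InvalidArgumentError("clearance must be >= 0")
    congruence = cfg["congruence_factor"]
    warnings = []
    if congruence <= 1.0:
        warnings.append("fully congruent lateral surface (congruence <= 1)")
    poly = _poly_of(baseplate)
    inner = poly.buffer(-1.0, join_style=1)
    if inner.is_empty or inner.geom_type != "Polygon":
        raise DesignFailureError("insert outline collapsed")
    outline = _contour_from_poly(inner, baseplate)
    _, ymin, _, ymax = poly.bounds
    return InsertProfile(
        socket_radius_mm=femoral.medial_arc.radius_mm + clearance,
        lateral_radius_mm=congruence * femoral.lateral_arc.radius_mm,
        anterior_cut_y_mm=float(ymin + cfg["anterior_frac"] * (ymax - ymin)),
        outline=outline,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# ignore zones and coverage


@dataclass
class IgnoreZones:
    """Named arc-length sectors excluded from over/under-hang scoring."""

    sectors: list[tuple[str, float, float]]

    def __post_init__(self) -> None:
        spans = []
        for name, a, b in self.sectors:
            if not (0.0 <= a < 1.0 and 0.0 <= b <= 1.0):
                raise InvalidArgumentError(f"zone {name} outside [0, 1)")
            spans.append((a, b))
        spans.sort()
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            if a2 < b1:
                raise InvalidArgumentError("ignore zones overlap")

    @classmethod
    def for_bone(cls, bone_kind: str, config: dict | None = None) -> "IgnoreZones":
        cfg = config or DEFAULTS["implant"]
        key = "femoral" if bone_kind == "femur" else "tibial"
        return cls([(n, float(a), float(b)) for n, a, b in cfg["zones"][key]])


def coverage_report(
    bone_contour: PlanarContour,
    implant_contour: PlanarContour,
    zones: IgnoreZones | None = None,
) -> DistanceReport:
    """Unsigned over/under-hang distances outside the ignore zones."""
    sectors = zones.sectors if zones is not None else None
    return contour_distance(bone_contour, implant_contour, ignore_zones=sectors)


# ---------------------------------------------------------------------------
# whole-knee convenience


@dataclass
class DesignResult:
    plan: ResectionPlan | None = None
    femoral: ImplantProfile | None = None
    baseplate: PlanarContour | None = None
    keel: KeelSpec | None = None
    insert: InsertProfile | None = None
    femoral_bone_contour: PlanarContour | None = None
    tibial_bone_contour: PlanarContour | None = None
    femoral_coverage: DistanceReport | None = None
    tibial_coverage: DistanceReport | None = None
    failures: list[str] = field(default_factory=list)

    @property
    def success(self) -> bool:
        return not self.failures


def design_implants(
    sp: SecondaryParams,
    femur_mesh: trimesh.Trimesh,
    tibia_mesh: trimesh.Trimesh,
    config: dict | None = None,
    femoral_lms=None,
) -> DesignResult:
    """Plan resections, design all components, and score coverage.

    Design failures are recorded in ``failures`` (never silently
    swallowed) so a cohort run can report its success rate.
    """
    cfg = config or DEFAULTS["implant"]
    out = DesignResult()
    out.plan = plan_resections(sp, cfg)
    try:
        distal_c = section_contour(femur_mesh, out.plan.femoral_distal)
        posterior_c = section_contour(femur_mesh, out.plan.femoral_posterior)
        out.femoral_bone_contour = distal_c
        out.femoral = design_femoral_profile(
            sp, distal_c, posterior_c, cfg, femoral_lms=femoral_lms
        )
        out.femoral_coverage = coverage_report(
            distal_c, out.femoral.contour, IgnoreZones.for_bone("femur", cfg)
        )
    except (EmptySectionError, DesignFailureError) as e:
        out.failures.append(f"femoral: {e}")
    try:
        tib_c = section_contour(tibia_mesh, out.plan.tibial_proximal)
        out.tibial_bone_contour = tib_c
        out.baseplate, out.keel = design_tibial_baseplate(tib_c, cfg)
        out.tibial_coverage = coverage_report(
            tib_c, out.baseplate, IgnoreZones.for_bone("tibia", cfg)
        )
    except (EmptySectionError, DesignFailureError) as e:
        out.failures.append(f"tibial: {e}")
    if out.femoral is not None and out.baseplate is not None:
        try:
            out.insert = design_insert_profile(out.femoral, out.baseplate, cfg)
        except (DesignFailureError, InvalidArgumentError) as e:
            out.failures.append(f"insert: {e}")
    return out
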