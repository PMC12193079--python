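"""Evaluation metrics: Dice overlap, surface RMSE/Hausdorff, contour distances.

Surface distances are measured from source vertices to the exact
triangulated target surface.  Symmetric variants (the default for every
reported number) average the RMSE of both directions and take the maximum
of both Hausdorff distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from ._mesh import SurfaceQuery
from .types import InvalidArgumentError, LabelMask, PlanarContour


@dataclass
class DistanceReport:
    rmse: float  # mm
    hausdorff: float  # mm
    distances: np.ndarray  # per-sample distances (mm), both directions if symmetric
    direction: str  # "a_to_b" | "symmetric"

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float).ravel()


def dice(mask_a: LabelMask | np.ndarray, mask_b: LabelMask | np.ndarray,
         label: int = 1) -> float:
    """Dice coefficient 2|A∩B| / (|A|+|B|) for one label value."""
    a = mask_a.labels if isinstance(mask_a, LabelMask) else np.asarray(mask_a)
    b = mask_b.labels if isinstance(mask_b, LabelMask) else np.asarray(mask_b)
    if a.shape != b.shape:
        raise InvalidArgumentError("mask grids differ in shape")
    a = a == label
    b = b == label
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.logical_and(a, b).sum()) / denom


def _directed(points: np.ndarray, target: trimesh.Trimesh | SurfaceQuery) -> np.ndarray:
    q = target if isinstance(target, SurfaceQuery) else SurfaceQuery(target)
    _, d = q.closest(points)
    return d


def surface_distance(
    mesh_a: trimesh.Trimesh,
    mesh_b: trimesh.Trimesh,
    symmetric: bool = True,
    query_a: SurfaceQuery | None = None,
    query_b: SurfaceQuery | None = None,
) -> DistanceReport:
    """Vertex-to-surface distance report between two meshes.

    RMSE uses the source mesh's vertices as samples (no area weighting).
    Pre-built :class:`SurfaceQuery` objects may be passed to amortize
    repeated comparisons against the same mesh.
    """
    if len(mesh_a.vertices) == 0 or len(mesh_b.vertices) == 0:
        raise InvalidArgumentError("meshes must be non-empty")
    d_ab = _directed(mesh_a.vertices.view(np.ndarray), query_b or mesh_b)
    if not symmetric:
        return DistanceReport(
            rmse=float(np.sqrt(np.mean(d_ab**2))),
            hausdorff=float(d_ab.max()),
            distances=d_ab,
            direction="a_to_b",
        )
    d_ba = _directed(mesh_b.vertices.view(np.ndarray), query_a or mesh_a)
    rmse = 0.5 * (float(np.sqrt(np.mean(d_ab**2))) + float(np.sqrt(np.mean(d_ba**2))))
    return DistanceReport(
        rmse=rmse,
        hausdorff=float(max(d_ab.max(), d_ba.max())),
        distances=np.concatenate([d_ab, d_ba]),
        direction="symmetric",
    )


# ---------------------------------------------------------------------------
# planar contours


def _resample(points: np.ndarray, step: float) -> tuple[np.ndarray, np.ndarray]:
    """Sample a closed polyline at <= step arc intervals.

    Returns (samples (n, 2), normalized arc-length position of each sample).
    """
    closed = np.vstack([points, points[:1]])
    seg = np.diff(closed, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    total = seglen.sum()
    if total <= 0:
        raise InvalidArgumentError("degenerate contour")
    n = max(int(np.ceil(total / step)), 8)
    s = np.linspace(0.0, total, n, endpoint=False)
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seglen) - 1)
    frac = (s - cum[idx]) / np.maximum(seglen[idx], 1e-12)
    samples = closed[idx] + frac[:, None] * seg[idx]
    return samples, s / total


def _point_to_polyline(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Min distance from each point to a closed polyline (vectorized)."""
    closed = np.vstack([poly, poly[:1]])
    a = closed[:-1]
    ab = closed[1:] - a
    denom = np.maximum(np.einsum("ij,ij->i", ab, ab), 1e-18)
    # (n_pts, n_seg) projections
    ap = points[:, None, :] - a[None, :, :]
    t = np.clip(np.einsum("pij,ij->pi", ap, ab) / denom[None, :], 0.0, 1.0)
    closest = a[None, :, :] + t[:, :, None] * ab[None, :, :]
    d = np.linalg.norm(points[:, None, :] - closest, axis=2)
    return d.min(axis=1)


def _in_zone(pos: np.ndarray, zones) -> np.ndarray:
    mask = np.zeros(len(pos), dtype=bool)
    for zone in zones or []:
        start, end = float(zone[-2]), float(zone[-1])
        if start <= end:
            mask |= (pos >= start) & (pos <= end)
        else:  # wrap-around sector
            mask |= (pos >= start) | (pos <= end)
    return mask


def contour_distance(
    contour_a: PlanarContour,
    contour_b: PlanarContour,
    ignore_zones=None,
    symmetric: bool = True,
    step_mm: float = 0.5,
) -> DistanceReport:
    """Closest distances between two closed coplanar contours.

    Contours are canonicalized (counter-clockwise, starting at the most
    anterior point) and sampled at <= ``step_mm`` arc intervals; samples
    whose normalized arc position falls inside any ignore zone (sectors
    ``(name, start, end)`` in [0, 1)) are excluded on both contours.
    """
    if abs(abs(float(contour_a.normal @ contour_b.normal)) - 1.0) > 1e-6:
        raise InvalidArgumentError("contours must be coplanar")
    a = contour_a.canonicalized()
    b = contour_b.canonicalized()
    # express b in a's frame
    b3 = b.to_3d()
    b2 = (b3 - a.origin) @ a.axes.T

    sa, pos_a = _resample(a.points, step_mm)
    sb, pos_b = _resample(b2, step_mm)
    keep_a = ~_in_zone(pos_a, ignore_zones)
    keep_b = ~_in_zone(pos_b, ignore_zones)
    if not keep_a.any() or (symmetric and not keep_b.any()):
        raise InvalidArgumentError("contour empty after ignore-zone exclusion")
    d_ab = _point_to_polyline(sa[keep_a], b2)
    if not symmetric:
        return DistanceReport(
            rmse=float(np.sqrt(np.mean(d_ab**2))),
            hausdorff=float(d_ab.max()),
            distances=d_ab,
            direction="a_to_b",
        )
    d_ba = _point_to_polyline(sb[keep_b], a.points)
    rmse = 0.5 * (float(np.sqrt(np.mean(d_ab**2))) + float(np.sqrt(np.mean(d_ba**2))))
    return DistanceReport(
        rmse=rmse,
        hausdorff=float(max(d_ab.max(), d_ba.max())),
        distances=np.concatenate([d_ab, d_ba]),
        direction="symmetric",
    )
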