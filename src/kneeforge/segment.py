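"""Slice-wise segmentation with pluggable predictors, post-processing, meshing.

A *slice predictor* maps one transverse 2D intensity slice to a foreground
probability slice in [0, 1].  In the clinic this would be a trained 2D
network; here a pluggable callable contract keeps the bespoke logic
(morphological cleanup, watershed bone separation, marching-cubes meshing)
independent of how the per-slice prediction is produced, and a simple
intensity-threshold predictor serves the synthetic pseudo-CT volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure, morphology, segmentation
from skimage.feature import peak_local_max

from ._mesh import taubin_smooth
from .types import CTVolume, InvalidArgumentError, LabelMask, make_mesh

SlicePredictor = Callable[[np.ndarray], np.ndarray]

ACQUISITIONS = ("hip", "knee", "ankle")


def default_slice_predictor(threshold_hu: float = 200.0) -> SlicePredictor:
    """Binary intensity-threshold predictor (1 where HU >= threshold)."""
    if not np.isfinite(threshold_hu):
        raise InvalidArgumentError("threshold must be finite")

    def predict(slice_2d: np.ndarray) -> np.ndarray:
        return (np.asarray(slice_2d) >= threshold_hu).astype(float)

    return predict


@dataclass
class SegmentationResult:
    mask: LabelMask
    meshes: dict[str, trimesh.Trimesh]
    empty_slices: np.ndarray  # bool per transverse slice
    ambiguous_boundary: bool  # watershed split was needed
    empty: bool = False
    flags: list[str] = field(default_factory=list)


def _clean_slice(binary: np.ndarray, min_area_px: float) -> np.ndarray:
    """Opening then closing (3x3), drop small 2D components."""
    se = np.ones((3, 3), dtype=bool)
    out = morphology.closing(morphology.opening(binary, se), se)
    if min_area_px >= 1 and out.any():
        comp, ncomp = ndimage.label(out)
        sizes = ndimage.sum_labels(out, comp, index=np.arange(1, ncomp + 1))
        small = np.flatnonzero(sizes < min_area_px) + 1
        if len(small):
            out[np.isin(comp, small)] = False
    return out


def _watershed_split(component: np.ndarray, spacing: np.ndarray,
                     min_sep_mm: float) -> np.ndarray | None:
    """Split one connected component into two by marker-based watershed.

    Markers are the two largest maxima of the interior distance transform
    with at least ``min_sep_mm`` separation; ties break on larger distance
    value, then lower voxel index.  Returns a label grid {0,1,2} or None
    when no two admissible markers exist.
    """
    dist = ndimage.distance_transform_edt(component, sampling=spacing)
    min_sep_vox = max(1, int(np.floor(min_sep_mm / float(spacing.min()))))
    peaks = peak_local_max(
        dist, min_distance=min_sep_vox, exclude_border=False, labels=component
    )
    if len(peaks) < 2:
        return None
    vals = dist[tuple(peaks.T)]
    order = np.lexsort((np.arange(len(peaks)), -vals))
    peaks = peaks[order[:2]]
    markers = np.zeros_like(component, dtype=np.int32)
    markers[tuple(peaks[0])] = 1
    markers[tuple(peaks[1])] = 2
    return segmentation.watershed(-dist, markers=markers, mask=component)


def postprocess_masks(
    prob_slices: np.ndarray,
    spacing: np.ndarray | float,
    acquisition: str = "knee",
    origin: np.ndarray | None = None,
    prob_threshold: float = 0.5,
    min_area_mm2: float = 30.0,
    marker_min_separation_mm: float = 10.0,
) -> tuple[LabelMask, dict]:
    """Clean per-slice predictions and separate femur from tibia.

    ``prob_slices`` is the (x, y, z) probability grid; slices are fixed-z
    planes.  Per slice: binarize, open/close with a 3x3 element, drop 2D
    components below ``min_area_mm2``.  In 3D the two largest components
    are kept; a single merged component in a knee acquisition is split by
    marker-based watershed on the inverted interior-distance map.  Label 1
    goes to the more proximal (higher z centroid) component of a knee
    volume, otherwise by acquisition (hip -> femur, ankle -> tibia).
    """
    if acquisition not in ACQUISITIONS:
        raise InvalidArgumentError(f"acquisition must be one of {ACQUISITIONS}")
    prob = np.asarray(prob_slices, dtype=float)
    if prob.ndim != 3:
        raise InvalidArgumentError("expected a 3D stack of slices")
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float).ravel(), (3,)).copy()
    if origin is None:
        origin = np.zeros(3)
    px_area = spacing[0] * spacing[1]
    min_area_px = min_area_mm2 / px_area

    binary = np.zeros(prob.shape, dtype=bool)
    empty_slices = np.zeros(prob.shape[2], dtype=bool)
    for k in range(prob.shape[2]):
        sl = prob[:, :, k] >= prob_threshold
        if not sl.any():
            empty_slices[k] = True
            continue
        binary[:, :, k] = _clean_slice(sl, min_area_px)
        empty_slices[k] = not binary[:, :, k].any()

    info = {"empty_slices": empty_slices, "ambiguous_boundary": False,
            "empty": False, "flags": []}
    labels = np.zeros(prob.shape, dtype=np.int16)
    if not binary.any():
        info["empty"] = True
        info["flags"].append("empty-mask")
        return LabelMask(labels, spacing, origin), info

    comp, ncomp = ndimage.label(binary)
    sizes = ndimage.sum_labels(binary, comp, index=np.arange(1, ncomp + 1))
    order = np.argsort(-sizes)[:2] + 1

    parts: list[np.ndarray] = []
    if acquisition == "knee" and len(order) == 1:
        split = _watershed_split(comp == order[0], spacing, marker_min_separation_mm)
        if split is not None:
            info["ambiguous_boundary"] = True
            info["flags"].append("watershed-split")
            parts = [split == 1, split == 2]
        else:
            parts = [comp == order[0]]
    elif acquisition == "knee" and len(order) == 2:
        parts = [comp == order[0], comp == order[1]]
    else:
        parts = [comp == order[0]]

    if acquisition == "knee" and len(parts) == 2:
        cz = [np.mean(np.nonzero(p)[2]) for p in parts]
        femur = parts[int(np.argmax(cz))]
        tibia = parts[int(np.argmin(cz))]
        labels[femur] = 1
        labels[tibia] = 2
    elif acquisition == "hip":
        labels[parts[0]] = 1
    elif acquisition == "ankle":
        labels[parts[0]] = 2
    else:  # knee volume where only one bone is visible
        labels[parts[0]] = 1
        info["flags"].append("single-component-knee")
    return LabelMask(labels, spacing, origin), info


def mask_to_mesh(label_mask: LabelMask, label: int,
                 smoothing_iters: int = 10) -> trimesh.Trimesh:
    """Marching cubes at iso-level 0.5 followed by Taubin smoothing.

    Taubin's lambda/mu scheme (lambda = 0.5, mu = -0.53) smooths without the
    volume shrinkage of plain Laplacian smoothing.
    """
    indicator = (label_mask.labels == label).astype(np.float32)
    if not indicator.any():
        raise KeyError(f"label {label} absent from mask")
    padded = np.pad(indicator, 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5)
    verts = (verts - 1.0) * label_mask.spacing + label_mask.origin
    mesh = make_mesh(verts, faces)
    if mesh.volume < 0:
        mesh.invert()
    return taubin_smooth(mesh, smoothing_iters)


def strip_boundary_caps(
    mesh: trimesh.Trimesh, mask: LabelMask, margin_vox: float = 1.5
) -> trimesh.Trimesh:
    """Remove the flat caps a bounded field of view leaves on a bone mesh.

    Marching cubes closes a bone that extends beyond the acquisition
    window with a planar cap at the volume's axial boundary; those faces
    are not bone surface and must not take part in model fitting.  Faces
    whose centroid lies within ``margin_vox`` voxels of either axial
    boundary are dropped (the mesh may become open there, which partial
    fitting permits).
    """
    v = mesh.vertices.view(np.ndarray)
    f = mesh.faces.view(np.ndarray)
    zc = v[f].mean(axis=1)[:, 2]
    z_lo = mask.origin[2] + margin_vox * mask.spacing[2]
    z_hi = mask.origin[2] + (mask.shape[2] - 1 - margin_vox) * mask.spacing[2]
    keep = (zc > z_lo) & (zc < z_hi)
    if keep.all():
        return mesh
    kept = f[keep]
    used = np.unique(kept)
    remap = np.full(len(v), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return make_mesh(v[used], remap[kept])


def segment_volume(
    volume: CTVolume,
    predictor: SlicePredictor,
    acquisition: str,
    smoothing_iters: int = 10,
    **postprocess_kw,
) -> SegmentationResult:
    """Predict per transverse slice, post-process, and mesh each bone."""
    if acquisition not in ACQUISITIONS:
        raise InvalidArgumentError(f"acquisition must be one of {ACQUISITIONS}")
    prob = np.zeros(volume.shape, dtype=float)
    for k in range(volume.shape[2]):
        out = np.asarray(predictor(volume.intensities[:, :, k]), dtype=float)
        if out.shape != volume.shape[:2]:
            raise InvalidArgumentError("predictor changed the slice shape")
        if out.min() < -1e-9 or out.max() > 1 + 1e-9:
            raise InvalidArgumentError("predictor output outside [0, 1]")
        prob[:, :, k] = out
    mask, info = postprocess_masks(
        prob, volume.spacing, acquisition, origin=volume.origin, **postprocess_kw
    )
    meshes: dict[str, trimesh.Trimesh] = {}
    for label, kind in ((1, "femur"), (2, "tibia")):
        if (mask.labels == label).any():
            meshes[kind] = mask_to_mesh(mask, label, smoothing_iters)
    return SegmentationResult(
        mask=mask,
        meshes=meshes,
        empty_slices=info["empty_slices"],
        ambiguous_boundary=info["ambiguous_boundary"],
        empty=info["empty"],
        flags=info["flags"],
    )
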