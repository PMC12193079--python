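"""File I/O: meshes (STL/PLY), volumes (NIfTI), landmarks (JSON).

Meshes are loaded with ``process=False`` so vertex order — and therefore
any point correspondence — survives a round trip.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import trimesh

from .types import CTVolume, GroundTruthBone, LabelMask, LandmarkSet, make_mesh


def save_mesh(mesh: trimesh.Trimesh, path: str | Path) -> None:
    mesh.export(str(path))


def load_mesh(path: str | Path) -> trimesh.Trimesh:
    m = trimesh.load(str(path), process=False, force="mesh")
    return make_mesh(m.vertices, m.faces)


def _affine(spacing: np.ndarray, origin: np.ndarray) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def save_volume(vol: CTVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(
        np.asarray(vol.intensities, dtype=np.float32),
        _affine(vol.spacing, vol.origin),
    )
    nib.save(img, str(path))


def load_volume(path: str | Path) -> CTVolume:
    img = nib.load(str(path))
    aff = img.affine
    return CTVolume(
        np.asarray(img.dataobj, dtype=np.float32),
        np.abs(np.diag(aff)[:3]),
        aff[:3, 3],
    )


def save_mask(mask: LabelMask, path: str | Path) -> None:
    img = nib.Nifti1Image(
        np.asarray(mask.labels, dtype=np.int16), _affine(mask.spacing, mask.origin)
    )
    nib.save(img, str(path))


def load_mask(path: str | Path) -> LabelMask:
    img = nib.load(str(path))
    aff = img.affine
    return LabelMask(
        np.asarray(img.dataobj, dtype=np.int16),
        np.abs(np.diag(aff)[:3]),
        aff[:3, 3],
    )


def save_bone(bone: GroundTruthBone, directory: str | Path) -> None:
    """Ground-truth bone as mesh + landmarks + metadata in one directory."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    # PLY keeps the indexed vertex list intact; STL would explode the
    # mesh into a triangle soup and destroy the vertex correspondence
    save_mesh(bone.mesh, d / "mesh.ply")
    bone.landmarks.save_json(d / "landmarks.json")
    meta = {
        "bone_kind": bone.bone_kind,
        "side": bone.side,
        "seed": bone.seed,
        "scale": bone.scale,
        "pathological": bone.pathological,
        "latent": np.asarray(bone.latent).tolist(),
    }
    if bone.landmark_vertex_ids is not None:
        meta["landmark_vertex_ids"] = bone.landmark_vertex_ids.tolist()
    (d / "meta.json").write_text(json.dumps(meta, indent=1))


def load_bone(directory: str | Path) -> GroundTruthBone:
    d = Path(directory)
    meta = json.loads((d / "meta.json").read_text())
    ids = meta.get("landmark_vertex_ids")
    return GroundTruthBone(
        mesh=load_mesh(d / "mesh.ply"),
        landmarks=LandmarkSet.load_json(d / "landmarks.json"),
        latent=np.asarray(meta["latent"], dtype=float),
        bone_kind=meta["bone_kind"],
        side=meta["side"],
        seed=int(meta["seed"]),
        scale=float(meta.get("scale", 1.0)),
        pathological=bool(meta.get("pathological", False)),
        landmark_vertex_ids=None if ids is None else np.asarray(ids, dtype=np.int64),
    )
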