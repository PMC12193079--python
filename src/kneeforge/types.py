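"""Core value types shared across the planning pipeline.

All geometry lives in a right-handed patient frame in millimetres:
+z proximal, +y anterior, +x lateral (for a right bone).  Triangle meshes
are :class:`trimesh.Trimesh` objects built with ``process=False`` so that
vertex order and count are preserved exactly — point correspondence across
a shape population is expressed purely through shared vertex indexing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import trimesh


class InvalidArgumentError(ValueError):
    """An argument violates an operation's precondition."""


class DesignFailureError(RuntimeError):
    """An implant design step produced degenerate geometry.

    Recorded (not silently swallowed) by the orchestration layer so that a
    design success rate can be reported.
    """


def make_mesh(vertices: np.ndarray, faces: np.ndarray) -> trimesh.Trimesh:
    """Build a mesh without any vertex merging or reordering."""
    return trimesh.Trimesh(
        vertices=np.asarray(vertices, dtype=float),
        faces=np.asarray(faces, dtype=np.int64),
        process=False,
    )


@dataclass(frozen=True)
class Landmark:
    point: np.ndarray  # (3,) mm
    weight: float = 1.0  # osteophyte-risk weight in [0, 1]

    def __post_init__(self) -> None:
        p = np.asarray(self.point, dtype=float).reshape(3)
        object.__setattr__(self, "point", p)
        if not np.all(np.isfinite(p)):
            raise InvalidArgumentError("landmark coordinates must be finite")
        if not 0.0 <= self.weight <= 1.0:
            raise InvalidArgumentError("risk weight must lie in [0, 1]")


class LandmarkSet:
    """Ordered map of named 3D anatomical points with risk weights."""

    def __init__(self, landmarks: Mapping[str, Landmark] | None = None):
        self._d: dict[str, Landmark] = dict(landmarks or {})

    @classmethod
    def from_points(
        cls,
        names: Sequence[str],
        points: np.ndarray,
        weights: Sequence[float] | None = None,
    ) -> "LandmarkSet":
        points = np.asarray(points, dtype=float).reshape(-1, 3)
        if len(names) != len(points):
            raise InvalidArgumentError("names and points length mismatch")
        if len(set(names)) != len(names):
            raise InvalidArgumentError("landmark names must be unique")
        if weights is None:
            weights = [1.0] * len(names)
        return cls({n: Landmark(p, w) for n, p, w in zip(names, points, weights)})

    @property
    def names(self) -> list[str]:
        return list(self._d)

    @property
    def points(self) -> np.ndarray:
        if not self._d:
            return np.zeros((0, 3))
        return np.stack([lm.point for lm in self._d.values()])

    @property
    def weights(self) -> np.ndarray:
        return np.array([lm.weight for lm in self._d.values()], dtype=float)

    def __len__(self) -> int:
        return len(self._d)

    def __iter__(self) -> Iterator[str]:
        return iter(self._d)

    def __contains__(self, name: str) -> bool:
        return name in self._d

    def __getitem__(self, name: str) -> Landmark:
        return self._d[name]

    def with_points(self, points: np.ndarray) -> "LandmarkSet":
        """Same names/weights with replaced coordinates (order preserved)."""
        points = np.asarray(points, dtype=float).reshape(-1, 3)
        if len(points) != len(self._d):
            raise InvalidArgumentError("point count mismatch")
        return LandmarkSet(
            {n: Landmark(p, lm.weight) for (n, lm), p in zip(self._d.items(), points)}
        )

    def with_weights(self, weights: Mapping[str, float]) -> "LandmarkSet":
        return LandmarkSet(
            {
                n: Landmark(lm.point, float(weights.get(n, lm.weight)))
                for n, lm in self._d.items()
            }
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray,
                    scale: np.ndarray | float = 1.0) -> "LandmarkSet":
        """Apply ``x -> R (s * x) + t`` to every point."""
        s = np.asarray(scale, dtype=float)
        pts = (np.asarray(rotation) @ (self.points * s).T).T + np.asarray(translation)
        return self.with_points(pts)

    def to_dict(self) -> dict:
        return {
            n: {"point": lm.point.tolist(), "weight": lm.weight}
            for n, lm in self._d.items()
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "LandmarkSet":
        out = {}
        for n, v in d.items():
            if isinstance(v, Mapping):
                out[n] = Landmark(np.asarray(v["point"]), float(v.get("weight", 1.0)))
            else:  # bare [x, y, z]
                out[n] = Landmark(np.asarray(v))
        return cls(out)

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load_json(cls, path: str | Path) -> "LandmarkSet":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class CTVolume:
    """Pseudo-CT intensity grid (HU-like), axis order (x, y, z)."""

    intensities: np.ndarray
    spacing: np.ndarray  # (3,) mm/voxel
    origin: np.ndarray  # (3,) mm, world position of voxel (0, 0, 0) centre

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.intensities.ndim != 3 or self.intensities.size == 0:
            raise InvalidArgumentError("intensity grid must be non-empty 3D")
        if np.any(self.spacing <= 0):
            raise InvalidArgumentError("voxel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape


@dataclass
class LabelMask:
    """Integer segmentation grid: 0 background, 1 femur, 2 tibia."""

    labels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.labels.ndim != 3 or self.labels.size == 0:
            raise InvalidArgumentError("label grid must be non-empty 3D")
        if np.any(self.spacing <= 0):
            raise InvalidArgumentError("voxel spacing must be positive")
        bad = set(np.unique(self.labels)) - {0, 1, 2}
        if bad:
            raise InvalidArgumentError(f"label values outside {{0,1,2}}: {sorted(bad)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape


@dataclass
class GroundTruthBone:
    """A synthetic bone with exact landmarks and generative coefficients."""

    mesh: trimesh.Trimesh
    landmarks: LandmarkSet
    latent: np.ndarray  # generative coefficients, unitless
    bone_kind: str  # "femur" | "tibia"
    side: str = "right"
    seed: int = 0
    pathological: bool = False
    scale: float = 1.0  # recorded global isotropic jitter
    landmark_vertex_ids: np.ndarray | None = None  # anchors on the template grid

    def copy_with(self, **kw) -> "GroundTruthBone":
        return replace(self, **kw)


@dataclass
class PlanarContour:
    """Closed polyline in the 2D frame of a resection plane.

    ``points`` are 2D, in mm, without a repeated closing vertex (closure is
    implicit).  ``origin`` and the two in-plane unit ``axes`` recover 3D
    coordinates as ``origin + u * axes[0] + v * axes[1]``.
    """

    origin: np.ndarray  # (3,)
    axes: np.ndarray  # (2, 3) orthonormal in-plane directions
    points: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float).reshape(2, 3)
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if len(pts) >= 2 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        self.points = pts
        if len(self.points) < 8:
            raise InvalidArgumentError("contour needs at least 8 points")
        g = self.axes @ self.axes.T
        if not np.allclose(g, np.eye(2), atol=1e-8):
            raise InvalidArgumentError("plane axes must be orthonormal")

    @property
    def normal(self) -> np.ndarray:
        return np.cross(self.axes[0], self.axes[1])

    def signed_area(self) -> float:
        x, y = self.points[:, 0], self.points[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def perimeter(self) -> float:
        d = np.roll(self.points, -1, axis=0) - self.points
        return float(np.linalg.norm(d, axis=1).sum())

    def canonicalized(self) -> "PlanarContour":
        """Counter-clockwise orientation, starting at the most anterior point.

        The second in-plane axis is the anterior direction by convention, so
        normalized arc length 0 sits anteriorly and 0.5 posteriorly — the
        parameterization used for ignore-zone sectors.
        """
        pts = self.points
        if self.signed_area() < 0:
            pts = pts[::-1]
        start = int(np.argmax(pts[:, 1]))
        pts = np.roll(pts, -start, axis=0)
        return PlanarContour(self.origin, self.axes, pts)

    def to_3d(self) -> np.ndarray:
        return self.origin + self.points @ self.axes

    def to_dict(self) -> dict:
        return {
            "origin_mm": self.origin.tolist(),
            "axes": self.axes.tolist(),
            "points_mm": self.points.tolist(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PlanarContour":
        return cls(np.asarray(d["origin_mm"]), np.asarray(d["axes"]),
                   np.asarray(d["points_mm"]))
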