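"""Low-level mesh numerics: exact closest-point queries and smoothing.

The closest-point query combines a KD-tree over triangle centroids (for
candidate pruning) with the exact point-to-triangle projection, which keeps
distance fields exact to machine precision wherever the true nearest
triangle is among the candidates.  Candidates include the k nearest
centroids plus every triangle incident to the nearest mesh vertex, which is
ample for the smooth, quasi-uniform meshes used here.
"""

from __future__ import annotations

import numpy as np
import trimesh
from scipy import sparse
from scipy.spatial import cKDTree


def closest_point_on_triangles(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Exact closest point on each triangle for each paired query point.

    points: (n, 3); triangles: (n, 3, 3).  Vectorized version of the
    classic barycentric-region case analysis.
    """
    a = triangles[:, 0]
    b = triangles[:, 1]
    c = triangles[:, 2]
    p = points

    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)

    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)

    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    # vertex A
    m = (d1 <= 0) & (d2 <= 0)
    out[m] = a[m]
    done |= m
    # vertex B
    m = ~done & (d3 >= 0) & (d4 <= d3)
    out[m] = b[m]
    done |= m
    # edge AB
    vc = d1 * d4 - d3 * d2
    m = ~done & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = d1 / (d1 - d3)
    out[m] = a[m] + v[m, None] * ab[m]
    done |= m
    # vertex C
    m = ~done & (d6 >= 0) & (d5 <= d6)
    out[m] = c[m]
    done |= m
    # edge AC
    vb = d5 * d2 - d1 * d6
    m = ~done & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = d2 / (d2 - d6)
    out[m] = a[m] + w[m, None] * ac[m]
    done |= m
    # edge BC
    va = d3 * d6 - d5 * d4
    m = ~done & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
    out[m] = b[m] + w[m, None] * (c[m] - b[m])
    done |= m
    # interior
    m = ~done
    denom = va + vb + vc
    with np.errstate(invalid="ignore", divide="ignore"):
        v = vb / denom
        w = vc / denom
    out[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return out


class SurfaceQuery:
    """Reusable closest-point query structure for one triangle mesh."""

    def __init__(self, mesh: trimesh.Trimesh, k: int = 12,
                 vertex_faces: np.ndarray | None = None):
        self.mesh = mesh
        self.triangles = mesh.triangles.view(np.ndarray)
        self.centroids = self.triangles.mean(axis=1)
        self.k = min(k, len(self.triangles))
        self._tri_tree = cKDTree(self.centroids)
        self._vert_tree = cKDTree(mesh.vertices.view(np.ndarray))
        if vertex_faces is None:
            # vertex -> incident faces, padded with repeats; topology-only,
            # so callers fitting a deforming mesh may pass it precomputed
            vf = mesh.vertex_faces  # (V, max_deg), -1 padded
            vertex_faces = np.where(vf >= 0, vf, vf.max(axis=1, keepdims=True))
        self._vertex_faces = vertex_faces

    @property
    def vertex_faces_padded(self) -> np.ndarray:
        return self._vertex_faces

    def closest(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (closest surface points, distances) for query points."""
        cp, d, _ = self.closest_full(points)
        return cp, d

    def closest_full(
        self, points: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (closest points, distances, triangle indices)."""
        points = np.asarray(points, dtype=float).reshape(-1, 3)
        _, cand = self._tri_tree.query(points, k=self.k)
        cand = np.atleast_2d(cand)
        _, nv = self._vert_tree.query(points)
        cand = np.hstack([cand, self._vertex_faces[nv]])

        n, m = cand.shape
        flat_pts = np.repeat(points, m, axis=0)
        flat_tri = self.triangles[cand.ravel()]
        cp = closest_point_on_triangles(flat_pts, flat_tri)
        d2 = np.einsum("ij,ij->i", flat_pts - cp, flat_pts - cp).reshape(n, m)
        best = np.argmin(d2, axis=1)
        idx = np.arange(n)
        closest = cp.reshape(n, m, 3)[idx, best]
        return closest, np.sqrt(d2[idx, best]), cand[idx, best]


def uniform_laplacian(mesh: trimesh.Trimesh) -> sparse.csr_matrix:
    """Row-normalized graph Laplacian L = I - D^-1 A over mesh edges."""
    e = mesh.edges_unique
    n = len(mesh.vertices)
    rows = np.concatenate([e[:, 0], e[:, 1]])
    cols = np.concatenate([e[:, 1], e[:, 0]])
    adj = sparse.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n)).tocsr()
    deg = np.asarray(adj.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    dinv = sparse.diags(1.0 / deg)
    return (sparse.eye(n) - dinv @ adj).tocsr()


def taubin_smooth(mesh: trimesh.Trimesh, iterations: int,
                  lam: float = 0.5, mu: float = -0.53) -> trimesh.Trimesh:
    """Taubin λ/μ smoothing (volume-preserving, unlike plain Laplacian)."""
    if iterations <= 0:
        return mesh.copy()
    lap = uniform_laplacian(mesh)
    v = mesh.vertices.view(np.ndarray).copy()
    for _ in range(iterations):
        v = v - lam * (lap @ v)
        v = v - mu * (lap @ v)
    out = mesh.copy()
    out.vertices = v
    return out
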