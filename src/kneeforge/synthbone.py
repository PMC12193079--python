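"""Parametric femur/tibia-like bone generator with exact ground truth.

The generator stands in for a clinical CT training population: it produces
watertight right-side bone surfaces with named anatomical landmarks,
smooth inter-subject shape variation, optional osteophyte bumps at the
joint margins, partial (cropped) fields of view, and pseudo-CT
rasterizations.

Geometry model
--------------
Each template bone is a generalized cylinder: rings of vertices around a
straight longitudinal axis (+z proximal), with radius ``r(z, theta)`` =
(shaft profile + smooth Gaussian bumps for condyles, plateaus, head,
trochanter, malleolus) tapered to poles by a dome factor at both ends.
Landmarks are anchored to template vertices, so they sit exactly on the
surface and are carried exactly by any vertex displacement field.

Population model
----------------
Members share the template topology (exact correspondence).  Each member
is the template displaced by a linear combination of ``k_latent`` fixed
smooth polynomial vector fields (orthonormalized over template vertices so
a unit coefficient produces 1 mm RMS surface displacement), with
coefficients drawn i.i.d. N(0, sd^2), plus a recorded global isotropic
scale jitter.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
import trimesh
from scipy import ndimage
from shapely import contains_xy
from shapely.geometry import Polygon

from .types import (
    CTVolume,
    GroundTruthBone,
    InvalidArgumentError,
    LabelMask,
    LandmarkSet,
    make_mesh,
)

BONE_KINDS = ("femur", "tibia")

FEMORAL_LANDMARK_NAMES = [
    "AP Sizing Point",
    "Lateral Anterior",
    "Lateral Distal",
    "Lateral Epicondyle",
    "Lateral Posterior",
    "Medial Anterior",
    "Medial Distal",
    "Medial Epicondyle",
    "Medial Posterior",
    "Top Groove",
    "Top Notch",
    "Femoral Head Center",
]

TIBIAL_LANDMARK_NAMES = [
    "Ankle Joint Center",
    "Knee Center",
    "Lateral Wear Point",
    "Medial Wear Point",
    "Lateral Condyle Center",
    "Medial Condyle Center",
]

N_RINGS = 104
N_THETA = 48


def _sig(x: np.ndarray | float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def _recipe(bone_kind: str) -> dict:
    """Shaft profile, surface bumps and landmark chart for one bone kind.

    Bumps: (amplitude mm, theta0 deg, z0 mm, sigma_theta deg, sigma_z mm).
    Theta convention (right bone): 0 = +x lateral, 90 = +y anterior,
    180 = -x medial, 270 = -y posterior.
    """
    if bone_kind == "femur":
        return {
            "length": 380.0,
            "dome": 18.0,
            "base": lambda z: 13.0 + 16.0 * _sig((42.0 - z) / 14.0)
            + 9.0 * _sig((z - 330.0) / 16.0),
            # medial condyle larger and more distal, lateral trochlear ridge
            # higher: the natural chirality that disambiguates pose
            "bumps": [
                (12.0, 230.0, 18.0, 34.0, 16.0),   # medial posterior condyle
                (10.0, 310.0, 22.0, 30.0, 16.0),   # lateral posterior condyle
                (3.5, 125.0, 30.0, 18.0, 14.0),    # medial trochlear ridge
                (5.0, 55.0, 32.0, 22.0, 14.0),     # lateral trochlear ridge
                (-4.0, 90.0, 34.0, 18.0, 18.0),    # trochlear groove
                (-6.0, 270.0, 12.0, 14.0, 10.0),   # intercondylar notch
                (20.0, 180.0, 372.0, 45.0, 22.0),  # femoral head
                (9.0, 0.0, 356.0, 35.0, 14.0),     # greater trochanter
                (3.0, 270.0, 190.0, 25.0, 110.0),  # linea aspera (posterior ridge)
            ],
            "landmarks": {
                "AP Sizing Point": (90.0, 72.0),
                "Lateral Anterior": (55.0, 34.0),
                "Lateral Distal": (325.0, 6.0),
                "Lateral Epicondyle": (0.0, 24.0),
                "Lateral Posterior": (310.0, 20.0),
                "Medial Anterior": (125.0, 34.0),
                "Medial Distal": (215.0, 6.0),
                "Medial Epicondyle": (180.0, 24.0),
                "Medial Posterior": (230.0, 20.0),
                "Top Groove": (90.0, 44.0),
                "Top Notch": (270.0, 30.0),
                "Femoral Head Center": (180.0, 372.0),
            },
            # joint-margin band (z-range fractions) for osteophyte seeding
            "margin_frac": (0.01, 0.12),
        }
    if bone_kind == "tibia":
        return {
            "length": 360.0,
            "dome": 16.0,
            "base": lambda z: 12.0 + 14.0 * _sig((z - 318.0) / 12.0)
            + 6.0 * _sig((26.0 - z) / 10.0),
            # medial plateau broader/deeper than lateral, as in vivo
            "bumps": [
                (9.0, 185.0, 348.0, 46.0, 12.0),   # medial plateau lobe
                (6.0, 355.0, 349.0, 34.0, 12.0),   # lateral plateau lobe
                (4.0, 80.0, 315.0, 25.0, 15.0),    # tibial tuberosity
                (3.0, 90.0, 180.0, 22.0, 120.0),   # anterior tibial crest
                (6.0, 180.0, 8.0, 30.0, 10.0),     # medial malleolus
            ],
            "landmarks": {
                "Ankle Joint Center": "bottom_pole",
                "Knee Center": "top_pole",
                "Lateral Wear Point": (0.0, 354.0),
                "Medial Wear Point": (180.0, 354.0),
                "Lateral Condyle Center": (340.0, 350.0),
                "Medial Condyle Center": (200.0, 350.0),
            },
            "margin_frac": (0.91, 0.99),
        }
    raise InvalidArgumentError(f"unknown bone kind: {bone_kind!r}")


def _radius(recipe: dict, z: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Surface radius r(z, theta), smooth in both arguments."""
    r = recipe["base"](z)
    for amp, t0, z0, st, sz in recipe["bumps"]:
        dth = np.angle(np.exp(1j * (theta - math.radians(t0))))
        r = r + amp * np.exp(
            -((dth / math.radians(st)) ** 2) - (((z - z0) / sz) ** 2)
        )
    # dome taper to poles
    L, d = recipe["length"], recipe["dome"]
    f = np.ones_like(np.asarray(z, dtype=float))
    lo = z < d
    hi = z > L - d
    f = np.where(lo, np.sqrt(np.clip(1.0 - ((d - z) / d) ** 2, 0.0, None)), f)
    f = np.where(hi, np.sqrt(np.clip(1.0 - ((z - (L - d)) / d) ** 2, 0.0, None)), f)
    return r * f


@lru_cache(maxsize=4)
def _template_arrays(bone_kind: str) -> tuple:
    rec = _recipe(bone_kind)
    L = rec["length"]
    z_eps = 0.75
    zs = np.linspace(z_eps, L - z_eps, N_RINGS)
    thetas = np.arange(N_THETA) * (2.0 * math.pi / N_THETA)
    zz, tt = np.meshgrid(zs, thetas, indexing="ij")
    rr = _radius(rec, zz, tt)
    verts = np.column_stack(
        [(rr * np.cos(tt)).ravel(), (rr * np.sin(tt)).ravel(), zz.ravel()]
    )
    bottom = len(verts)
    top = bottom + 1
    verts = np.vstack([verts, [0.0, 0.0, 0.0], [0.0, 0.0, L]])

    faces = []
    for i in range(N_RINGS - 1):
        for j in range(N_THETA):
            j2 = (j + 1) % N_THETA
            v00 = i * N_THETA + j
            v01 = i * N_THETA + j2
            v10 = (i + 1) * N_THETA + j
            v11 = (i + 1) * N_THETA + j2
            faces.append((v00, v01, v11))
            faces.append((v00, v11, v10))
    for j in range(N_THETA):
        j2 = (j + 1) % N_THETA
        faces.append((bottom, j2, j))
        faces.append((top, (N_RINGS - 1) * N_THETA + j, (N_RINGS - 1) * N_THETA + j2))
    faces = np.array(faces, dtype=np.int64)

    anchors = []
    names = []
    for name, spec in rec["landmarks"].items():
        if spec == "bottom_pole":
            anchors.append(bottom)
        elif spec == "top_pole":
            anchors.append(top)
        else:
            t0, z0 = math.radians(spec[0]), spec[1]
            r0 = float(_radius(rec, np.array(z0), np.array(t0)))
            target = np.array([r0 * math.cos(t0), r0 * math.sin(t0), z0])
            anchors.append(int(np.argmin(np.linalg.norm(verts - target, axis=1))))
        names.append(name)
    return verts, faces, tuple(names), np.array(anchors, dtype=np.int64)


def make_template(bone_kind: str) -> GroundTruthBone:
    """Deterministic right-side template bone with surface landmarks."""
    if bone_kind not in BONE_KINDS:
        raise InvalidArgumentError(f"unknown bone kind: {bone_kind!r}")
    verts, faces, names, anchors = _template_arrays(bone_kind)
    mesh = make_mesh(verts.copy(), faces.copy())
    lms = LandmarkSet.from_points(list(names), verts[anchors])
    return GroundTruthBone(
        mesh=mesh,
        landmarks=lms,
        latent=np.zeros(0),
        bone_kind=bone_kind,
        side="right",
        seed=0,
        landmark_vertex_ids=anchors.copy(),
    )


def mirror_to_left(bone: GroundTruthBone) -> GroundTruthBone:
    """Mirror a right bone to a left one (x -> -x, faces re-wound)."""
    v = bone.mesh.vertices.view(np.ndarray).copy()
    v[:, 0] *= -1.0
    f = bone.mesh.faces.view(np.ndarray)[:, ::-1].copy()
    pts = bone.landmarks.points.copy()
    pts[:, 0] *= -1.0
    return bone.copy_with(
        mesh=make_mesh(v, f),
        landmarks=bone.landmarks.with_points(pts),
        side="left",
        landmark_vertex_ids=None,
    )


# ---------------------------------------------------------------------------
# population sampling


_MONOMIALS = {
    "1": lambda x, y, z: np.ones_like(x),
    "x": lambda x, y, z: x,
    "y": lambda x, y, z: y,
    "z": lambda x, y, z: z,
    "zz": lambda x, y, z: z * z,
    "xz": lambda x, y, z: x * z,
    "yz": lambda x, y, z: y * z,
    "xy": lambda x, y, z: x * y,
    "zzz": lambda x, y, z: z * z * z,
    "xx-yy": lambda x, y, z: x * x - y * y,
    "xxz": lambda x, y, z: x * x * z,
    "yyz": lambda x, y, z: y * y * z,
}

# (axis, monomial) sequence defining the fixed basis-field family
_FIELD_SEQ = [
    (2, "z"), (0, "z"), (1, "z"), (0, "x"), (1, "y"), (2, "zz"),
    (0, "zz"), (1, "zz"), (0, "y"), (1, "x"), (2, "x"), (2, "y"),
    (0, "xz"), (1, "yz"), (2, "zzz"), (0, "yz"), (1, "xz"), (2, "xy"),
    (0, "zzz"), (1, "zzz"), (2, "xx-yy"), (0, "xx-yy"), (1, "xx-yy"),
    (2, "xz"), (0, "xxz"), (1, "yyz"),
]


def basis_fields(template: GroundTruthBone, k_latent: int) -> np.ndarray:
    """k smooth orthonormal displacement fields over the template vertices.

    Orthonormal under <f, g> = mean_v f(v).g(v), so a unit coefficient
    yields 1 mm RMS surface displacement.
    Returns array of shape (k, V, 3).
    """
    if k_latent < 1:
        raise InvalidArgumentError("k_latent must be >= 1")
    if k_latent > len(_FIELD_SEQ):
        raise InvalidArgumentError(f"at most {len(_FIELD_SEQ)} basis fields available")
    v = template.mesh.vertices.view(np.ndarray)
    c = 0.5 * (v.max(axis=0) + v.min(axis=0))
    h = 0.5 * (v.max(axis=0) - v.min(axis=0))
    x, y, z = ((v - c) / h).T
    nv = len(v)

    def _dot(f, g):
        return float(np.mean(np.sum(f * g, axis=1)))

    # Infinitesimal similarity generators (translations, rotations about the
    # centroid, isotropic scaling).  Candidate fields are projected into
    # their orthogonal complement so population variation is genuinely
    # non-rigid: Procrustes alignment then preserves the latent rank.
    rel = v - v.mean(axis=0)
    sim = [np.tile(np.eye(3)[a], (nv, 1)) for a in range(3)]
    sim += [np.cross(np.eye(3)[a], rel) for a in range(3)]
    sim.append(rel.copy())
    sim_ortho: list[np.ndarray] = []
    for f in sim:
        for g in sim_ortho:
            f = f - _dot(f, g) * g
        f = f / math.sqrt(_dot(f, f))
        sim_ortho.append(f)

    # Walk the fixed candidate sequence, keeping fields that stay
    # independent modulo the similarity group (some candidates collapse,
    # e.g. the three axis stretches span only two dims beyond isotropic
    # scaling), until k fields are collected.
    ortho: list[np.ndarray] = []
    for axis, mono in _FIELD_SEQ:
        if len(ortho) == k_latent:
            break
        f = np.zeros((nv, 3))
        f[:, axis] = _MONOMIALS[mono](x, y, z)
        for g in sim_ortho + ortho:
            f = f - _dot(f, g) * g
        norm = math.sqrt(_dot(f, f))
        if norm < 0.02:  # essentially a similarity motion: skip
            continue
        ortho.append(f / norm)
    if len(ortho) < k_latent:
        raise InvalidArgumentError("candidate field family exhausted")
    return np.stack(ortho)


def _displace(template: GroundTruthBone, disp: np.ndarray,
              scale: float) -> tuple[np.ndarray, np.ndarray]:
    """Apply a vertex displacement field then isotropic scale about centroid."""
    v = template.mesh.vertices.view(np.ndarray) + disp
    cent = v.mean(axis=0)
    v = cent + scale * (v - cent)
    return v, v[template.landmark_vertex_ids]


def sample_population(
    template: GroundTruthBone,
    n: int,
    k_latent: int = 6,
    sd: float = 2.0,
    seed: int = 0,
    scale_jitter: tuple[float, float] | None = (0.92, 1.08),
) -> list[GroundTruthBone]:
    """Draw n bones sharing the template topology (exact correspondence)."""
    if n < 2:
        raise InvalidArgumentError("population size must be >= 2")
    if sd < 0:
        raise InvalidArgumentError("sd must be >= 0")
    if template.landmark_vertex_ids is None:
        raise InvalidArgumentError("template must carry landmark vertex anchors")
    fields = basis_fields(template, k_latent)
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        c = rng.normal(0.0, sd, size=k_latent)
        s = float(rng.uniform(*scale_jitter)) if scale_jitter else 1.0
        disp = np.tensordot(c, fields, axes=(0, 0))
        v, lm_pts = _displace(template, disp, s)
        out.append(
            GroundTruthBone(
                mesh=make_mesh(v, template.mesh.faces.view(np.ndarray).copy()),
                landmarks=template.landmarks.with_points(lm_pts),
                latent=c,
                bone_kind=template.bone_kind,
                side=template.side,
                seed=seed,
                scale=s,
                landmark_vertex_ids=template.landmark_vertex_ids.copy(),
            )
        )
    return out


def add_osteophytes(bone: GroundTruthBone, severity: float,
                    seed: int = 0) -> GroundTruthBone:
    """Add 3-8 localized radial bumps near the joint margin.

    Landmark coordinates are deliberately left untouched: osteophytes are
    pathology that downstream model fitting must *not* reproduce, and the
    landmark ground truth refers to the underlying pre-morbid surface.
    """
    if not 0.0 <= severity <= 1.0:
        raise InvalidArgumentError("severity must lie in [0, 1]")
    if severity == 0.0:
        return bone.copy_with(mesh=bone.mesh.copy(), pathological=False)
    rec = _recipe(bone.bone_kind)
    v = bone.mesh.vertices.view(np.ndarray).copy()
    zmin, zmax = v[:, 2].min(), v[:, 2].max()
    f0, f1 = rec["margin_frac"]
    zlo, zhi = zmin + f0 * (zmax - zmin), zmin + f1 * (zmax - zmin)
    pool = np.flatnonzero((v[:, 2] >= zlo) & (v[:, 2] <= zhi))

    rng = np.random.default_rng(seed)
    n_bumps = int(rng.integers(3, 9))
    centers = rng.choice(pool, size=min(n_bumps, len(pool)), replace=False)
    # outward along the surface normal, so a bump's height equals its
    # distance to the pre-morbid surface (the ground-truth oracle)
    normals = bone.mesh.vertex_normals.view(np.ndarray).copy()
    normals /= np.maximum(np.linalg.norm(normals, axis=1, keepdims=True), 1e-12)

    mag = np.zeros(len(v))
    cap = 6.0 * severity
    for ci in centers:
        r_b = rng.uniform(4.0, 10.0)
        h = cap * rng.uniform(0.4, 1.0)
        d = np.linalg.norm(v - v[ci], axis=1)
        mag += h * np.exp(-((d / (r_b / 2.0)) ** 2))
    mag = np.minimum(mag, cap)
    v += mag[:, None] * normals
    return bone.copy_with(
        mesh=make_mesh(v, bone.mesh.faces.view(np.ndarray).copy()),
        pathological=True,
        seed=seed,
    )


def crop_extremities(mesh: trimesh.Trimesh, proximal_frac: float,
                     distal_frac: float) -> tuple[trimesh.Trimesh, trimesh.Trimesh]:
    """Split a bone into proximal/distal pieces along its z extent.

    Faces are kept if their centroid lies in the top ``proximal_frac`` or
    bottom ``distal_frac`` of the z-range; crop boundaries stay open.
    """
    if proximal_frac <= 0 or distal_frac <= 0 or proximal_frac + distal_frac > 1:
        raise InvalidArgumentError("fractions must be > 0 and sum to <= 1")
    v = mesh.vertices.view(np.ndarray)
    f = mesh.faces.view(np.ndarray)
    cz = v[f].mean(axis=1)[:, 2]
    zmin, zmax = v[:, 2].min(), v[:, 2].max()
    span = zmax - zmin
    prox = _submesh(v, f[cz >= zmax - proximal_frac * span])
    dist = _submesh(v, f[cz <= zmin + distal_frac * span])
    return prox, dist


def _submesh(vertices: np.ndarray, faces: np.ndarray) -> trimesh.Trimesh:
    used = np.unique(faces)
    remap = np.full(len(vertices), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return make_mesh(vertices[used], remap[faces])


def position_joint(
    femur: GroundTruthBone, tibia: GroundTruthBone, gap_mm: float = 6.0
) -> GroundTruthBone:
    """Translate a femur so it articulates above a tibia with a joint gap."""
    shift = (
        tibia.mesh.vertices.view(np.ndarray)[:, 2].max()
        + gap_mm
        - femur.mesh.vertices.view(np.ndarray)[:, 2].min()
    )
    v = femur.mesh.vertices.view(np.ndarray).copy()
    v[:, 2] += shift
    pts = femur.landmarks.points
    pts[:, 2] += shift
    return femur.copy_with(
        mesh=make_mesh(v, femur.mesh.faces.view(np.ndarray).copy()),
        landmarks=femur.landmarks.with_points(pts),
    )


def subject_volumes(
    femur: GroundTruthBone,
    tibia: GroundTruthBone,
    acquisitions=("hip", "knee", "ankle"),
    spacing: float = 1.0,
    noise_sd: float = 30.0,
    seed: int = 0,
    window_mm: float = 150.0,
) -> dict[str, tuple[CTVolume, LabelMask]]:
    """Rasterize hip/knee/ankle fields of view for one positioned subject.

    The knee window straddles the joint line; hip and ankle windows cover
    the top of the femur and the bottom of the tibia respectively.
    """
    fz = femur.mesh.vertices.view(np.ndarray)[:, 2]
    tz = tibia.mesh.vertices.view(np.ndarray)[:, 2]
    joint = 0.5 * (tz.max() + fz.min())
    windows = {
        "hip": ([femur], (fz.max() - window_mm, fz.max() + 1.0)),
        "knee": ([femur, tibia], (joint - window_mm / 2, joint + window_mm / 2)),
        "ankle": ([tibia], (tz.min() - 1.0, tz.min() + window_mm)),
    }
    out = {}
    for i, acq in enumerate(acquisitions):
        bones, win = windows[acq]
        out[acq] = rasterize_ct(
            bones, spacing=spacing, noise_sd=noise_sd,
            seed=seed * 10 + i, z_window=win,
        )
    return out


# ---------------------------------------------------------------------------
# pseudo-CT rasterization


def _fill_slice(mesh: trimesh.Trimesh, z: float, xs: np.ndarray,
                ys: np.ndarray) -> np.ndarray:
    """Even-odd point-in-mesh test for one transverse slice."""
    try:
        path = mesh.section(plane_origin=[0.0, 0.0, z], plane_normal=[0.0, 0.0, 1.0])
    except Exception:
        path = None
    inside = np.zeros(xs.shape, dtype=bool)
    if path is None:
        return inside
    for loop in path.discrete:
        if len(loop) < 3:
            continue
        poly = Polygon(loop[:, :2])
        if not poly.is_valid:
            poly = poly.buffer(0)
        if poly.is_empty:
            continue
        inside ^= contains_xy(poly, xs, ys)
    return inside


def rasterize_ct(
    bones: list[GroundTruthBone],
    spacing: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    pad_mm: float = 10.0,
    z_window: tuple[float, float] | None = None,
    cortical_hu: float = 700.0,
    interior_hu: float = 300.0,
    background_hu: float = 40.0,
    shell_mm: float = 2.0,
) -> tuple[CTVolume, LabelMask]:
    """Rasterize bones into a pseudo-CT volume plus ground-truth labels.

    Intensities: cortical shell ``cortical_hu``, interior ``interior_hu``,
    background ``background_hu``, plus additive Gaussian noise.  The
    optional ``z_window`` restricts the axial extent, emulating a joint
    acquisition (e.g. a knee field of view over two full-bone models).
    """
    if not bones:
        raise InvalidArgumentError("at least one bone is required")
    if spacing <= 0:
        raise InvalidArgumentError("spacing must be positive")
    allv = np.vstack([b.mesh.vertices.view(np.ndarray) for b in bones])
    lo = allv.min(axis=0) - pad_mm
    hi = allv.max(axis=0) + pad_mm
    if z_window is not None:
        lo[2] = max(lo[2], z_window[0])
        hi[2] = min(hi[2], z_window[1])
    shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 1)
    origin = lo
    xs1 = origin[0] + spacing * np.arange(shape[0])
    ys1 = origin[1] + spacing * np.arange(shape[1])
    zs1 = origin[2] + spacing * np.arange(shape[2])
    xg, yg = np.meshgrid(xs1, ys1, indexing="ij")
    xg, yg = xg.ravel(), yg.ravel()

    labels = np.zeros(tuple(shape), dtype=np.int16)
    intens = np.full(tuple(shape), background_hu, dtype=np.float32)
    n_shell = max(1, int(round(shell_mm / spacing)))
    for bone in bones:
        mesh = bone.mesh
        bz = mesh.vertices.view(np.ndarray)[:, 2]
        mask = np.zeros(tuple(shape), dtype=bool)
        for k, z in enumerate(zs1):
            if z < bz.min() or z > bz.max():
                continue
            # nudge off exact vertex planes for a robust section
            mask[:, :, k] = _fill_slice(mesh, z + 1e-4, xg, yg).reshape(
                shape[0], shape[1]
            )
        interior = ndimage.binary_erosion(mask, iterations=n_shell)
        intens[mask] = cortical_hu
        intens[interior] = interior_hu
        labels[mask] = 1 if bone.bone_kind == "femur" else 2

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intens = intens + rng.normal(0.0, noise_sd, size=intens.shape).astype(
            np.float32
        )
    sp = np.full(3, float(spacing))
    return CTVolume(intens, sp, origin), LabelMask(labels, sp, origin.copy())
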