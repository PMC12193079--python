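"""Three-stage reconstruction of full bones from partial extremities.

Given a shape model and the segmented proximal + distal pieces of a bone,
the full surface is recovered by:

1. **bounding-box scaling** — the model mean is scaled per axis so its
   longitudinal extent matches the combined partial pieces and its
   transverse extents match the distal piece (all measured in the
   observation's own principal frame, which makes the whole fit
   equivariant under rigid motion of the input);
2. **rigid registration** — trimmed point-to-surface ICP of the scaled
   mean's extremity vertices onto the partial surfaces, initialized from
   the principal frame and scored over candidate axis flips (the classic
   180-degree trap), with one isotropic scale refinement folded in;
3. **regularized deformable fitting** — alternating closest-point
   matching (restricted to the observed longitudinal ranges) and a ridge
   least-squares solve for the mode coefficients, with residual trimming
   and a hard match-distance cap so osteophyte outgrowths and segmentation
   debris do not drag the model off the pre-morbid surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from ._mesh import SurfaceQuery
from .ssm import ShapeModel, synthesize, umeyama
from .types import InvalidArgumentError, LandmarkSet, make_mesh


class RegistrationFailure(RuntimeError):
    pass


class InsufficientOverlapError(RuntimeError):
    pass


@dataclass
class PartialObservation:
    proximal: trimesh.Trimesh
    distal: trimesh.Trimesh
    bone_kind: str = "femur"
    side: str = "right"

    def __post_init__(self) -> None:
        if len(self.proximal.vertices) == 0 or len(self.distal.vertices) == 0:
            raise InvalidArgumentError("partial pieces must be non-empty")


@dataclass
class FitResult:
    scale: np.ndarray  # (3,) per-axis scale applied to model coordinates
    rotation: np.ndarray  # (3, 3) proper rotation
    translation: np.ndarray  # (3,)
    b: np.ndarray  # mode coefficients, sd units
    reconstructed: trimesh.Trimesh  # full bone in patient space
    landmarks: LandmarkSet  # propagated, patient space
    residual_rmse: float  # mm, surface residual of kept matches
    inlier_fraction: float
    untrimmed_rmse: float = 0.0  # mm, residual over all in-range matches
    untrimmed_p98: float = 0.0  # mm, 98th percentile of the same distances

    def transform_points(self, pts: np.ndarray) -> np.ndarray:
        return (self.rotation @ (pts * self.scale).T).T + self.translation

    def inverse_transform_points(self, pts: np.ndarray) -> np.ndarray:
        return ((pts - self.translation) @ self.rotation) / self.scale


def observation_frame(partial: PartialObservation) -> tuple[np.ndarray, np.ndarray]:
    """Principal frame of the observation: columns (t1, t2, u).

    u is the longitudinal axis oriented distal -> proximal; t1/t2 span the
    transverse plane from the distal piece's principal spread.  The frame
    is equivariant under rigid motion of the input (up to the inherent
    sign choice of t1, which registration resolves).
    """
    pv = partial.proximal.vertices.view(np.ndarray)
    dv = partial.distal.vertices.view(np.ndarray)
    allv = np.vstack([pv, dv])
    c = allv.mean(axis=0)
    cov = np.cov((allv - c).T)
    w, vec = np.linalg.eigh(cov)
    u = vec[:, np.argmax(w)]
    if (pv.mean(axis=0) - dv.mean(axis=0)) @ u < 0:
        u = -u
    dproj = dv - np.outer(dv @ u, u)
    dc = dproj.mean(axis=0)
    cov2 = np.cov((dproj - dc).T)
    w2, vec2 = np.linalg.eigh(cov2)
    order = np.argsort(w2)[::-1]
    t1 = vec2[:, order[0]]
    t1 = t1 - (t1 @ u) * u
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(u, t1)
    return c, np.column_stack([t1, t2, u])


def _extent(points: np.ndarray, axis: np.ndarray) -> float:
    p = points @ axis
    return float(p.max() - p.min())


def init_scale(model: ShapeModel, partial: PartialObservation) -> np.ndarray:
    """Per-axis scale matching the mean shape to the partial bounding box.

    Longitudinal: combined extent of both pieces along the observation's
    long axis over the mean's z extent.  Transverse: the distal piece's
    principal in-plane extents over the extents of the *matching* distal
    portion of the mean, measured along that portion's own principal
    axes — both sides are reduced the same way so the ratio compares like
    with like.  Transverse ratios are clamped to a plausible band: the
    bounding box is a coarse instrument and population-scale transverse
    variation stays within ~15%, while an unclamped outlier ratio (e.g.
    from a tilted shaft) poisons every later stage.
    """
    _, F = observation_frame(partial)
    t1, t2, u = F.T
    pv = partial.proximal.vertices.view(np.ndarray)
    dv = partial.distal.vertices.view(np.ndarray)
    allv = np.vstack([pv, dv])

    mv = model.mean_mesh().vertices.view(np.ndarray)
    z = mv[:, 2]
    span = z.max() - z.min()
    # model reference region = same longitudinal share as the distal piece
    _, fd = _observed_fracs(partial, 1.0)
    distal_m = mv[z <= z.min() + fd * span]
    dm2 = distal_m[:, :2] - distal_m[:, :2].mean(axis=0)
    w2, vec2 = np.linalg.eigh(np.cov(dm2.T))
    m1 = np.append(vec2[:, np.argmax(w2)], 0.0)
    m2 = np.cross([0.0, 0.0, 1.0], m1)

    num = np.array([_extent(dv, t1), _extent(dv, t2), _extent(allv, u)])
    den = np.array([_extent(distal_m, m1), _extent(distal_m, m2), span])
    if np.any(num < 1e-9) or np.any(den < 1e-9):
        raise InvalidArgumentError("degenerate (flat) input extents")
    s = num / den
    s[:2] = np.clip(s[:2], 0.85, 1.20)
    return s


def _model_end_sets(
    model: ShapeModel, end_frac: float | tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    fp, fd = (end_frac, end_frac) if np.isscalar(end_frac) else end_frac
    mv = model.mean_mesh().vertices.view(np.ndarray)
    z = mv[:, 2]
    span = z.max() - z.min()
    prox = mv[z >= z.max() - fp * span]
    dist = mv[z <= z.min() + fd * span]
    return prox, dist


def _observed_fracs(partial: PartialObservation, end_frac: float) -> tuple[float, float]:
    """Model end fractions matched to the observed piece lengths.

    Matching more of the model than the data covers drags the unmatched
    vertices to the crop boundaries and biases the pose, so each end
    fraction is capped by its piece's share of the combined longitudinal
    extent (minus a small boundary margin).
    """
    _, F = observation_frame(partial)
    u = F[:, 2]
    pv = partial.proximal.vertices.view(np.ndarray) @ u
    dv = partial.distal.vertices.view(np.ndarray) @ u
    total = max(pv.max(), dv.max()) - min(pv.min(), dv.min())
    fp = np.clip((pv.max() - pv.min()) / total - 0.02, 0.05, end_frac)
    fd = np.clip((dv.max() - dv.min()) / total - 0.02, 0.05, end_frac)
    return float(fp), float(fd)


def _rigid_candidates(
    model: ShapeModel,
    partial: PartialObservation,
    scale: np.ndarray,
    end_frac: float = 0.28,
    max_iters: int = 50,
    tol: float = 1e-6,
    n_best: int | None = 2,
) -> list[tuple[float, np.ndarray, np.ndarray, float]]:
    """Ranked rigid poses: list of (residual, rotation, translation, sigma).

    Initial rotations sweep a ring of roll angles about the observation's
    longitudinal axis, for both longitudinal orientations (the 180-degree
    trap); each is scored by a short trimmed ICP of the anisotropically
    scaled mean's extremity vertices, and the best few (mutually distinct
    in rotation) are refined to convergence.
    """
    scale = np.asarray(scale, dtype=float).reshape(3)
    prox_m, dist_m = _model_end_sets(model, _observed_fracs(partial, end_frac))
    src = np.vstack([prox_m, dist_m]) * scale
    n_prox = len(prox_m)
    q_prox = SurfaceQuery(partial.proximal)
    q_dist = SurfaceQuery(partial.distal)

    c_obs, F = observation_frame(partial)
    c_src = src.mean(axis=0)

    # model-side principal frame: longitudinal = +z, transverse from the
    # distal part's in-plane principal spread (mirrors observation_frame)
    dm = dist_m * scale
    dproj = dm[:, :2] - dm[:, :2].mean(axis=0)
    w2, vec2 = np.linalg.eigh(np.cov(dproj.T))
    m1 = np.append(vec2[:, np.argmax(w2)], 0.0)
    mz = np.array([0.0, 0.0, 1.0])
    M = np.column_stack([m1, np.cross(mz, m1), mz])

    def targets_of(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        tp, dp = q_prox.closest(pts[:n_prox])
        td, dd = q_dist.closest(pts[n_prox:])
        return np.vstack([tp, td]), np.concatenate([dp, dd])

    def run_icp(R0: np.ndarray, iters: int) -> tuple:
        sR = R0.copy()
        sig = 1.0
        t = c_obs - sig * sR @ c_src
        prev = np.inf
        for _ in range(iters):
            cur = sig * src @ sR.T + t
            tgt, d = targets_of(cur)
            sig, sR, t = umeyama(src, tgt, with_scale=True)
            resid = float(np.sqrt(np.mean(d**2)))
            if abs(prev - resid) < tol * max(prev, 1.0):
                prev = resid
                break
            prev = resid
        cur = sig * src @ sR.T + t
        _, d = targets_of(cur)
        return float(np.sqrt(np.mean(d**2))), sig, sR, t

    t1, t2, u = F.T
    candidates = []
    for flip in (False, True):
        a1, a2, a3 = (t1, t2, u) if not flip else (t1, -t2, -u)
        for roll in np.arange(0.0, 2.0 * np.pi, np.pi / 4.0):
            ca, sa = np.cos(roll), np.sin(roll)
            Fc = np.column_stack([ca * a1 + sa * a2, -sa * a1 + ca * a2, a3])
            candidates.append(Fc @ M.T)
    if n_best is None:
        # one short-ICP pose per canonical roll, plus the best flipped one
        out = []
        flipped = []
        for i, R0 in enumerate(candidates):
            resid, sig, R, t = run_icp(R0, 8)
            (out if i < 8 else flipped).append((resid, R, t, sig))
        out.append(min(flipped, key=lambda x: x[0]))
        return out
    scored = sorted(
        ((run_icp(R0, 8)[0], i, R0) for i, R0 in enumerate(candidates)),
        key=lambda x: x[0],
    )
    # refine the best candidates that are mutually distinct rotations
    out = []
    used: list[np.ndarray] = []
    for _, _, R0 in scored:
        if any(np.trace(R0.T @ Ru) > 2.8 for Ru in used):  # < ~25 deg apart
            continue
        used.append(R0)
        resid, sig, R, t = run_icp(R0, max_iters)
        out.append((resid, R, t, sig))
        if len(out) == n_best:
            break
    out.sort(key=lambda x: x[0])
    return out


def _ring_poses(model, partial, scale, end_frac=0.28):
    """Short-ICP poses for every candidate roll plus the best flipped pose."""
    return _rigid_candidates(model, partial, scale, end_frac=end_frac,
                             n_best=None)


def rigid_register(
    model: ShapeModel,
    partial: PartialObservation,
    scale: np.ndarray,
    end_frac: float = 0.28,
    max_iters: int = 50,
    tol: float = 1e-6,
    fail_mm: float = 20.0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Best rigid pose of the scaled mean against the partial surfaces.

    Returns (rotation, translation, isotropic refinement factor sigma);
    the pose maps model coordinates x to R (sigma * scale * x) + t.
    """
    cands = _rigid_candidates(
        model, partial, scale, end_frac=end_frac, max_iters=max_iters,
        tol=tol, n_best=1,
    )
    resid, R, t, sig = cands[0]
    if resid > fail_mm:
        raise RegistrationFailure(f"ICP residual {resid:.1f} mm exceeds {fail_mm} mm")
    return R, t, sig


def deform_fit(
    model: ShapeModel,
    partial: PartialObservation,
    ridge: float = 1.0,
    trim_frac: float = 0.10,
    iters: int = 25,
    end_frac: float = 0.28,
    max_match_dist_mm: float = 5.0,
    min_matches: int = 100,
    pose: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
    reverse_matching: bool = True,
    match_stride: int = 1,
    queries: tuple[SurfaceQuery, SurfaceQuery] | None = None,
) -> FitResult:
    """Solve for mode coefficients b against the partial surfaces.

    Alternates (closest-point matching within the observed longitudinal
    ranges) with (trimming of the ``trim_frac`` worst residuals plus any
    match beyond ``max_match_dist_mm``) and a ridge least-squares solve
    ``min ||S(b) - targets||^2 + ridge ||b||^2`` — the ridge term is a
    Mahalanobis prior since b is expressed in sd units.  Trimming and the
    distance cap provide the robustness that keeps osteophytes out of the
    reconstruction.
    """
    if pose is None:
        aniso = init_scale(model, partial)
        R, t, sig0 = rigid_register(model, partial, aniso, end_frac=end_frac)
        # retain a single isotropic scale from here on (the longitudinal
        # ratio — the best-measured extent); residual anisotropy is
        # absorbed by the deformation modes
        sig = float((sig0 * aniso)[2])
    else:
        scale0, R, t = pose
        scale0 = np.asarray(scale0, dtype=float).reshape(3)
        sig = float(scale0[2])
        aniso = scale0 / sig
    s0 = np.ones(3)

    q_prox, q_dist = queries or (
        SurfaceQuery(partial.proximal),
        SurfaceQuery(partial.distal),
    )
    pv = partial.proximal.vertices.view(np.ndarray)
    dv = partial.distal.vertices.view(np.ndarray)

    n_modes = model.n_modes
    sd = np.sqrt(model.variances)
    V = model.n_vertices
    modes_r = model.modes.reshape(-1, 3, n_modes)  # (V+L, 3, M)
    mean_r = model.mean.reshape(-1, 3)
    faces = model.faces
    vf_model = SurfaceQuery(model.mean_mesh()).vertex_faces_padded
    data_pts = np.vstack([pv, dv])[::match_stride]  # observed surface points

    # seed the coefficients with the mode-space image of the anisotropic
    # bounding-box stretch, so deformation starts near the observed shape;
    # the stretch is clamped to the population-plausible range because the
    # bounding-box ratio is coarse and a wrong large seed is worse than none
    rel = np.asarray(aniso, dtype=float) / float(np.cbrt(np.prod(aniso)))
    rel = np.clip(rel, 0.92, 1.08)
    b = model.project((mean_r * rel).ravel(), n_modes)
    n_total = n_kept = 0
    kept_resid = np.zeros(0)
    d_all = np.zeros(0)
    caps = np.geomspace(6.0 * max_match_dist_mm, max_match_dist_mm, max(iters - 4, 1))
    for it in range(iters):
        # anneal the robust match cap over the whole budget: while the fit
        # is coarse an honest mismatch can exceed the final cap, and
        # locking such regions out early is irrecoverable; only near
        # convergence do residuals beyond the cap mean pathology
        cap = float(caps[min(it, len(caps) - 1)])
        trim_now = trim_frac if it >= iters - 5 else 0.0
        # observed longitudinal ranges in model coordinates (crop-side
        # boundaries shrunk so they do not attract the model)
        inv = lambda p: ((p - t) @ R) / sig
        margin = 2.0 / sig
        pz = inv(pv)[:, 2]
        dz = inv(dv)[:, 2]

        vec = model.mean + model.modes @ (b * sd)
        verts = vec[: 3 * V].reshape(-1, 3)
        z = verts[:, 2]
        sel_p = np.flatnonzero(z >= pz.min() + margin)[::match_stride]
        sel_d = np.flatnonzero(z <= dz.max() - margin)[::match_stride]
        cur = sig * verts @ R.T + t

        # forward matches: model vertices -> observed surfaces
        tp, dp = q_prox.closest(cur[sel_p])
        td, dd = q_dist.closest(cur[sel_d])
        sel_f = np.concatenate([sel_p, sel_d])
        src_f = verts[sel_f]
        tgt_f = np.vstack([tp, td])
        d_f = np.concatenate([dp, dd])

        # reverse matches: observed points -> model surface (barycentric)
        if reverse_matching:
            q_model = SurfaceQuery(make_mesh(cur, faces), vertex_faces=vf_model)
            cp_r, d_r, tri_r = q_model.closest_full(data_pts)
            bw = trimesh.triangles.points_to_barycentric(
                cur[faces[tri_r]], cp_r
            )
            bw = np.clip(bw, 0.0, 1.0)
            bw /= bw.sum(axis=1, keepdims=True)
            fverts_r = faces[tri_r]  # (mr, 3) vertex ids
            src_r = np.einsum("mj,mjc->mc", bw, verts[fverts_r])
            tgt_r = data_pts
        else:
            bw = np.zeros((0, 3))
            fverts_r = np.zeros((0, 3), dtype=np.int64)
            src_r = np.zeros((0, 3))
            tgt_r = np.zeros((0, 3))
            d_r = np.zeros(0)

        src = np.vstack([src_f, src_r])
        tgt = np.vstack([tgt_f, tgt_r])
        d = np.concatenate([d_f, d_r])
        n_total = len(d)

        keep = d <= cap
        if trim_now > 0 and keep.sum() > 0:
            thresh = np.quantile(d[keep], 1.0 - trim_now)
            keep &= d <= thresh
        if keep.sum() < min_matches:
            raise InsufficientOverlapError(
                f"only {int(keep.sum())} matches survive trimming"
            )
        n_kept = int(keep.sum())
        kept_resid = d[keep]

        # refine the similarity pose on the kept matches, then solve for b
        sig, R, t = umeyama(src[keep], tgt[keep], with_scale=True)
        tgt_model = ((tgt[keep] - t) @ R) / sig

        keep_f = keep[: len(d_f)]
        keep_r = keep[len(d_f):]
        A_f = modes_r[sel_f[keep_f]]  # (mf, 3, M)
        mean_f = mean_r[sel_f[keep_f]]
        A_r = np.einsum("mj,mjcK->mcK", bw[keep_r], modes_r[fverts_r[keep_r]])
        mean_b = np.einsum("mj,mjc->mc", bw[keep_r], mean_r[fverts_r[keep_r]])
        A = np.vstack([A_f, A_r]).reshape(-1, n_modes) * sd[None, :]
        rhs = (tgt_model - np.vstack([mean_f, mean_b])).ravel()
        ata = A.T @ A + ridge * np.eye(n_modes)
        b_new = np.linalg.solve(ata, A.T @ rhs)
        if np.linalg.norm(b_new - b) < 1e-4 and it >= len(caps):
            b = b_new
            break
        b = b_new

    scale = sig * s0
    mesh, lms = synthesize(model, b)
    verts = (R @ (mesh.vertices.view(np.ndarray) * scale).T).T + t
    mesh = make_mesh(verts, mesh.faces.view(np.ndarray))
    lms = lms.transformed(R, t, scale)

    # untrimmed residual over all in-range matches (both directions):
    # unlike the robust (trimmed) residual this cannot hide a chirality
    # mismatch, so it is the score used to arbitrate between poses
    inv = lambda p: ((p - t) @ R) / sig
    margin = 2.0 / sig
    pz = inv(pv)[:, 2]
    dz = inv(dv)[:, 2]
    vm = inv(mesh.vertices.view(np.ndarray))
    z = vm[:, 2]
    _, dp = q_prox.closest(mesh.vertices[z >= pz.min() + margin])
    _, dd = q_dist.closest(mesh.vertices[z <= dz.max() - margin])
    q_final = SurfaceQuery(mesh, vertex_faces=vf_model)
    _, d_rev = q_final.closest(data_pts)
    d_all = np.concatenate([dp, dd, d_rev])
    return FitResult(
        scale=scale,
        rotation=R,
        translation=t,
        b=b,
        reconstructed=mesh,
        landmarks=lms,
        residual_rmse=float(np.sqrt(np.mean(kept_resid**2))) if n_kept else 0.0,
        inlier_fraction=(n_kept / n_total) if n_total else 0.0,
        untrimmed_rmse=float(np.sqrt(np.mean(d_all**2))) if len(d_all) else 0.0,
        untrimmed_p98=float(np.quantile(d_all, 0.98)) if len(d_all) else 0.0,
    )


def fit_partial(model: ShapeModel, partial: PartialObservation,
                end_frac: float = 0.28, fail_mm: float = 20.0,
                score_iters: int = 12, **kw) -> FitResult:
    """Run all three stages (scale, rigid, deform).

    Every candidate roll about the longitudinal axis (plus the best
    longitudinally flipped pose) is carried through a short deformable
    fit and the winner — by *untrimmed* surface residual — is refined to
    convergence.  Rigid residuals alone cannot arbitrate the roll on
    near-symmetric bone shafts, and the robust trimmed objective cannot
    either, because trimming discards exactly the asymmetric evidence.
    """
    s0 = init_scale(model, partial)
    queries = (SurfaceQuery(partial.proximal), SurfaceQuery(partial.distal))
    cands = _ring_poses(model, partial, s0, end_frac=end_frac)
    if min(c[0] for c in cands) > fail_mm:
        raise RegistrationFailure(
            f"best ICP residual {min(c[0] for c in cands):.1f} mm "
            f"exceeds {fail_mm} mm"
        )
    other_kw = {k: v for k, v in kw.items() if k != "iters"}
    full_iters = kw.get("iters", 25)
    scored: list[tuple[float, tuple]] = []
    for _, R, t, sig in cands:
        try:
            short = deform_fit(
                model, partial, pose=(sig * s0, R, t), end_frac=end_frac,
                iters=score_iters, match_stride=2, queries=queries,
                **other_kw,
            )
        except InsufficientOverlapError:
            continue
        # a flipped pose can match almost everywhere and hide its
        # mismatch (e.g. a malleolus on the wrong side) in a small area:
        # score by the tail of the untrimmed distances, not their RMS
        scored.append((short.untrimmed_p98, (sig * s0, R, t)))
    if not scored:
        raise InsufficientOverlapError("no candidate pose retains matches")
    # near-symmetric poses only separate once the fit has converged, so
    # the shortlist is re-scored at the full iteration budget
    scored.sort(key=lambda x: x[0])
    refined: list[tuple[float, tuple]] = []
    for _, pose in scored[:3]:
        fit = deform_fit(
            model, partial, pose=pose, end_frac=end_frac,
            iters=full_iters, match_stride=2, queries=queries, **other_kw,
        )
        refined.append((fit.untrimmed_p98, pose))
    best_pose = min(refined, key=lambda x: x[0])[1]
    return deform_fit(model, partial, pose=best_pose, end_frac=end_frac,
                      queries=queries, **kw)


def reconstruct(model: ShapeModel,
                fit: FitResult) -> tuple[trimesh.Trimesh, LandmarkSet]:
    """Full bone and landmarks at the fitted coefficients, patient space."""
    mesh, lms = synthesize(model, fit.b)
    verts = fit.transform_points(mesh.vertices.view(np.ndarray))
    return make_mesh(verts, mesh.faces.view(np.ndarray)), lms.transformed(
        fit.rotation, fit.translation, fit.scale
    )
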