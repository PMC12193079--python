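# Methods

This note documents the models and procedures implemented in `kneeforge`,
the assumptions behind them, the parameters that matter, and what the
synthetic evaluation does and does not demonstrate.

## Coordinate conventions

All geometry is in millimetres in a right-handed patient frame: +z
proximal, +y anterior, +x lateral for a right bone. Left bones are
handled by mirroring x → −x (with face rewinding); all modelling operates
on right-side geometry. Meshes preserve vertex order everywhere
(`process=False`), because point correspondence across a population is
expressed purely through shared vertex indexing.

## The synthetic bone generator

The generator stands in for a clinical CT training population and is
first-class, tested code — its outputs are the ground truth every other
stage is scored against.

**Templates.** Each bone is a generalized cylinder: rings of vertices
around a straight longitudinal axis with radius `r(z, θ)` = shaft profile
plus smooth Gaussian bumps (condyles, trochlea, head, trochanter,
plateau lobes, malleolus, tuberosity), tapered to poles by a dome factor.
Templates are deliberately chiral, as real bones are: the medial condyle
is larger and more distal, the lateral trochlear ridge higher, the medial
tibial plateau broader, and both bones carry an extended ridge (linea
aspera posteriorly on the femur, the anterior crest on the tibia). The
chirality matters: a mirror-symmetric synthetic bone makes the 180° roll
a true ambiguity that no surface-based fitter could resolve. Landmarks
(12 femoral, 6 tibial names) are anchored to template vertices, so they
lie exactly on the surface and are carried exactly by any vertex
displacement field. Budget ≈ 5 000 vertices per bone.

**Population model.** Members share the template topology (exact
correspondence). Each is displaced by a linear combination of `k_latent`
fixed low-order polynomial vector fields with coefficients drawn i.i.d.
N(0, sd²), plus a recorded global isotropic scale jitter U(0.92, 1.08).
The fields are orthonormalized over template vertices (unit coefficient =
1 mm RMS surface displacement) **and projected orthogonal to the
infinitesimal similarity group** (translations, rotations, scaling);
without that projection, Procrustes alignment absorbs part of the latent
variation and the latent dimension would not be recoverable from the
aligned covariance. Defaults: `k_latent = 6`, `sd = 2.0` mm — roughly
5 mm RMS inter-subject surface variation, a plausible magnitude for adult
femora; the clinical population's variance is not characterized, so this
is a documented free parameter, chosen once.

**Pathology.** Osteophytes are 3–8 localized outward bumps
(Gaussian profile, radius 4–10 mm, height ≤ 6·severity mm, capped) seeded
at joint-margin vertices, displacing the mesh along vertex normals so a
bump's height equals its distance to the pre-morbid surface. Landmark
coordinates are left on the pre-morbid surface: osteophytes are what
reconstruction must *not* reproduce.

**Pseudo-CT.** Bones are rasterized slice-wise (mesh–plane sections
filled by even–odd polygon tests): cortical shell 700 HU (2 mm), interior
300 HU, background 40 HU, additive Gaussian noise. Acquisition windows
(hip / knee / ankle, 150 mm axial extent) emulate the three per-joint
fields of view.

## Segmentation

A *slice predictor* (2D intensity slice → foreground probability) is a
pluggable contract; learned models are out of scope and a threshold
predictor (≥ 200 HU) serves the synthetic volumes. Post-processing per
slice: binarize at 0.5, 3×3 opening + closing, drop components < 30 mm².
In 3D: keep the two largest components; a single merged component in a
knee volume is split by marker-based watershed on the inverted interior
distance transform (markers = two largest maxima, ≥ 10 mm apart, ties by
distance value then voxel index). Label 1 (femur) goes to the more
proximal component in a knee volume, else by acquisition. Meshing:
marching cubes at iso-level 0.5 on the padded indicator, then Taubin
smoothing (λ = 0.5, μ = −0.53, 10 iterations — volume-preserving).
Meshes cut by the acquisition window are closed with planar caps by
marching cubes; those caps are stripped before fitting (they are not bone
surface, and matches onto them corrupt the fit).

## Augmented shape models

Built by similarity Procrustes alignment (vertex block only; transforms
applied to the landmark block, which enters scaled by `w_L`, default 1)
followed by PCA; all `M = min(P−1, 3(V+L))` modes are stored and the
working model keeps the smallest N with ≥ 99% cumulative variance.
Coefficients are expressed in sd units. Quality triad:

- *compactness(N)* = 100 · Σ_{i≤N} λ_i / Σ λ_i;
- *generality(N)* = RMS point-to-point distance between an aligned unseen
  shape and its projection onto the first N modes, mean ± sd over
  members. Corresponded-point distance (the classical choice) rather
  than closest-surface distance, because only the former is guaranteed
  non-increasing in N — closest-surface distances can *rise* with N when
  a coarse projection slides tangentially;
- *specificity(N)* = minimum symmetric surface RMSE from a random
  `b ~ N(0, I_N)` sample to any training member, mean ± sd over samples.

Correspondence for off-topology surfaces is established by non-rigid ICP:
similarity initialization, then 10 rounds of closest-point matching and a
Laplacian-regularized displacement solve `(I + αLᵀL) d = targets − cur`
with α annealed geometrically 10 → 0.1; mean residual > 5 mm raises a
correspondence failure. The generator's exact correspondence serves as
the oracle for this machinery in tests.

Models persist as HDF5 (mean, modes, variances, faces, landmark names,
`w_L`, aligned training shapes for specificity).

## Partial-data fitting

Three stages, matching the observation's own principal frame so the whole
fit is equivariant under rigid motion of the input:

1. **Scaling.** Per-axis ratios of the observation's bounding box to the
   mean shape's (longitudinal: combined pieces; transverse: distal piece
   vs the *matching* distal portion of the mean, both measured along
   their own principal axes). Transverse ratios are clamped to
   [0.85, 1.20] — the bounding box is a coarse instrument, and an outlier
   ratio from a tilted shaft would poison every later stage.
2. **Rigid registration.** Trimmed point-to-surface ICP of the scaled
   mean's extremity vertices (end fractions capped by the observed piece
   lengths) with similarity updates. Initial rotations sweep an 8-roll
   ring about the longitudinal axis plus the flipped orientation; the
   retained isotropic scale is the *longitudinal* ratio (the
   best-measured extent), with residual anisotropy absorbed by the modes.
3. **Deformable fitting.** Iterate: match model vertices inside the
   observed longitudinal ranges to the piece surfaces *and* piece points
   back to the model surface (barycentric rows); refine the similarity
   pose on the kept matches; solve the ridge least squares
   `min ‖S(b) − targets‖² + ridge‖b‖²` (ridge = 1, a Mahalanobis prior in
   sd units). The match cap anneals geometrically 30 → 5 mm across the
   25-iteration budget and the 10% residual trim engages only in the last
   five iterations: while the fit is coarse an honest mismatch can exceed
   the final cap, and locking such regions out early is irrecoverable;
   near convergence, residuals beyond the cap mean pathology. The
   coefficient vector is seeded with the mode-space image of the
   (clamped) anisotropic stretch.

**Pose arbitration.** Bone shafts are nearly roll-symmetric, so every
ring candidate is carried through a short deformable fit, the best three
re-scored at the full budget, and the winner chosen by the 98th
percentile of *untrimmed* residuals. Two deliberate choices here: the
robust (trimmed) objective cannot arbitrate, because trimming discards
exactly the asymmetric evidence; and RMS cannot either, because a flipped
pose hides its mismatch (a malleolus on the wrong side) in a small
fraction of the surface.

## Landmarks and morphometrics

Landmarks propagate with the deformed model (they are part of the shape
vector) and are then refined toward the segmented surface:
`p′ = p + w · clamp(proj(p) − p, 5 mm)` with per-name osteophyte-risk
weights (0.2 at margins prone to osteophytes — epicondyles, wear points —
0.8 elsewhere; configurable). Secondary parameters derive from the
primary landmarks only and are rigid-invariant by construction: femoral
mechanical axis (head centre → Top-Notch-derived knee centre), tibial
mechanical axis (knee centre → ankle centre), AP direction and sizes
(overall and per condyle), ML width, tibial condylar line, sulcus angle,
and the reference points used for resection planning. The tibial
condylar line's accuracy is assessed as the angular error between
centre-to-centre lines built from ≥ 3 plateau edge points per side.

## Implant design (2.5D)

Resections: femoral distal plane ⟂ mechanical axis 9 mm proximal to the
more distal condyle point; femoral posterior plane ⟂ AP direction 8 mm
anterior to the most posterior condyle; tibial plane ⟂ mechanical axis
tilted 3° posteriorly, 8 mm below the higher wear point. All depths are
surgeon-style configuration defaults. Contours are the largest closed
mesh–plane section loops, canonicalized counter-clockwise from the most
anterior point (so normalized arc length 0 is anterior and 0.5
posterior — the parameterization of the ignore zones).

Femoral component: per-condyle pivot radius = 0.33 × that condyle's AP
size (a configurable linear law standing in for an unspecified sizing
rule), circles tangent to both cuts, rollback cut at 25°, outline = the
resected contour inset 0.25 mm (no overhang by construction). Tibial
baseplate: 0.5 mm rim inset, 3 mm additional posterior retreat over the
posterior 20% of the AP extent (kept inside the posterior ignore zone,
which exists precisely to exclude this deliberate deviation from the
bone contour), 2 mm fillets, keel between the contour
centroid and the mechanical-axis piercing point, stem = 0.35 × ML extent.
Insert: socket = medial pivot radius + 0.5 mm, lateral radius = 2 × the
lateral condyle radius (low congruence), anterior cut at 85% of the AP
extent, outline nested 1 mm inside the baseplate. Collapsing offsets
raise recorded design failures (never silently), so cohort runs can
report a success rate. Coverage = contour-to-contour distances outside
ignore sectors (tibial posterior 0.35–0.65; femoral notch 0.42–0.58 and
anterior 0–0.05 / 0.95–1).

## Study sizes and numerical choices

The synthetic study uses 20 training shapes, 10 held-out bones
(30%/30% crops), 5 noisy knee volumes at 1 mm / 30 HU, and 10 design
subjects — sizes chosen so the whole evaluation runs comfortably on one
CPU while keeping Monte-Carlo noise well below the tolerances tested.
Closest-point queries are exact point-to-triangle distances with KD-tree
candidate pruning. Ties in closest-point queries resolve to the lowest
triangle index; all randomness flows through a single integer seed per
operation (NumPy `default_rng`).

## What passing tests do and do not show

The generator emulates: smooth inter-subject variation of known rank,
exact correspondence and landmarks, osteophytes, partial fields of view,
and CT-like intensity structure with noise. It does **not** emulate:
cortical/trabecular texture, cartilage, the patella, metal artefacts,
segmentation ambiguity at true joint contact, or — most importantly —
*localized* inter-subject shape detail: the latent fields are global
polynomials, so the mode space cannot produce local bumps. Two
consequences are worth stating plainly. First, reconstruction accuracy
here (≈ 0.2–0.4 mm RMSE) is better than one should expect on clinical
data, where shape variation is not exactly low-rank. Second, the
trimming mechanism shows no measurable benefit on osteophytic inputs in
this world — the global mode space is already structurally immune to
local outgrowths (fits degrade by ~0.02 mm without any robustness), so
the corresponding strict-improvement property test fails honestly; on
clinical SSMs, whose modes carry localized detail, trimming is what
keeps the fit off the osteophytes. The mechanism is implemented,
configurable, and verified not to harm clean fits.

Known limitations: single-bone fitting (no joint femur+tibia coupling);
2.5D implant parameterization rather than solid CAD; the pose-arbitration
margin shrinks for bones whose deformation happens to mimic a roll
flip — the anatomical ridges keep this rare but it is the failure mode to
watch on harder populations.
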