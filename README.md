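# kneeforge

Desk-scale, fully automated planning for patient-specific total knee
arthroplasty (TKA): from CT-like volumes to a scored medial-pivot implant
design, with a synthetic bone generator providing exact ground truth at
every stage.

## Who this is for

Researchers in orthopaedic image analysis and statistical shape modelling
who want a complete, testable implementation of the automated TKA planning
chain — segmentation post-processing, augmented statistical shape models
(SSMs), partial-data bone reconstruction, anatomical landmarking and
parametric implant design — without access to clinical CT data. Every
stage is exercised end-to-end on generated femur/tibia populations whose
landmarks, label masks and latent shape coefficients are known exactly.

## The model

**Augmented SSM.** A population of corresponded surfaces (vertex `i` is the
same anatomical location on every member) is extended with L named
landmarks: each training shape contributes a vector
`(x_1 … x_3V, w_L · l_1 … w_L · l_3L)`. After generalized Procrustes
alignment (similarity transforms, driven by the vertex block), PCA of the
sample covariance gives the mean shape `x̄`, orthonormal modes `φ_i` and
variances `λ_1 ≥ … ≥ λ_M`. Shapes are synthesized as

```
x(b) = x̄ + Σ_i b_i √λ_i φ_i        (b in standard-deviation units)
```

and the model is truncated at the smallest N with Σλ_i ≥ 99% of total
variance. Model quality is reported as the classical triad: compactness
(variance captured per mode count), generality (reconstruction error of
unseen shapes), specificity (distance of random samples to the training
set).

**Partial-data fitting.** Given the segmented proximal and distal
extremities of a bone, the full shape is recovered in three stages:
bounding-box scaling of the mean, rigid/similarity ICP registration
(with candidate-pose arbitration against the 180° roll ambiguity), and
regularized deformable fitting — alternating closest-point matching with a
ridge (Mahalanobis-prior) least-squares solve for `b`, with an annealed
match-distance cap and terminal residual trimming so osteophytes are not
reproduced.

**Implant design.** The femoral component follows the medial-pivot
concept: each condyle's sagittal curvature is one circle of radius
`0.33 × that condyle's AP size`, placed tangent to the distal and
posterior resection planes; the tibial baseplate is an inward offset of
the resected plateau contour with a 3 mm posterior retreat; the insert
excavates the pivot sphere medially and carries a lowly congruent convex
lateral surface. Fit quality is over/under-hang: bone-to-implant contour
distances outside configured ignore zones.

## A worked example

`examples/03_build_and_fit_ssm.py` trains a femur model on 20 synthetic
bones and reconstructs a held-out bone from its proximal/distal 30%:

```
model: 19 modes from 20 shapes
compactness at 6 modes: 99.97%
truncated to 6 modes (>= 99% variance)

observation: proximal 1669 + distal 1416 vertices (middle 40% unseen)
reconstruction vs ground truth: RMSE 0.334 mm, Hausdorff 1.60 mm
landmarks: mean 2.06 mm, worst AP Sizing Point at 2.70 mm
(sub-millimetre RMSE means the unseen mid-shaft was recovered from the
two extremities alone)
```

The other examples cover population generation (`01`), segmentation of a
noisy knee volume (`02`), implant design with coverage scoring (`04`) and
the full hip-to-ankle workflow with its JSON report (`05`). A thin CLI
exposes the same operations (`kneeforge synth | segment | evaluate |
build-ssm | ssm-quality | fit | landmarks | design | run |
evaluate-run`).

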