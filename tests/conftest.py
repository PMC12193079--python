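"""Shared fixtures: templates, trained models, and the held-out cohort.

The expensive artifacts (population, model, ten partial-data fits) are
session-scoped so the reconstruction/landmark/coverage analyses and the
per-module tests all reuse one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from kneeforge import fitting, ssm, synthbone

TRAIN_N = 20
TRAIN_SEED = 7
TIBIA_TRAIN_SEED = 8
HELDOUT_N = 10
HELDOUT_SEED = 99
K_LATENT = 6
SD = 2.0
CROP = (0.3, 0.3)


@pytest.fixture(scope="session")
def femur_template():
    return synthbone.make_template("femur")


@pytest.fixture(scope="session")
def tibia_template():
    return synthbone.make_template("tibia")


@pytest.fixture(scope="session")
def femur_population(femur_template):
    return synthbone.sample_population(
        femur_template, TRAIN_N, k_latent=K_LATENT, sd=SD, seed=TRAIN_SEED
    )


@pytest.fixture(scope="session")
def femur_model_full(femur_population):
    return ssm.build_model(ssm.CorrespondedSet.from_population(femur_population))


@pytest.fixture(scope="session")
def femur_model(femur_model_full):
    return ssm.truncate(femur_model_full, 0.99)


@pytest.fixture(scope="session")
def tibia_model(tibia_template):
    pop = synthbone.sample_population(
        tibia_template, TRAIN_N, k_latent=K_LATENT, sd=SD, seed=TIBIA_TRAIN_SEED
    )
    return ssm.truncate(
        ssm.build_model(ssm.CorrespondedSet.from_population(pop)), 0.99
    )


@pytest.fixture(scope="session")
def femur_heldout(femur_template):
    return synthbone.sample_population(
        femur_template, HELDOUT_N, k_latent=K_LATENT, sd=SD, seed=HELDOUT_SEED
    )


@pytest.fixture(scope="session")
def femur_fits(femur_model, femur_heldout):
    """Three-stage fits of the ten held-out femurs from 30/30 crops."""
    out = []
    for bone in femur_heldout:
        prox, dist = synthbone.crop_extremities(bone.mesh, *CROP)
        obs = fitting.PartialObservation(prox, dist, "femur")
        out.append((bone, obs, fitting.fit_partial(femur_model, obs)))
    return out


@pytest.fixture(scope="session")
def knee_cohort(femur_template, tibia_template):
    """Five synthetic knee acquisitions (1 mm, 30 HU noise) + truth labels."""
    cohort = []
    for i in range(5):
        fb = synthbone.sample_population(
            femur_template, 2, k_latent=K_LATENT, sd=SD, seed=200 + i
        )[0]
        tb = synthbone.sample_population(
            tibia_template, 2, k_latent=K_LATENT, sd=SD, seed=300 + i
        )[0]
        fb = synthbone.position_joint(fb, tb)
        tz = tb.mesh.vertices.view(np.ndarray)[:, 2]
        fz = fb.mesh.vertices.view(np.ndarray)[:, 2]
        joint = 0.5 * (tz.max() + fz.min())
        vol, labels = synthbone.rasterize_ct(
            [fb, tb], spacing=1.0, noise_sd=30.0, seed=i + 1,
            z_window=(joint - 75.0, joint + 75.0),
        )
        cohort.append((vol, labels))
    return cohort
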