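"""Segmentation post-processing tests with voxel-level oracles."""

import numpy as np
import pytest
import trimesh

from kneeforge import metrics, segment, synthbone
from kneeforge.types import InvalidArgumentError


def _sphere_bone(template, radius, center, kind="femur"):
    s = trimesh.creation.icosphere(subdivisions=4, radius=radius)
    s.vertices += np.asarray(center, dtype=float)
    return template.copy_with(
        mesh=trimesh.Trimesh(s.vertices, s.faces, process=False), bone_kind=kind
    )


@pytest.fixture(scope="module")
def small_knee(femur_template, tibia_template):
    """One coarse (1.5 mm) knee acquisition with ground-truth labels."""
    fb = synthbone.sample_population(femur_template, 2, 4, 1.5, seed=61)[0]
    tb = synthbone.sample_population(tibia_template, 2, 4, 1.5, seed=62)[0]
    fb = synthbone.position_joint(fb, tb)
    tz = tb.mesh.vertices.view(np.ndarray)[:, 2].max()
    return fb, tb, (tz - 60.0, tz + 66.0)


class TestPredictor:
    def test_constant_slices(self):
        pred = segment.default_slice_predictor(200.0)
        assert not pred(np.full((5, 5), 40.0)).any()
        assert pred(np.full((5, 5), 700.0)).all()

    def test_mixed_slice_brute_force_count(self):
        rng = np.random.default_rng(3)
        sl = rng.uniform(0, 800, size=(20, 20))
        pred = segment.default_slice_predictor(200.0)
        assert pred(sl).sum() == (sl >= 200.0).sum()

    def test_threshold_must_be_finite(self):
        with pytest.raises(InvalidArgumentError):
            segment.default_slice_predictor(np.nan)


class TestPostprocess:
    def test_two_disjoint_spheres_match_per_sphere_rasterization(
        self, femur_template
    ):
        f = _sphere_bone(femur_template, 18.0, (0, 0, 60), "femur")
        t = _sphere_bone(femur_template, 15.0, (0, 0, 0), "tibia")
        vol, labels = synthbone.rasterize_ct([f, t], spacing=1.0, noise_sd=0.0)
        res = segment.segment_volume(
            vol, segment.default_slice_predictor(200.0), "knee"
        )
        assert set(np.unique(res.mask.labels)) == {0, 1, 2}
        for label in (1, 2):
            ref = int((labels.labels == label).sum())
            got = int((res.mask.labels == label).sum())
            assert abs(got - ref) / ref < 0.02

    def test_touching_spheres_split_by_watershed(self, femur_template):
        # centres 28 mm apart, radii 15: overlap ~2 mm
        f = _sphere_bone(femur_template, 15.0, (0, 0, 28), "femur")
        t = _sphere_bone(femur_template, 15.0, (0, 0, 0), "tibia")
        vol, _ = synthbone.rasterize_ct([f, t], spacing=1.0, noise_sd=0.0)
        res = segment.segment_volume(
            vol, segment.default_slice_predictor(200.0), "knee"
        )
        assert res.ambiguous_boundary
        assert set(np.unique(res.mask.labels)) == {0, 1, 2}
        for label, cz in ((1, 28.0), (2, 0.0)):
            idx = np.array(np.nonzero(res.mask.labels == label)).T
            centroid = idx.mean(axis=0) * res.mask.spacing + res.mask.origin
            assert abs(centroid[2] - cz) <= 2.0

    def test_idempotent_on_clean_mask(self, femur_template):
        f = _sphere_bone(femur_template, 15.0, (0, 0, 50), "femur")
        t = _sphere_bone(femur_template, 12.0, (0, 0, 0), "tibia")
        vol, _ = synthbone.rasterize_ct([f, t], spacing=1.5, noise_sd=0.0)
        res1 = segment.segment_volume(
            vol, segment.default_slice_predictor(200.0), "knee"
        )
        prob2 = (res1.mask.labels > 0).astype(float)
        mask2, _ = segment.postprocess_masks(
            prob2, res1.mask.spacing, "knee", origin=res1.mask.origin
        )
        assert np.array_equal(mask2.labels > 0, res1.mask.labels > 0)
        assert np.array_equal(mask2.labels, res1.mask.labels)

    def test_empty_volume_flagged_not_raised(self):
        prob = np.zeros((10, 10, 5))
        mask, info = segment.postprocess_masks(prob, 1.0, "knee")
        assert info["empty"]
        assert not mask.labels.any()

    def test_acquisition_label_assignment(self, femur_template):
        b = _sphere_bone(femur_template, 12.0, (0, 0, 0), "femur")
        vol, _ = synthbone.rasterize_ct([b], spacing=1.5, noise_sd=0.0)
        pred = segment.default_slice_predictor(200.0)
        hip = segment.segment_volume(vol, pred, "hip")
        ankle = segment.segment_volume(vol, pred, "ankle")
        assert set(np.unique(hip.mask.labels)) == {0, 1}
        assert set(np.unique(ankle.mask.labels)) == {0, 2}


@pytest.fixture(scope="module")
def sphere_mask(femur_template):
    b = _sphere_bone(femur_template, 20.0, (0, 0, 0), "femur")
    _, labels = synthbone.rasterize_ct([b], spacing=1.0, noise_sd=0.0)
    return labels


class TestMaskToMesh:
    def test_surface_accuracy_vs_analytic_sphere(self, sphere_mask):
        mesh = segment.mask_to_mesh(sphere_mask, 1, smoothing_iters=10)
        d = np.abs(np.linalg.norm(mesh.vertices.view(np.ndarray), axis=1) - 20.0)
        assert d.mean() < 0.5  # half a voxel
        assert mesh.is_watertight

    def test_volume_matches_voxel_count(self, sphere_mask):
        mesh = segment.mask_to_mesh(sphere_mask, 1, smoothing_iters=10)
        voxels = int((sphere_mask.labels == 1).sum())
        assert abs(mesh.volume - voxels) / voxels < 0.03

    def test_unsmoothed_vertices_on_half_integer_lattice(self, sphere_mask):
        mesh = segment.mask_to_mesh(sphere_mask, 1, smoothing_iters=0)
        frac = ((mesh.vertices.view(np.ndarray) - sphere_mask.origin) * 2.0) % 1.0
        assert np.allclose(np.minimum(frac, 1 - frac), 0.0, atol=1e-6)

    def test_absent_label(self, sphere_mask):
        with pytest.raises(KeyError):
            segment.mask_to_mesh(sphere_mask, 2)


class TestSegmentVolume:
    def test_clean_knee_yields_both_bones(self, small_knee):
        fb, tb, window = small_knee
        vol, labels = synthbone.rasterize_ct(
            [fb, tb], spacing=1.5, noise_sd=0.0, z_window=window
        )
        res = segment.segment_volume(
            vol, segment.default_slice_predictor(200.0), "knee"
        )
        assert set(res.meshes) == {"femur", "tibia"}
        for kind, label in (("femur", 1), ("tibia", 2)):
            assert metrics.dice(res.mask, labels, label) > 0.98

    def test_dice_monotone_in_noise(self, small_knee):
        """Averaged over 5 seeds, per-bone Dice must not improve with noise."""
        fb, tb, window = small_knee
        means = []
        for noise in (0.0, 30.0, 80.0):
            vals = []
            for seed in range(5):
                vol, labels = synthbone.rasterize_ct(
                    [fb, tb], spacing=1.5, noise_sd=noise, seed=seed,
                    z_window=window,
                )
                res = segment.segment_volume(
                    vol, segment.default_slice_predictor(200.0), "knee"
                )
                vals.append(metrics.dice(res.mask, labels, 1))
                vals.append(metrics.dice(res.mask, labels, 2))
            means.append(np.mean(vals))
        assert means[0] >= means[1] - 1e-6
        assert means[1] >= means[2] - 1e-6

    def test_resolution_convergence(self, femur_template):
        """Finer voxels bring the meshed surface closer to the true one."""
        b = _sphere_bone(femur_template, 20.0, (0, 0, 0), "femur")
        errs = {}
        for spacing in (2.0, 0.5):
            _, labels = synthbone.rasterize_ct([b], spacing=spacing, noise_sd=0.0)
            mesh = segment.mask_to_mesh(labels, 1, smoothing_iters=10)
            d = np.linalg.norm(mesh.vertices.view(np.ndarray), axis=1) - 20.0
            errs[spacing] = float(np.sqrt(np.mean(d**2)))
        assert errs[0.5] < errs[2.0]

    def test_strip_boundary_caps_opens_mesh(self, femur_template):
        b = _sphere_bone(femur_template, 15.0, (0, 0, 0), "femur")
        _, labels = synthbone.rasterize_ct(
            [b], spacing=1.0, noise_sd=0.0, z_window=(-5.0, 5.0)
        )
        mesh = segment.mask_to_mesh(labels, 1, smoothing_iters=0)
        stripped = segment.strip_boundary_caps(mesh, labels)
        assert len(stripped.faces) < len(mesh.faces)
        zc = stripped.vertices.view(np.ndarray)[:, 2]
        assert zc.min() > labels.origin[2] + 0.4
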