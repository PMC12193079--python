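"""Implant design tests: resections, sections, profiles, coverage."""

import json

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings, strategies as st

from kneeforge import implant, metrics, morpho, synthbone
from kneeforge.types import (
    DesignFailureError,
    InvalidArgumentError,
    PlanarContour,
    make_mesh,
)


@pytest.fixture(scope="module")
def template_params(femur_template, tibia_template):
    return morpho.secondary_parameters(
        femur_template.landmarks, tibia_template.landmarks
    )


@pytest.fixture(scope="module")
def template_plan(template_params):
    return implant.plan_resections(template_params)


def _circle_contour(radius, n=128, origin=(0.0, 0.0, 0.0)):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack([radius * np.cos(th), radius * np.sin(th)])
    return PlanarContour(np.asarray(origin, dtype=float), np.eye(3)[:2], pts)


class TestPlanResections:
    def test_distal_plane_normal_parallel_to_mech_axis(
        self, template_params, template_plan
    ):
        axis = template_params.femoral_mech_axis[1] - (
            template_params.femoral_mech_axis[0]
        )
        axis /= np.linalg.norm(axis)
        n = template_plan.femoral_distal.normal
        assert abs(abs(n @ axis) - 1.0) < 1e-9

    def test_zero_distal_cut_passes_through_condyle_point(self, template_params):
        from kneeforge.config import default_config

        cfg = default_config()["implant"]
        cfg["distal_cut_mm"] = 0.0
        plan = implant.plan_resections(template_params, cfg)
        d = (template_params.distal_reference_point - plan.femoral_distal.point)
        assert abs(d @ plan.femoral_distal.normal) < 1e-9

    def test_tibial_slope_angle(self, template_params, template_plan):
        prox = template_params.tibial_mech_axis[0] - (
            template_params.tibial_mech_axis[1]
        )
        prox /= np.linalg.norm(prox)
        cosang = np.clip(template_plan.tibial_proximal.normal @ prox, -1, 1)
        assert np.degrees(np.arccos(cosang)) == pytest.approx(3.0, abs=1e-6)


class TestSectionContour:
    def test_cylinder_perimeter(self):
        cyl = trimesh.creation.cylinder(radius=20.0, height=60.0, sections=256)
        cyl = make_mesh(cyl.vertices, cyl.faces)
        plane = implant.Plane(
            np.zeros(3), np.array([0.0, 0, 1]), np.eye(3)[0], np.eye(3)[1]
        )
        c = implant.section_contour(cyl, plane)
        assert c.perimeter() == pytest.approx(2 * np.pi * 20.0, rel=0.005)

    def test_sphere_great_circle(self):
        s = trimesh.creation.icosphere(subdivisions=4, radius=25.0)
        plane = implant.Plane(
            np.zeros(3), np.array([0.0, 0, 1]), np.eye(3)[0], np.eye(3)[1]
        )
        c = implant.section_contour(make_mesh(s.vertices, s.faces), plane)
        r = np.linalg.norm(c.points, axis=1)
        assert np.allclose(r, 25.0, atol=0.2)

    def test_non_intersecting_plane(self):
        s = trimesh.creation.icosphere(subdivisions=2, radius=10.0)
        plane = implant.Plane(
            np.array([0.0, 0, 50.0]), np.array([0.0, 0, 1]),
            np.eye(3)[0], np.eye(3)[1],
        )
        with pytest.raises(implant.EmptySectionError):
            implant.section_contour(make_mesh(s.vertices, s.faces), plane)


class TestPivotRadius:
    def test_default_ratio(self):
        assert implant.pivot_radius(60.0, 0.33) == pytest.approx(19.8)

    def test_half_ratio(self):
        assert implant.pivot_radius(40.0, 0.5) == pytest.approx(20.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(1.0, 200.0))
    def test_homogeneity(self, ap):
        assert implant.pivot_radius(2 * ap) == pytest.approx(
            2 * implant.pivot_radius(ap)
        )

    def test_nonpositive_rejected(self):
        with pytest.raises(InvalidArgumentError):
            implant.pivot_radius(0.0)


class TestTibialBaseplate:
    def test_pure_rim_offset_on_circle(self):
        from kneeforge.config import default_config

        cfg = default_config()["implant"]
        cfg["posterior_retreat_mm"] = 0.0
        out, keel = implant.design_tibial_baseplate(_circle_contour(30.0), cfg)
        r = np.linalg.norm(out.points, axis=1)
        assert np.allclose(r, 29.5, atol=0.1)

    def test_posterior_retreat_distance(self):
        out, _ = implant.design_tibial_baseplate(_circle_contour(30.0))
        rep = metrics.contour_distance(_circle_contour(30.0), out)
        # rim 0.5 + retreat 3 at the most posterior point
        assert rep.hausdorff == pytest.approx(3.5, abs=0.2)
        post = out.points[np.argmin(out.points[:, 1])]
        assert np.linalg.norm(post) == pytest.approx(30.0 - 3.5, abs=0.2)

    def test_keel_inside_contour(self, tibia_template, template_plan):
        c = implant.section_contour(
            tibia_template.mesh, template_plan.tibial_proximal
        )
        out, keel = implant.design_tibial_baseplate(c)
        from shapely.geometry import Point, Polygon

        assert Polygon(out.points).contains(Point(*keel.position))
        assert keel.stem_length_mm > 0

    def test_collapsing_offset_reports_failure(self):
        with pytest.raises(DesignFailureError):
            implant.design_tibial_baseplate(_circle_contour(3.0))


class TestFemoralProfile:
    def test_symmetric_landmarks_give_equal_radii(self, tibia_template):
        """A mirror-symmetric femoral landmark set is the symmetry oracle."""
        from kneeforge.types import LandmarkSet

        pts = {
            "Femoral Head Center": [0, 0, 372.0],
            "Top Notch": [0, -28, 30.0],
            "Top Groove": [0, 24, 44.0],
            "AP Sizing Point": [0, 26, 72.0],
            "Medial Posterior": [-22, -30, 20.0],
            "Lateral Posterior": [22, -30, 20.0],
            "Medial Anterior": [-20, 25, 34.0],
            "Lateral Anterior": [20, 25, 34.0],
            "Medial Distal": [-20, -5, 2.0],
            "Lateral Distal": [20, -5, 2.0],
            "Medial Epicondyle": [-32, 0, 24.0],
            "Lateral Epicondyle": [32, 0, 24.0],
        }
        lms = LandmarkSet.from_points(list(pts), np.array(list(pts.values())))
        sp = morpho.secondary_parameters(lms, tibia_template.landmarks)
        assert sp.ap_size_medial == pytest.approx(sp.ap_size_lateral, abs=1e-9)
        r_m = implant.pivot_radius(sp.ap_size_medial)
        r_l = implant.pivot_radius(sp.ap_size_lateral)
        assert abs(r_m - r_l) < 0.1

    def test_template_design_properties(
        self, femur_template, template_params, template_plan
    ):
        distal_c = implant.section_contour(
            femur_template.mesh, template_plan.femoral_distal
        )
        posterior_c = implant.section_contour(
            femur_template.mesh, template_plan.femoral_posterior
        )
        prof = implant.design_femoral_profile(
            template_params, distal_c, posterior_c,
            femoral_lms=femur_template.landmarks,
        )
        # tangency by construction: centre sits one radius off each plane
        assert prof.medial_arc.tangency_residual_mm < 0.05
        assert prof.medial_arc.center == pytest.approx(
            [prof.medial_arc.radius_mm] * 2
        )
        # clamped outline cannot exceed the bone contour
        bone_ml = distal_c.points[:, 0].max() - distal_c.points[:, 0].min()
        assert prof.ml_extent_mm <= bone_ml

    def test_profile_serialization_deterministic(
        self, femur_template, template_params, template_plan
    ):
        def build():
            distal_c = implant.section_contour(
                femur_template.mesh, template_plan.femoral_distal
            )
            posterior_c = implant.section_contour(
                femur_template.mesh, template_plan.femoral_posterior
            )
            prof = implant.design_femoral_profile(
                template_params, distal_c, posterior_c
            )
            return json.dumps(prof.to_dict(), sort_keys=True)

        assert build() == build()


class TestInsert:
    def test_socket_is_pivot_plus_clearance(
        self, femur_template, template_params, template_plan
    ):
        distal_c = implant.section_contour(
            femur_template.mesh, template_plan.femoral_distal
        )
        posterior_c = implant.section_contour(
            femur_template.mesh, template_plan.femoral_posterior
        )
        prof = implant.design_femoral_profile(
            template_params, distal_c, posterior_c
        )
        ins = implant.design_insert_profile(prof, _circle_contour(28.0))
        assert ins.socket_radius_mm == pytest.approx(
            prof.medial_arc.radius_mm + 0.5
        )
        assert ins.lateral_radius_mm == pytest.approx(
            2.0 * prof.lateral_arc.radius_mm
        )
        # outline nested inside the baseplate
        from shapely.geometry import Polygon

        assert Polygon(_circle_contour(28.0).points).contains(
            Polygon(ins.outline.points)
        )

    def test_full_congruence_flagged(
        self, femur_template, template_params, template_plan
    ):
        from kneeforge.config import default_config

        distal_c = implant.section_contour(
            femur_template.mesh, template_plan.femoral_distal
        )
        posterior_c = implant.section_contour(
            femur_template.mesh, template_plan.femoral_posterior
        )
        prof = implant.design_femoral_profile(
            template_params, distal_c, posterior_c
        )
        cfg = default_config()["implant"]
        cfg["congruence_factor"] = 1.0
        ins = implant.design_insert_profile(prof, _circle_contour(28.0), cfg)
        assert ins.warnings


class TestCoverage:
    def test_identical_contours_zero(self):
        c = _circle_contour(30.0)
        rep = implant.coverage_report(c, c)
        assert rep.rmse == pytest.approx(0.0, abs=1e-9)

    def test_uniform_offset(self):
        rep = implant.coverage_report(
            _circle_contour(30.0), _circle_contour(29.0)
        )
        assert rep.rmse == pytest.approx(1.0, rel=0.02)

    def test_zone_excludes_posterior_retreat(self):
        bone = _circle_contour(30.0)
        plate, _ = implant.design_tibial_baseplate(bone)
        zones = implant.IgnoreZones.for_bone("tibia")
        inside = implant.coverage_report(bone, plate, zones)
        assert inside.hausdorff < 1.2  # only rim + fillet remain

    def test_overlapping_zones_rejected(self):
        with pytest.raises(InvalidArgumentError):
            implant.IgnoreZones([("a", 0.1, 0.5), ("b", 0.4, 0.8)])


class TestWholeKnee:
    def test_template_design_succeeds(self, femur_template, tibia_template,
                                      template_params):
        res = implant.design_implants(
            template_params,
            femur_template.mesh,
            tibia_template.mesh,
            femoral_lms=femur_template.landmarks,
        )
        assert res.success
        assert res.femoral_coverage.rmse < 0.5
        assert res.tibial_coverage.rmse < 1.5
        assert res.insert is not None

    def test_no_femoral_overhang_by_construction(
        self, femur_template, tibia_template, template_params
    ):
        from shapely.geometry import Polygon

        res = implant.design_implants(
            template_params, femur_template.mesh, tibia_template.mesh
        )
        bone = Polygon(res.femoral_bone_contour.points).buffer(0.05)
        assert bone.contains(Polygon(res.femoral.contour.points))

    def test_failures_recorded_not_raised(self, femur_template, tibia_template,
                                          template_params):
        from kneeforge.config import default_config

        cfg = default_config()["implant"]
        cfg["rim_offset_mm"] = 200.0  # guaranteed collapse
        res = implant.design_implants(
            template_params, femur_template.mesh, tibia_template.mesh, cfg
        )
        assert not res.success
        assert any("tibial" in f for f in res.failures)
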