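"""Dose-engine tests: geometry, depth factor, convolution, scans."""

import math

import numpy as np
import pytest

import srscone as s
from srscone.errors import ConfigurationError, DomainError, ValidationError
from srscone.synthetic_field import NON_CONVERGING

from oracles import brute_force_dose, brute_force_fluence_grid

# toy cone focused 50 mm above the source: from the isocenter the visible
# source region is a 0.5 mm diameter disc (limited by the top aperture)
FOCUSED_TOY_CONE = s.ConeSpec(
    nominal_diameter=0.5,
    top_radius=0.175,
    bottom_radius=0.2,
    top_distance=300.0,
    bottom_distance=350.0,
)


class TestBeamAndConeValidation:
    def test_kernel_weights_must_sum_to_one(self):
        with pytest.raises(ValidationError):
            s.BeamModel(kernel_components=((0.5, 2.0), (0.4, 20.0)))

    def test_aperture_ordering_enforced(self):
        with pytest.raises(ValidationError):
            s.ConeSpec(5.0, 1.0, 1.0, 700.0, 630.0)

    def test_packaged_set_has_the_nine_nominal_diameters(self, cones):
        assert sorted(cones) == [5.0, 7.5, 10.0, 12.5, 15.0, 17.5, 20.0, 25.0, 30.0]
        for a, cone in cones.items():
            assert cone.nominal_diameter == a

    def test_bottom_aperture_projects_nominal_radius_to_iso(self, beam, cones):
        for a, cone in cones.items():
            proj = cone.bottom_radius * beam.source_to_iso / cone.bottom_distance
            assert proj == pytest.approx(a / 2.0, rel=1e-12)


class TestFluence:
    def test_fully_visible_source_inside_wide_cone(self, beam):
        cone = s.make_cone(30.0, beam)
        small_spot = s.BeamModel(focal_spot_diameter=1.0)
        assert s.fluence_at(small_spot, cone, (0.0, 0.0, 1000.0)) == 1.0

    def test_fully_blocked_outside_shadow(self, beam, cones):
        assert s.fluence_at(beam, cones[5.0], (10.0, 0.0, 1000.0)) == 0.0

    def test_partial_occlusion_matches_disc_area_ratio(self):
        # 0.5 mm visible disc inside a 2 mm spot: area fraction 0.0625
        beam = s.BeamModel(focal_spot_diameter=2.0)
        frac = s.fluence_at(beam, FOCUSED_TOY_CONE, (0.0, 0.0, 1000.0), n_samples=2000)
        assert frac == pytest.approx(0.0625, abs=0.01)

    def test_upstream_point_rejected(self, beam, cones):
        with pytest.raises(DomainError):
            s.fluence_at(beam, cones[5.0], (0.0, 0.0, 500.0))

    def test_minimum_sampling_enforced(self, beam, cones):
        with pytest.raises(ConfigurationError):
            s.fluence_at(beam, cones[5.0], (0.0, 0.0, 1000.0), n_samples=100)


class TestTermaDepthFactor:
    def test_zero_at_surface(self, beam):
        assert s.terma_depth_factor(beam, 0.0, 1000.0) == 0.0

    def test_inverse_square_limit(self):
        # saturated buildup, no attenuation: pure inverse square
        beam = s.BeamModel(mu=1e-12, buildup_beta=1e6)
        val = s.terma_depth_factor(beam, 50.0, 2000.0)
        assert val == pytest.approx(0.25, rel=1e-6)

    def test_reference_point_value(self, beam):
        # (1 - e^-4.5) e^-0.075, computed independently
        expected = (1.0 - math.exp(-0.3 * 15.0)) * math.exp(-0.005 * 15.0)
        assert expected == pytest.approx(0.9174371871505521, rel=1e-12)
        assert s.terma_depth_factor(beam, 15.0, 1000.0) == pytest.approx(expected)

    def test_negative_depth_rejected(self, beam):
        with pytest.raises(DomainError):
            s.terma_depth_factor(beam, -1.0, 1000.0)


class TestDoseAt:
    def test_equilibrium_field_matches_depth_factor(self, beam):
        # saturated field (>= D_LEE + 6 sigma_scatter ~ 190 mm): the kernel
        # integrates to 1, so the CAX dose is the depth factor alone
        big = s.make_cone(200.0, beam)
        fld = s.DoseField(beam, big, 1000.0)
        for depth in (15.0, 50.0, 100.0):
            expected = s.terma_depth_factor(beam, depth, 1000.0 + depth)
            assert fld.cax_dose(depth) == pytest.approx(expected, rel=5e-3)

    def test_small_field_loses_lateral_equilibrium(self, beam, cones):
        d5 = s.DoseField(beam, cones[5.0], 1000.0).cax_dose(15.0)
        d20 = s.DoseField(beam, cones[20.0], 1000.0).cax_dose(15.0)
        assert d5 / d20 < 1.0

    def test_cax_dose_monotone_in_cone_diameter(self, beam, cones):
        doses = [
            s.DoseField(beam, cones[a], 1000.0).cax_dose(15.0) for a in sorted(cones)
        ]
        assert np.all(np.diff(doses) > 0)

    def test_far_off_axis_dose_is_small(self, beam, cones):
        fld = s.DoseField(beam, cones[5.0], 1000.0)
        assert fld.dose(30.0, 1015.0, 15.0) < 0.02 * fld.cax_dose(15.0)

    def test_grid_step_coarser_than_kernel_rejected(self, beam, cones):
        with pytest.raises(ConfigurationError):
            s.DoseField(beam, cones[5.0], 1000.0, grid_step=3.0)

    def test_point_above_surface_rejected(self, beam, cones):
        with pytest.raises(DomainError):
            s.dose_at(beam, cones[5.0], (0.0, 0.0, 990.0))

    @pytest.mark.parametrize("a", [5.0, 12.5, 30.0])
    def test_matches_brute_force_convolution(self, beam, cones, a):
        """Radial-quadrature dose equals a direct Cartesian double sum."""
        cone = cones[a]
        fld = s.DoseField(beam, cone, 1000.0)
        grid = brute_force_fluence_grid(beam, cone, 1015.0)
        for r0 in np.linspace(0.0, 0.6 * a, 7):
            ref = brute_force_dose(beam, cone, grid, r0, 1015.0, 15.0)
            assert fld.dose(r0, 1015.0, 15.0) == pytest.approx(ref, rel=1e-3)


class TestScans:
    def test_untilted_pdd_equals_cax_dose(self, beam, cones, field5):
        depths = (5.0, 15.0, 50.0, 100.0)
        curve = s.simulate_scan(
            beam, cones[5.0], s.ScanRequest("PDD", 1000.0, depths)
        )
        for d, v in zip(depths, curve.values):
            assert v == pytest.approx(field5.cax_dose(d), rel=1e-12)

    def test_tilt_distorts_depth_more_than_buildup_region(self, beam, cones):
        req0 = s.ScanRequest("PDD", 1000.0, (20.0, 150.0), tilt_deg=0.0)
        req1 = s.ScanRequest("PDD", 1000.0, (20.0, 150.0), tilt_deg=1.0)
        v0 = s.simulate_scan(beam, cones[5.0], req0).dose
        v1 = s.simulate_scan(beam, cones[5.0], req1).dose
        rel = np.abs(v1 - v0) / v0
        assert rel[1] > rel[0]

    def test_oar_symmetric_about_axis(self, beam, cones):
        pos = tuple(np.arange(-8.0, 8.001, 0.5))
        curve = s.simulate_scan(
            beam, cones[5.0], s.ScanRequest("OAR", 925.0, pos, depth_mm=75.0)
        )
        v = curve.dose
        assert np.max(np.abs(v - v[::-1])) / v[len(v) // 2] < 1e-3

    def test_oar_requires_depth(self):
        with pytest.raises(ValidationError):
            s.ScanRequest("OAR", 925.0, (-5.0, 0.0, 5.0))

    def test_tilt_restricted_to_pdd(self):
        with pytest.raises(ValidationError):
            s.ScanRequest("OAR", 925.0, (-5.0, 0.0, 5.0), depth_mm=75.0, tilt_deg=1.0)

    def test_positions_must_increase(self):
        with pytest.raises(ValidationError):
            s.ScanRequest("PDD", 1000.0, (0.0, 10.0, 10.0))


class TestApertureGeometry:
    def test_focused_cone_converges_at_source(self):
        cone = s.ConeSpec(5.0, 1.0, 2.0, 100.0, 200.0)
        assert s.convergence_distance(cone) == pytest.approx(0.0, abs=1e-12)

    def test_line_intersection_closed_form(self):
        cone = s.ConeSpec(5.0, 1.25, 1.2645, 300.0, 350.0)
        expected = 300.0 - 1.25 * 50.0 / (1.2645 - 1.25)
        got = s.convergence_distance(cone)
        assert got == expected  # identical arithmetic path must be exact
        assert got == pytest.approx(-4010.34, abs=0.01)

    def test_cylindrical_bore_never_converges(self):
        cone = s.ConeSpec(5.0, 1.75, 1.75, 630.0, 700.0)
        assert s.convergence_distance(cone) == NON_CONVERGING

    def test_packaged_cones_converge_about_4m_above_source(self, cones):
        for cone in cones.values():
            assert s.convergence_distance(cone) == pytest.approx(-4000.0, rel=1e-6)

    def test_near_cylindrical_cone_has_no_occlusion(self, beam, cones):
        assert s.occlusion_fraction(cones[5.0], beam) == 0.0

    def test_under_projected_opening_occludes_by_area_ratio(self):
        beam = s.BeamModel(focal_spot_diameter=1.0)
        # projected opening 0.5 mm against a 1.0 mm spot: 1 - 0.25 = 0.75
        assert s.occlusion_fraction(FOCUSED_TOY_CONE, beam) == pytest.approx(0.75)

    def test_opening_equal_to_spot_is_boundary_case(self):
        beam = s.BeamModel(focal_spot_diameter=1.0)
        cone = s.ConeSpec(0.5, 0.35, 0.4, 300.0, 350.0)
        # top projects to exactly 1.0 mm at the source plane
        assert s.occlusion_fraction(cone, beam) == 0.0
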