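"""Curvature measurement, sections, buckling threshold, local regression."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from furrowshell.furrow_metrics import (
    CurvatureSeries,
    buckling_threshold,
    extract_section,
    loess_fit,
    recoil_velocity,
    three_point_curvature,
)


class TestThreePointCurvature:
    def test_known_circle(self):
        # (0,0), (5,5), (10,0) lie on the circle of radius 5 centred at (5,0)
        assert three_point_curvature((0, 0), (5, 5), (10, 0)) == pytest.approx(0.2)

    def test_collinear_gives_zero(self):
        assert three_point_curvature((0, 0), (1, 0), (2, 0)) == 0.0

    def test_coincident_rejected(self):
        with pytest.raises(ValueError):
            three_point_curvature((1, 1), (1, 1), (2, 0))

    def test_sign_convention(self):
        # bulging along the outward direction = convex = positive
        up = np.array([0.0, 1.0])
        assert three_point_curvature((-1, 0), (0, 1), (1, 0), outward=up) > 0
        assert three_point_curvature((-1, 0), (0, -1), (1, 0), outward=up) < 0

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        log_r=st.floats(min_value=-2.0, max_value=2.0),
        theta=st.floats(min_value=0.02, max_value=1.2),
        rot=st.floats(min_value=0.0, max_value=2 * np.pi),
    )
    def test_exact_on_circles_over_four_decades(self, log_r, theta, rot):
        # exactness across radii spanning 4 orders of magnitude, any rotation
        radius = 10.0**log_r
        ang = rot + np.array([-theta, 0.0, theta])
        pts = radius * np.column_stack([np.cos(ang), np.sin(ang)])
        k = three_point_curvature(pts[0], pts[1], pts[2])
        assert k == pytest.approx(1.0 / radius, rel=1e-9)

    def test_rigid_rotation_invariance(self):
        pts = np.array([[0.0, 0.0], [5.0, 5.0], [10.0, 0.0]])
        c, s = np.cos(0.7), np.sin(0.7)
        rot = pts @ np.array([[c, -s], [s, c]]).T + np.array([3.0, -2.0])
        k0 = three_point_curvature(*pts)
        k1 = three_point_curvature(*rot)
        assert k1 == pytest.approx(k0, rel=1e-12)


class TestSections:
    def test_reference_cross_section_closed_and_sized(self, small_mesh):
        sec = extract_section(small_mesh.vertices, small_mesh.faces, "cross", 0.0)
        r = np.linalg.norm(sec.points, axis=1)
        # mid-cross contour of the ovoid: radius between 1-d and 1+d
        assert r.min() > 0.8 and r.max() < 1.2
        assert len(sec.points) > 20

    def test_sagittal_section_extent(self, small_mesh):
        sec = extract_section(small_mesh.vertices, small_mesh.faces, "sagittal", 0.0)
        assert sec.points[:, 0].max() == pytest.approx(3.0, abs=0.02)
        assert sec.points[:, 0].min() == pytest.approx(-3.0, abs=0.02)

    def test_plane_missing_mesh_rejected(self, small_mesh):
        with pytest.raises(ValueError, match="misses"):
            extract_section(small_mesh.vertices, small_mesh.faces, "cross", 5.0)


class TestBucklingThreshold:
    def test_all_positive_not_reached(self):
        s = CurvatureSeries(np.array([0.0, 1.0, 2.0]), np.array([1.0, 0.8, 0.5]), "DV")
        assert buckling_threshold(s) is None

    def test_linear_interpolation_contract(self):
        # kappa(eps) = 1 - eps crosses zero at eps = 1 exactly
        eps = np.array([0.0, 0.4, 0.8, 1.2, 1.6])
        s = CurvatureSeries(eps, 1.0 - eps, "DV")
        assert buckling_threshold(s) == pytest.approx(1.0, abs=1e-12)

    def test_crossing_between_samples(self):
        s = CurvatureSeries(np.array([0.0, 2.0]), np.array([1.0, -3.0]), "DV")
        assert buckling_threshold(s) == pytest.approx(0.5)


class TestLoess:
    def test_linear_slope_exact(self):
        t = np.linspace(0, 10, 40)
        fitted, slope = loess_fit(t, 3.0 * t - 1.0, frac=0.3)
        np.testing.assert_allclose(slope, 3.0, atol=1e-9)
        np.testing.assert_allclose(fitted, 3.0 * t - 1.0, atol=1e-9)

    def test_exponential_initial_velocity(self):
        # d(t) = d0 (1 - e^(-t/tau)): max derivative d0/tau at t = 0
        d0, tau = 2.0, 1.5
        t = np.linspace(0, 3 * tau, 400)
        v = recoil_velocity((t, d0 * (1 - np.exp(-t / tau))), frac=0.1)
        assert v == pytest.approx(d0 / tau, rel=0.02)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            recoil_velocity(([0.0, 1.0], [0.0, 1.0]))

    def test_non_monotone_time_rejected(self):
        with pytest.raises(ValueError):
            recoil_velocity(([0.0, 2.0, 1.0], [0.0, 1.0, 2.0]))


class TestTrajectoryMetrics:
    def test_midline_curvature_reference_values(self, small_ramp):
        from furrowshell.furrow_metrics import midline_curvature

        kap = midline_curvature(small_ramp, axis="AP")
        kdv = midline_curvature(small_ramp, axis="DV")
        # reference ovoid: both convex, DV (short axis) more curved than AP
        assert kap.kappa[0] > 0 and kdv.kappa[0] > 0
        assert kdv.kappa[0] > kap.kappa[0]

    def test_furrow_depth_zero_at_reference(self, small_ramp):
        from furrowshell.furrow_metrics import furrow_apex_depth

        depth = furrow_apex_depth(small_ramp, [0.0, 1.0])
        ref = depth[depth["step"] == 0]
        assert np.abs(ref["depth"]).max() < 1e-9

    def test_depth_mirror_symmetric(self, small_ramp):
        from furrowshell.furrow_metrics import furrow_apex_depth

        depth = furrow_apex_depth(small_ramp, [-1.0, 1.0]).query("step == 2")
        d = depth.set_index("station")["depth"]
        assert d[-1.0] == pytest.approx(d[1.0], abs=1e-4)

    def test_station_outside_mesh_rejected(self, small_ramp):
        from furrowshell.furrow_metrics import furrow_apex_depth

        with pytest.raises(ValueError, match="stations"):
            furrow_apex_depth(small_ramp, [4.0])

    def test_distance_map_reference_equals_gap(self, small_ramp, small_vitelline):
        from furrowshell.furrow_metrics import distance_map_to_vitelline

        d0 = distance_map_to_vitelline(small_ramp.states[0], small_vitelline)
        np.testing.assert_allclose(d0, small_vitelline.gap, atol=1e-12)
        # a point on the vitelline has distance zero
        from furrowshell.geometry import OvoidShape  # noqa: F401
        surf_pt = small_ramp.mesh.vertices[:1] + small_vitelline.gap * (
            small_ramp.mesh.shape.surface_normal(small_ramp.mesh.vertices[:1])
        )
        assert distance_map_to_vitelline(surf_pt, small_vitelline)[0] == pytest.approx(
            0.0, abs=1e-6
        )

    def test_pole_distance_grows_under_contraction(self, small_ramp, small_vitelline):
        from furrowshell.furrow_metrics import pole_displacement

        series = pole_displacement(small_ramp, small_vitelline)
        assert series[0] == pytest.approx(small_vitelline.gap, abs=1e-9)
        assert (np.diff(series) >= -1e-12).all()
        assert series[-1] > series[0]

    def test_pole_distance_constant_without_prestrain(
        self, small_mesh, elastic, small_vitelline
    ):
        from furrowshell.shell_solver import RampSchedule, ramp_prestrain
        from furrowshell.furrow_metrics import pole_displacement

        traj = ramp_prestrain(
            small_mesh, elastic, small_vitelline, RampSchedule((0.0, 0.0)),
            tolerance=1e-3,
        )
        series = pole_displacement(traj, small_vitelline)
        assert np.ptp(series) < 1e-9

    def test_tissue_shortening_ventral_dv(self, small_ramp):
        from furrowshell.furrow_metrics import tissue_shortening

        # ventral DV markers (4 rows to each side) approach each other
        offset = 4 * 0.0788
        series = tissue_shortening(small_ramp, axis="DV", marker_offset=offset)
        assert series[0] == pytest.approx(2 * offset, rel=0.1)
        assert series[-1] < series[0]

    def test_tissue_shortening_dorsal_far_field(self, small_ramp):
        from furrowshell.furrow_metrics import tissue_shortening
        import furrowshell.furrow_metrics as fm

        # markers on the mid-sagittal AP contour far from the mesoderm change
        # little compared to the ventral DV contraction
        ap = tissue_shortening(small_ramp, axis="AP", marker_offset=1.1)
        rel_change = abs(ap[-1] - ap[0]) / ap[0]
        assert rel_change < 0.05

    def test_marker_offset_too_large_rejected(self, small_ramp):
        from furrowshell.furrow_metrics import tissue_shortening

        with pytest.raises(ValueError, match="offset"):
            tissue_shortening(small_ramp, axis="DV", marker_offset=10.0)
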