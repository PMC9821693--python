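"""Curve families: curvature formulas, generation, classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

import whiskerfit as wf
from whiskerfit import CesaroModel, ConfigurationError, EllipseModel


class TestCurvatureCartesian:
    @pytest.mark.parametrize(
        "dy,d2y,expected",
        [
            (0.0, 0.0, 0.0),  # straight line
            (0.0, 2.0, 2.0),  # y = x^2 at the origin
            (2.0, 2.0, 2.0 / 5.0**1.5),  # y = x^2 at x = 1
        ],
    )
    def test_closed_forms(self, dy, d2y, expected):
        np.testing.assert_allclose(wf.curvature_cartesian(dy, d2y), expected,
                                   atol=1e-12)


class TestDiscreteCurvature:
    def test_straight_line_is_flat(self):
        x = np.arange(0, 10, 0.25)
        kap = wf.discrete_curvature(np.stack([x, 0 * x], axis=-1))
        assert np.abs(kap).max() < 1e-9

    def test_circle_curvature(self):
        R = 20.0
        model = CesaroModel(A=0.0, B=1 / R)
        nodes, s = wf.generate_cesaro_curve(model, S=25.0, spacing=0.25)
        kap = wf.discrete_curvature(nodes, s)
        assert np.abs(kap[1:-1] - 1 / R).max() < 1e-3

    def test_cesaro_profile_recovered(self):
        # oracle: the generating equation kappa = A s + B
        model = CesaroModel(A=0.002, B=0.01)
        nodes, s = wf.generate_cesaro_curve(model, S=50.0, spacing=0.25)
        kap = wf.discrete_curvature(nodes, s)
        assert np.abs(kap - (0.002 * s + 0.01)).max() < 1e-3

    def test_curvature_consistency_across_coefficients(self):
        # generate -> measure must reproduce A s + B over the stated ranges
        for A, B in [(0.05, 0.5), (-0.05, 0.5), (0.01, -0.3), (-0.002, 0.0)]:
            model = CesaroModel(A=A, B=B)
            nodes, s = wf.generate_cesaro_curve(model, S=10.0, spacing=0.25)
            kap = wf.discrete_curvature(nodes, s)
            target = A * s + B
            tol = 1e-3 * max(np.abs(target).max(), 1.0)
            assert np.abs(kap - target).max() < tol, (A, B)

    def test_nonuniform_spacing_rejected(self):
        nodes = np.array([[0, 0], [0.25, 0], [1.0, 0], [1.25, 0]])
        with pytest.raises(ConfigurationError):
            wf.discrete_curvature(nodes)


class TestEllipseArc:
    def test_origin_and_quarter_point(self):
        m = EllipseModel(A=30.0, B=10.0, t_end=np.pi / 2)
        np.testing.assert_allclose(wf.ellipse_arc(m, 0.0), [0, 0], atol=1e-12)
        np.testing.assert_allclose(wf.ellipse_arc(m, np.pi / 2), [30, 10],
                                   atol=1e-12)

    def test_points_satisfy_ellipse_equation(self):
        m = EllipseModel(A=25.0, B=8.0, t_end=2.5)
        t = np.linspace(0, 2.5, 100)
        pts = wf.ellipse_arc(m, t)
        lhs = pts[:, 0] ** 2 / m.A**2 + (pts[:, 1] - m.B) ** 2 / m.B**2
        assert np.abs(lhs - 1).max() < 1e-12

    def test_circle_limit_curvature(self):
        # kappa(x, y) with centered ordinate reduces to 1/R on a circle
        R = 12.0
        m = EllipseModel(A=R, B=R, t_end=np.pi)
        rng = np.random.default_rng(0)
        t = rng.uniform(0, np.pi, 100)
        np.testing.assert_allclose(wf.ellipse_curvature(m, t), 1 / R, rtol=1e-9)

    def test_t_outside_range_rejected(self):
        with pytest.raises(ConfigurationError):
            wf.ellipse_arc(EllipseModel(10, 5, t_end=1.0), 2.0)


class TestQuarterFraction:
    @pytest.mark.parametrize("t_end,expected", [
        (np.pi / 2, 100.0), (np.pi / 4, 50.0), (0.6 * np.pi, 120.0),
    ])
    def test_fraction(self, t_end, expected):
        m = EllipseModel(A=20, B=10, t_end=t_end)
        np.testing.assert_allclose(wf.quarter_fraction(m), expected, atol=1e-9)
        if expected > 100:
            assert wf.quarter_fraction(m) > 100  # backwards whisker flag


class TestGenerateCesaroCurve:
    def test_zero_curvature_is_straight(self):
        nodes, s = wf.generate_cesaro_curve(CesaroModel(0.0, 0.0, psi0=0.5), 10.0)
        direction = nodes[-1] / np.hypot(*nodes[-1])
        np.testing.assert_allclose(direction, [np.cos(0.5), np.sin(0.5)],
                                   atol=1e-12)

    def test_constant_curvature_is_circle(self):
        # B = 0.1/mm -> radius 10 mm; arc of length 5*pi ends at (10, 10)
        nodes, s = wf.generate_cesaro_curve(CesaroModel(0.0, 0.1), 5 * np.pi,
                                            spacing=0.25)
        np.testing.assert_allclose(nodes[-1], [10.0, 10.0], atol=1e-9)

    def test_clothoid_endpoint_matches_quadrature(self):
        # oracle: adaptive quadrature of the Fresnel-type integrals
        nodes, s = wf.generate_cesaro_curve(CesaroModel(1.0, 0.0), 1.0,
                                            spacing=0.01)
        x_ref = quad(lambda u: np.cos(u * u / 2), 0, 1, epsabs=1e-13)[0]
        y_ref = quad(lambda u: np.sin(u * u / 2), 0, 1, epsabs=1e-13)[0]
        np.testing.assert_allclose(nodes[-1], [x_ref, y_ref], atol=1e-8)

    def test_total_length_and_spacing(self):
        nodes, s = wf.generate_cesaro_curve(CesaroModel(0.003, 0.02), 33.4)
        assert s[-1] == pytest.approx(33.4)
        np.testing.assert_allclose(np.diff(s)[:-1], 0.25, atol=1e-12)


class TestUniversalSpiral:
    def test_origin_and_tangent(self):
        np.testing.assert_allclose(wf.universal_spiral_point(0.0), [0, 0],
                                   atol=1e-15)
        # tangent at origin is +x: small steps move along x
        p = wf.universal_spiral_point(1e-4)
        assert p[0] == pytest.approx(1e-4, rel=1e-6)
        assert abs(p[1]) < 1e-8

    def test_defining_property_kappa_equals_s(self):
        s = np.arange(0.0, 2.0, 0.01)
        pts = wf.universal_spiral_point(s)
        kap = wf.discrete_curvature(pts, s)
        i = np.argmin(np.abs(s - 1.0))
        assert kap[i] == pytest.approx(1.0, abs=1e-3)

    def test_point_matches_quadrature(self):
        x_ref = quad(lambda u: np.cos(u * u / 2), 0, 1, epsabs=1e-13)[0]
        y_ref = quad(lambda u: np.sin(u * u / 2), 0, 1, epsabs=1e-13)[0]
        np.testing.assert_allclose(wf.universal_spiral_point(1.0),
                                   [x_ref, y_ref], atol=1e-12)

    def test_odd_symmetry(self):
        s = np.linspace(0.1, 3.0, 17)
        np.testing.assert_allclose(wf.universal_spiral_point(-s),
                                   -wf.universal_spiral_point(s), atol=1e-14)


class TestClassifyShape:
    @pytest.mark.parametrize(
        "A,B,S,quadrant,inflection,all_pos",
        [
            (0.001, 0.01, 10.0, 1, False, True),
            (-0.001, 0.02, 10.0, 4, False, True),  # kappa(S)=0.01>0
            (0.002, -0.01, 10.0, 2, True, False),  # inflection at s=5
            (-0.002, -0.01, 10.0, 3, False, False),
        ],
    )
    def test_examples(self, A, B, S, quadrant, inflection, all_pos):
        sc = wf.classify_shape(CesaroModel(A, B), S)
        assert sc.quadrant == quadrant
        assert sc.inflection_inside == inflection
        assert sc.all_positive == all_pos

    @settings(derandomize=True, max_examples=200)
    @given(
        A=st.floats(-0.1, 0.1, allow_nan=False),
        B=st.floats(-1.0, 1.0, allow_nan=False),
        S=st.floats(0.1, 300.0, allow_nan=False),
    )
    def test_total_and_single_valued(self, A, B, S):
        sc = wf.classify_shape(CesaroModel(A, B), S)
        assert sc.quadrant in (1, 2, 3, 4)
        if sc.inflection_inside:
            assert 0 < -B / A < S


class TestMeanCurvature:
    def test_constant_curvature(self):
        assert wf.mean_curvature(CesaroModel(0.0, 0.07), 12.0) == pytest.approx(0.07)

    def test_linear_profile(self):
        assert wf.mean_curvature(CesaroModel(0.002, 0.01), 10.0) == pytest.approx(0.02)

    def test_matches_numeric_average(self):
        # oracle: trapezoidal average of the linear curvature profile
        m = CesaroModel(0.013, -0.2)
        s = np.linspace(0, 37.0, 100001)
        numeric = np.trapezoid(m.kappa(s), s) / 37.0
        assert wf.mean_curvature(m, 37.0) == pytest.approx(numeric, abs=1e-9)
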