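"""Orthogonal-distance fits: projection, recovery, invariances."""

import numpy as np
import pytest

import whiskerfit as wf
from whiskerfit import (
    CesaroModel,
    EllipseModel,
    FitConfig,
    FractionalModel,
    PolynomialModel,
)

from conftest import make_whisker, straight_trace


def brute_force_distance(model, q, t_max, n=100_000, alpha=0.0):
    """Independent oracle: dense parameter sweep of the point-to-curve distance."""
    t = np.linspace(0.0, t_max, n)
    if isinstance(model, PolynomialModel) or isinstance(model, FractionalModel):
        pts = np.stack([t, np.asarray(model.y(t))], axis=-1)
    else:
        pts = np.stack([model.A * np.sin(t), model.B * (1 - np.cos(t))], axis=-1)
    c, s = np.cos(alpha), np.sin(alpha)
    pts = pts @ np.array([[c, s], [-s, c]])
    return float(np.min(np.hypot(pts[:, 0] - q[0], pts[:, 1] - q[1])))


class TestProjectPoint:
    def test_point_on_curve_has_zero_residual(self):
        m = PolynomialModel((2,), (0.05,))
        t_star, r = wf.project_point(m, (2.0, 0.05 * 4.0), t_max=10.0)
        assert abs(r) < 1e-9
        assert t_star == pytest.approx(2.0, abs=1e-6)

    def test_parabola_apex_point_matches_brute_force(self):
        m = PolynomialModel((2,), (1.0,))
        q = (0.0, 1.0)
        _, r = wf.project_point(m, q, t_max=5.0)
        assert abs(abs(r) - brute_force_distance(m, q, 5.0)) < 1e-6

    def test_sign_convention(self):
        m = PolynomialModel((2,), (0.02,))
        _, r_above = wf.project_point(m, (5.0, 5.0), t_max=20.0)
        _, r_below = wf.project_point(m, (5.0, -5.0), t_max=20.0)
        assert r_above > 0 > r_below

    @pytest.mark.parametrize("family", ["poly", "frac", "ellipse"])
    def test_random_points_match_brute_force(self, family):
        rng = np.random.default_rng(42)
        for _ in range(25):
            if family == "poly":
                m = PolynomialModel((2, 3), tuple(rng.uniform(-0.01, 0.03, 2)))
                t_max = 30.0
            elif family == "frac":
                m = FractionalModel(rng.uniform(1.5, 3.5), rng.uniform(1e-4, 0.05))
                t_max = 30.0
            else:
                m = EllipseModel(rng.uniform(5, 40), rng.uniform(2, 20),
                                 t_end=0.995 * np.pi)
                t_max = 0.995 * np.pi
            q = rng.uniform(-10, 40, 2)
            _, r = wf.project_point(m, q, t_max=t_max)
            assert abs(abs(r) - brute_force_distance(m, q, t_max)) < 1e-6


class TestPolynomialFit:
    def test_noise_free_quadratic_recovery(self, quadratic_trace, fit_config):
        fit = wf.fit_polynomial(quadratic_trace, (2,), fit_config)
        assert fit.model.coeffs[0] == pytest.approx(0.02, rel=1e-6)
        assert fit.rss < 1e-10

    def test_straight_line_gives_zero_coefficient(self, fit_config):
        fit = wf.fit_polynomial(straight_trace(length=30.0), (2,), fit_config)
        assert abs(fit.model.coeffs[0]) < 1e-8
        assert fit.rss < 1e-12

    def test_rotation_within_bounds_absorbed_by_alpha(self, quadratic_trace,
                                                      fit_config):
        fit0 = wf.fit_polynomial(quadratic_trace, (2,), fit_config)
        rot = wf.standardize(quadratic_trace, alpha=0.15)
        fit1 = wf.fit_polynomial(rot, (2,), fit_config)
        assert abs(fit0.rss - fit1.rss) < 1e-8

    def test_pure_cubic_recovered_and_a2_vanishes(self, fit_config):
        tr = make_whisker("poly", {"orders": (3,), "coeffs": (1e-4,)}, S=40).trace
        fits = wf.fit_polynomials(tr, [(3,), (2, 3)], fit_config)
        assert fits[(3,)].model.coeffs[0] == pytest.approx(1e-4, rel=1e-4)
        a2 = fits[(2, 3)].model.coeffs[0]
        assert abs(a2) < 1e-6

    def test_nested_models_do_not_increase_rss(self, fit_config):
        tr = make_whisker("frac", {"beta": 2.5, "a_beta": 0.01}, S=30,
                          noise_dpi=6400).trace
        fits = wf.fit_polynomials(tr, config=fit_config)
        assert fits[(2, 3)].rss <= fits[(2,)].rss + 1e-9
        assert fits[(2, 3, 4)].rss <= fits[(2, 3)].rss + 1e-9
        assert fits[(2, 3, 4, 5)].rss <= fits[(2, 3, 4)].rss + 1e-9

    def test_quadratic_and_cubic_residuals_skew_oppositely(self):
        # a beta=2.5 whisker lies between the quadratic and cubic curves, so
        # in fixed standard orientation the two single-term fits run on
        # opposite sides of the whisker
        tr = make_whisker("frac", {"beta": 2.5, "a_beta": 0.01}, S=30).trace
        cfg = wf.FitConfig(alpha_bounds=(-1e-9, 1e-9), seed=1, multistart_count=2)
        f2 = wf.fit_polynomial(tr, (2,), cfg)
        f3 = wf.fit_polynomial(tr, (3,), cfg)
        assert np.mean(f2.signed_residuals) * np.mean(f3.signed_residuals) < 0


class TestFractionalFit:
    def test_exponent_recovery(self, fit_config):
        tr = make_whisker("frac", {"beta": 2.5, "a_beta": 0.01}).trace
        fit = wf.fit_fractional(tr, fit_config)
        assert fit.model.beta == pytest.approx(2.5, abs=0.02)
        assert fit.model.a_beta == pytest.approx(0.01, rel=0.01)

    def test_quadratic_is_recovered_as_beta_two(self, quadratic_trace, fit_config):
        fit = wf.fit_fractional(quadratic_trace, fit_config)
        assert fit.model.beta == pytest.approx(2.0, abs=0.02)

    def test_species_fit_reduces_to_single_whisker(self, fit_config):
        tr = make_whisker("frac", {"beta": 2.7, "a_beta": 0.004}).trace
        single = wf.fit_fractional(tr, fit_config)
        species = wf.fit_fractional_species([tr], fit_config)
        assert species.beta_star == pytest.approx(single.model.beta, abs=5e-3)

    def test_species_shared_exponent_recovery(self, fit_config):
        rng = np.random.default_rng(3)
        traces = []
        for i in range(6):
            S = float(rng.uniform(20, 40))
            a = 0.6 * S ** (1 - 2.4) * float(np.exp(0.2 * rng.standard_normal()))
            traces.append(
                make_whisker("frac", {"beta": 2.4, "a_beta": a}, S=S, seed=i).trace
            )
        sf = wf.fit_fractional_species(traces, fit_config)
        assert sf.beta_star == pytest.approx(2.4, abs=0.03)
        assert all(f.model.beta == sf.beta_star for f in sf.fits)


class TestEllipseFit:
    def test_quarter_ellipse_recovery(self, fit_config):
        S = wf.ellipse_arc_length(EllipseModel(30, 10), np.pi / 2)
        tr = make_whisker("ellipse", {"A": 30.0, "B": 10.0}, S=S).trace
        fit = wf.fit_ellipse(tr, fit_config)
        assert fit.model.A == pytest.approx(30.0, rel=0.01)
        assert fit.model.B == pytest.approx(10.0, rel=0.01)
        assert wf.quarter_fraction(fit.model) == pytest.approx(100.0, abs=1.0)

    def test_circular_arc_fraction(self, fit_config):
        R = 25.0
        S = 0.4 * (np.pi / 2) * R  # 40% of a quarter circle
        tr = make_whisker("ellipse", {"A": R, "B": R}, S=S).trace
        fit = wf.fit_ellipse(tr, fit_config)
        assert fit.model.A == pytest.approx(R, rel=0.01)
        assert fit.model.B == pytest.approx(R, rel=0.01)
        assert wf.quarter_fraction(fit.model) == pytest.approx(40.0, abs=2.0)

    def test_backwards_whisker_exceeds_quarter(self, fit_config):
        S = wf.ellipse_arc_length(EllipseModel(20, 8), 0.7 * np.pi)
        tr = make_whisker("ellipse", {"A": 20.0, "B": 8.0}, S=S).trace
        fit = wf.fit_ellipse(tr, fit_config)
        assert wf.quarter_fraction(fit.model) > 100.0


class TestCesaroFit:
    def test_circular_arc(self, fit_config):
        tr = make_whisker("cesaro", {"A": 0.0, "B": 0.1}, S=15.0).trace
        fit = wf.fit_cesaro(tr, fit_config)
        assert abs(fit.model.A) < 1e-5
        assert fit.model.B == pytest.approx(0.1, abs=1e-3)

    def test_coefficient_recovery(self, fit_config):
        tr = make_whisker("cesaro", {"A": 0.001, "B": 0.01}, S=50.0).trace
        fit = wf.fit_cesaro(tr, fit_config)
        assert fit.model.A == pytest.approx(0.001, rel=0.01)
        assert fit.model.B == pytest.approx(0.01, rel=0.01)

    def test_rigid_motion_invariance(self, fit_config):
        base = wf.SyntheticSpec("cesaro", {"A": 0.001, "B": 0.01}, S=50.0)
        moved = wf.SyntheticSpec("cesaro", {"A": 0.001, "B": 0.01}, S=50.0,
                                 rotation=np.deg2rad(37), translation=(12.0, -8.0))
        tr0 = wf.resample_trace(wf.generate_whisker(base).points)
        tr1 = wf.resample_trace(wf.generate_whisker(moved).points)
        f0 = wf.fit_cesaro(tr0, fit_config)
        f1 = wf.fit_cesaro(tr1, fit_config)
        assert f0.model.A == pytest.approx(f1.model.A, abs=1e-6)
        assert f0.model.B == pytest.approx(f1.model.B, abs=1e-6)


class TestFitInvariants:
    def test_orthogonality_at_convergence(self, fit_config):
        tr = make_whisker("frac", {"beta": 2.5, "a_beta": 0.01}, S=30,
                          noise_dpi=6400).trace
        fit = wf.fit_polynomial(tr, (2, 3), fit_config)
        curve = wf.fitting._PolyCurve((2, 3), 100.0)
        theta = np.asarray(fit.model.coeffs)
        Qr = wf.fitting._rotate(tr.nodes, -fit.alpha)
        p = curve.xy(fit.t_params, theta)
        dp = curve.dxy(fit.t_params, theta)
        r = Qr - p
        nr = np.hypot(r[:, 0], r[:, 1])
        ndp = np.hypot(dp[:, 0], dp[:, 1])
        mask = nr > 1e-9
        cosang = np.abs(np.einsum("ij,ij->i", r, dp))[mask] / (nr * ndp)[mask]
        assert cosang.max() < 1e-4

    def test_determinism_same_seed_same_theta(self, fit_config):
        tr = make_whisker("cesaro", {"A": 0.002, "B": 0.015}, S=35,
                          noise_dpi=6400).trace
        f1 = wf.fit_parametric(tr, "poly23", fit_config)
        f2 = wf.fit_parametric(tr, "poly23", fit_config)
        assert np.array_equal(f1.theta, f2.theta)
        c1 = wf.fit_cesaro(tr, fit_config)
        c2 = wf.fit_cesaro(tr, fit_config)
        assert np.array_equal(c1.theta, c2.theta)

    def test_scaling_consistency(self, fit_config):
        lam = 2.0
        tr = make_whisker("cesaro", {"A": 0.002, "B": 0.02}, S=30.0).trace
        scaled = wf.resample_trace(tr.nodes * lam, spacing=0.25)
        f = wf.fit_cesaro(tr, fit_config)
        g = wf.fit_cesaro(scaled, fit_config)
        assert g.model.B == pytest.approx(f.model.B / lam, rel=0.01)
        assert g.model.A == pytest.approx(f.model.A / lam**2, rel=0.01)

    def test_fractional_scaling_consistency(self, fit_config):
        lam = 1.5
        tr = make_whisker("frac", {"beta": 2.5, "a_beta": 0.01}, S=25.0).trace
        scaled_nodes = tr.nodes * lam
        scaled = wf.resample_trace(scaled_nodes, spacing=0.25)
        f = wf.fit_fractional(tr, fit_config)
        g = wf.fit_fractional(scaled, fit_config)
        assert g.model.beta == pytest.approx(f.model.beta, abs=0.02)
        expected_a = f.model.a_beta * lam ** (1 - f.model.beta)
        assert g.model.a_beta == pytest.approx(expected_a, rel=0.02)

    def test_unknown_family_rejected(self, quadratic_trace, fit_config):
        with pytest.raises(wf.ConfigurationError):
            wf.fit_parametric(quadratic_trace, "spline", fit_config)
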