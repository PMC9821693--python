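"""End-to-end validation studies run on synthetic whisker data.

Each function generates its own data from a seed, runs the relevant slice
of the pipeline (preprocess -> fit -> summarize), and returns measured
quantities.  The test suite asserts tolerances on these outputs and the
reproduction script reports them; both therefore exercise exactly the same
code paths a study of real scanned whiskers would.

Problem sizes default to desk scale (tens of whiskers per family); see the
methods note for the rationale behind each study's design.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import (
    FitConfig,
    fit_cesaro,
    fit_ellipse,
    fit_fractional,
    fit_polynomial,
    fit_polynomials,
    project_point,
)
from .models import (
    CesaroModel,
    EllipseModel,
    FractionalModel,
    PolynomialModel,
    classify_shape,
    discrete_curvature,
    ellipse_arc_length,
    generate_cesaro_curve,
)
from .selection import SELECTION_LADDER, select_polynomial_order
from .spiral import conform, conform_nodes
from .synthetic import ArraySpec, SyntheticSpec, generate_whisker
from .traces import preprocess

#: orientation envelope used for synthetic whiskers generated in the
#: standard frame: wide enough to contain both zero (the generating pose)
#: and the preprocessing alignment rotation
ALPHA_ENVELOPE = (-0.35, 0.35)


def _config(seed: int) -> FitConfig:
    return FitConfig(alpha_bounds=ALPHA_ENVELOPE, seed=seed, multistart_count=2)


def _prep(spec: SyntheticSpec, smooth: bool):
    raw = generate_whisker(spec)
    return preprocess(raw, window_mm=4.0 if smooth else None)


# ---------------------------------------------------------------------------
# Parameter recovery
# ---------------------------------------------------------------------------

def parameter_recovery_study(seed: int = 0, n_per_family: int = 50,
                             noise_dpi: float | None = None) -> pd.DataFrame:
    """Generate whiskers from every family, preprocess, fit, compare.

    Noise-free input skips the smoothing pass (there is nothing to
    denoise); pixelated input gets the full smooth+resample pipeline, and
    whisker lengths are kept >= 20 mm.  Returns one row per recovered
    parameter with its relative (or, for beta, absolute) error.
    """
    rng = np.random.default_rng(seed)
    cfg = _config(seed)
    smooth = noise_dpi is not None
    rows = []
    for i in range(n_per_family):
        # polynomial (2, 3)
        a2, a3 = rng.uniform(0.005, 0.02), rng.uniform(5e-5, 3e-4)
        S = rng.uniform(20, 40)
        pre = _prep(SyntheticSpec("poly", {"orders": (2, 3), "coeffs": (a2, a3)},
                                  S=S, noise_dpi=noise_dpi, seed=seed * 7919 + i),
                    smooth)
        fit = fit_polynomial(pre.trace, (2, 3), cfg)
        rows.append(("poly", "a2", a2, fit.model.coeffs[0],
                     abs(fit.model.coeffs[0] / a2 - 1)))
        rows.append(("poly", "a3", a3, fit.model.coeffs[1],
                     abs(fit.model.coeffs[1] / a3 - 1)))

        # fractional exponent
        beta = rng.uniform(1.8, 3.2)
        S = rng.uniform(20, 40)
        a_b = 0.6 * S ** (1 - beta) * np.exp(0.2 * rng.standard_normal())
        pre = _prep(SyntheticSpec("frac", {"beta": beta, "a_beta": a_b}, S=S,
                                  noise_dpi=noise_dpi, seed=seed * 7919 + i),
                    smooth)
        fit = fit_fractional(pre.trace, cfg)
        rows.append(("frac", "beta", beta, fit.model.beta,
                     abs(fit.model.beta - beta)))
        rows.append(("frac", "a_beta", a_b, fit.model.a_beta,
                     abs(fit.model.a_beta / a_b - 1)))

        # ellipse
        A, B = rng.uniform(15, 40), rng.uniform(5, 15)
        frac_quarter = rng.uniform(0.6, 1.1)
        S = frac_quarter * ellipse_arc_length(EllipseModel(A, B), np.pi / 2)
        pre = _prep(SyntheticSpec("ellipse", {"A": A, "B": B}, S=S,
                                  noise_dpi=noise_dpi, seed=seed * 7919 + i),
                    smooth)
        fit = fit_ellipse(pre.trace, cfg)
        rows.append(("ellipse", "A", A, fit.model.A, abs(fit.model.A / A - 1)))
        rows.append(("ellipse", "B", B, fit.model.B, abs(fit.model.B / B - 1)))

        # Cesaro
        Ac = rng.uniform(5e-4, 3e-3) * rng.choice([-1.0, 1.0], p=[0.2, 0.8])
        Bc = rng.uniform(0.008, 0.03)
        S = rng.uniform(25, 50)
        pre = _prep(SyntheticSpec("cesaro", {"A": Ac, "B": Bc}, S=S,
                                  noise_dpi=noise_dpi,
                                  rotation=rng.uniform(-np.pi, np.pi),
                                  translation=tuple(rng.uniform(-30, 30, 2)),
                                  seed=seed * 7919 + i),
                    smooth)
        fit = fit_cesaro(pre.trace, cfg)
        # a concave-up flip during standardization mirrors the whisker,
        # negating its signed curvature and hence both coefficients
        sgn = -1.0 if pre.trace.flipped else 1.0
        rows.append(("cesaro", "A", sgn * Ac, fit.model.A,
                     abs(fit.model.A / (sgn * Ac) - 1)))
        rows.append(("cesaro", "B", sgn * Bc, fit.model.B,
                     abs(fit.model.B / (sgn * Bc) - 1)))
    return pd.DataFrame(rows, columns=["family", "param", "true", "fitted", "err"])


# ---------------------------------------------------------------------------
# Projection oracle agreement
# ---------------------------------------------------------------------------

def projection_agreement_study(seed: int = 0, n_pairs: int = 100,
                               brute_n: int = 100_000) -> pd.DataFrame:
    """Compare project_point distances against dense brute-force sweeps."""
    rng = np.random.default_rng(seed)
    rows = []
    for family in ("poly", "frac", "ellipse"):
        worst = 0.0
        for _ in range(n_pairs):
            # whisker-scale curves: y stays within tens of mm over the
            # domain, so the brute-force grid is dense in arc length too
            if family == "poly":
                model = PolynomialModel(
                    (2, 3), (rng.uniform(-0.005, 0.02), rng.uniform(-1e-4, 3e-4)))
                t_max = 30.0
            elif family == "frac":
                beta = rng.uniform(1.5, 3.5)
                a_b = 0.6 * 30.0 ** (1 - beta) * np.exp(0.3 * rng.standard_normal())
                model = FractionalModel(beta, a_b)
                t_max = 30.0
            else:
                model = EllipseModel(rng.uniform(5, 40), rng.uniform(2, 20),
                                     t_end=0.995 * np.pi)
                t_max = 0.995 * np.pi
            q = rng.uniform(-10, 40, 2)
            _, r = project_point(model, q, t_max=t_max)
            t = np.linspace(0.0, t_max, brute_n)
            if isinstance(model, EllipseModel):
                pts = np.stack([model.A * np.sin(t), model.B * (1 - np.cos(t))],
                               axis=-1)
            else:
                pts = np.stack([t, np.asarray(model.y(t))], axis=-1)
            brute = float(np.min(np.hypot(pts[:, 0] - q[0], pts[:, 1] - q[1])))
            worst = max(worst, abs(abs(r) - brute))
        rows.append((family, worst))
    return pd.DataFrame(rows, columns=["family", "max_abs_deviation_mm"])


# ---------------------------------------------------------------------------
# Curvature and spiral identities
# ---------------------------------------------------------------------------

def curvature_consistency_study(seed: int = 0, n_draws: int = 30,
                                S: float = 10.0) -> float:
    """Max |measured - A s - B| over random coefficients in the stated ranges."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_draws):
        A = rng.uniform(-0.05, 0.05)
        B = rng.uniform(-0.5, 0.5)
        nodes, s = generate_cesaro_curve(CesaroModel(A, B), S, spacing=0.25)
        kap = discrete_curvature(nodes, s)
        worst = max(worst, float(np.abs(kap - (A * s + B)).max()))
    return worst


def _kabsch(src: np.ndarray, dst: np.ndarray, allow_reflection: bool) -> np.ndarray:
    sc, dc = src.mean(axis=0), dst.mean(axis=0)
    H = (src - sc).T @ (dst - dc)
    U, _, Vt = np.linalg.svd(H)
    if allow_reflection:
        R = Vt.T @ U.T
    else:
        d = np.sign(np.linalg.det(Vt.T @ U.T))
        R = Vt.T @ np.diag([1.0, d]) @ U.T
    return (src - sc) @ R.T + dc


def conformation_study(seed: int = 0, n_draws: int = 20) -> dict:
    """Scaled-whisker-on-spiral identity for random (A != 0, B) pairs.

    Returns the worst geometric deviation of the rescaled whisker from the
    universal spiral and the worst algebraic error of the segment
    endpoints against [B/sqrt(A), sqrt(A) S + B/sqrt(A)].
    """
    rng = np.random.default_rng(seed)
    worst_geom, worst_alg = 0.0, 0.0
    for _ in range(n_draws):
        A = rng.uniform(1e-4, 0.1) * rng.choice([-1.0, 1.0])
        B = rng.uniform(-0.5, 0.5)
        S = rng.uniform(5, 15)
        model = CesaroModel(A, B)
        nodes, s = generate_cesaro_curve(model, S, spacing=0.25)
        scaled = nodes * np.sqrt(abs(A))
        if A < 0:
            scaled = scaled * [1.0, -1.0]
        s_hat, spiral_pts = conform_nodes(model, S, spacing=0.25)
        aligned = _kabsch(scaled, spiral_pts, allow_reflection=False)
        worst_geom = max(worst_geom, float(np.abs(aligned - spiral_pts).max()))
        seg = conform(model, S)
        root = np.sqrt(abs(A))
        sign = 1.0 if A > 0 else -1.0
        worst_alg = max(
            worst_alg,
            abs(seg.s_hat_start - B / root),
            abs(seg.s_hat_end - (B / root + sign * root * S)),
        )
    return {"max_spiral_deviation": worst_geom, "max_endpoint_error": worst_alg}


# ---------------------------------------------------------------------------
# Polynomial order selection on populations
# ---------------------------------------------------------------------------

def order_selection_study(seed: int = 0, n_populations: int = 3,
                          n_whiskers: int = 12) -> pd.DataFrame:
    """Apply the 90% rule to quadratic and quadratic+cubic populations.

    Whiskers carry half-pixel pixelation noise at 6,400 dpi.  Per
    population the RSS of each ladder order set is summed over whiskers and
    walked with the selection rule.  Returns one row per population with
    its kind and chosen order set.
    """
    rng = np.random.default_rng(seed)
    cfg = _config(seed)
    rows = []
    for kind in ("quadratic", "mixture"):
        for p in range(n_populations):
            rss_sums = {orders: 0.0 for orders in SELECTION_LADDER}
            for w in range(n_whiskers):
                a2 = rng.uniform(0.005, 0.02)
                S = rng.uniform(20, 40)
                if kind == "quadratic":
                    params = {"orders": (2,), "coeffs": (a2,)}
                else:
                    params = {"orders": (2, 3), "coeffs": (a2, rng.uniform(1e-4, 3e-4))}
                pre = _prep(SyntheticSpec("poly", params, S=S, noise_dpi=6400,
                                          seed=seed * 104729 + p * 1000 + w),
                            smooth=True)
                fits = fit_polynomials(pre.trace, SELECTION_LADDER, cfg)
                for orders, fr in fits.items():
                    rss_sums[orders] += fr.rss
            sel = select_polynomial_order([rss_sums[o] for o in SELECTION_LADDER])
            rows.append((kind, p, sel.chosen_orders, sel.rss_by_order))
    return pd.DataFrame(rows, columns=["kind", "population", "chosen", "rss"])


# ---------------------------------------------------------------------------
# Species separability
# ---------------------------------------------------------------------------

def separability_power_study(seed: int = 0, n: int = 100,
                             means=(2.2, 2.8), sd: float = 0.15) -> float:
    """p-value of the pooled t-test between two synthetic species' betas."""
    from .selection import pairwise_separability
    from .synthetic import generate_population

    a = generate_population(ArraySpec(beta_mean=means[0], beta_sd=sd,
                                      seed=seed * 2 + 1), n)[1]
    b = generate_population(ArraySpec(beta_mean=means[1], beta_sd=sd,
                                      seed=seed * 2 + 2), n)[1]
    m = pairwise_separability({"a": a["beta"], "b": b["beta"]})
    return float(m.p_values[0, 1])


def pvalue_uniformity_study(seed: int = 0, n_reps: int = 100,
                            n: int = 100) -> dict:
    """p-values under the null (identical beta distributions) across seeds.

    Returns the Kolmogorov-Smirnov p-value of the replicate p-values
    against Uniform(0, 1); a healthy test statistic leaves it large.
    """
    from .selection import pairwise_separability
    from .synthetic import generate_population

    pvals = []
    for r in range(n_reps):
        a = generate_population(ArraySpec(beta_mean=2.5, beta_sd=0.15,
                                          seed=seed * 100000 + 2 * r), n)[1]
        b = generate_population(ArraySpec(beta_mean=2.5, beta_sd=0.15,
                                          seed=seed * 100000 + 2 * r + 1), n)[1]
        m = pairwise_separability({"a": a["beta"], "b": b["beta"]})
        pvals.append(float(m.p_values[0, 1]))
    ks = stats.kstest(pvals, "uniform")
    return {"p_values": np.asarray(pvals), "ks_pvalue": float(ks.pvalue)}


# ---------------------------------------------------------------------------
# Cesaro shape-class percentages
# ---------------------------------------------------------------------------

def quadrant_study(seed: int = 0, n_whiskers: int = 50) -> dict:
    """Full pipeline to shape-class percentages on a Cesaro population.

    Generates whiskers in arbitrary rigid poses with pixelation noise,
    preprocesses, fits the Cesaro model, classifies shapes, and returns the
    quadrant percentages plus the all-positive-curvature fraction, both as
    fitted and as implied by the generator's ground truth.
    """
    from .synthetic import generate_population

    cfg = _config(seed)
    spec = ArraySpec(seed=seed, noise_dpi=6400)
    traces, truth = generate_population(spec, n_whiskers, family="cesaro")
    recs = []
    for raw, (_, row) in zip(traces, truth.iterrows()):
        pre = preprocess(raw, window_mm=4.0)
        fit = fit_cesaro(pre.trace, cfg)
        S = pre.trace.S
        sc_fit = classify_shape(fit.model, S)
        # the concave-up flip mirrors the whisker and negates its signed
        # curvature; the published statistics are for standard orientation
        sgn = -1.0 if pre.trace.flipped else 1.0
        sc_true = classify_shape(CesaroModel(sgn * row["A"], sgn * row["B"]), S)
        recs.append({
            "quadrant_fit": sc_fit.quadrant, "quadrant_true": sc_true.quadrant,
            "all_positive_fit": sc_fit.all_positive,
            "all_positive_true": sc_true.all_positive,
        })
    df = pd.DataFrame(recs)
    out = {}
    for q in (1, 2, 3, 4):
        out[f"q{q}_fit_pct"] = 100.0 * float((df.quadrant_fit == q).mean())
        out[f"q{q}_true_pct"] = 100.0 * float((df.quadrant_true == q).mean())
    out["all_positive_fit_pct"] = 100.0 * float(df.all_positive_fit.mean())
    out["all_positive_true_pct"] = 100.0 * float(df.all_positive_true.mean())
    out["n"] = len(df)
    return out
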