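"""Orthogonal-distance fitting of whisker traces to the four curve families.

Every Cartesian family (polynomial, fractional exponent, ellipse) is fit by
two alternating optimizations: (i) each observed node is orthogonally
projected onto the current parametric curve, and (ii) the model
coefficients -- including the orientation nuisance angle alpha, constrained
to the proximal-alignment bounds -- are updated by constrained least
squares on the orthogonal distances, with the projections refreshed by
warm-started Newton steps as the parameters move.  The cycle repeats until
the residual sum of squares (RSS) stops changing under a full safeguarded
re-projection.

The Cesaro family is coordinate free: a curve of equal arc length generated
from kappa(s) = A s + B is anchored at the trace base and compared node by
node at equal arc coordinates, minimizing the summed Euclidean distance;
the initial tangent angle psi0 absorbs orientation.

The fractional-exponent model is fit by a nested search: the inner problem
optimizes (a_beta, alpha) at fixed beta by the alternation above; the outer
problem selects beta by minimizing the squared residual *sum* (sum r_i)^2,
a bias-sensitive criterion that vanishes only when the curve threads
through the point cloud rather than running systematically to one side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares

from ._exceptions import ConfigurationError, FitError
from .models import (
    CesaroModel,
    EllipseModel,
    FractionalModel,
    PolynomialModel,
    _cesaro_xy,
    discrete_curvature,
)
from .traces import OrientationBounds, Trace

POLY_ORDER_SETS: tuple[tuple[int, ...], ...] = (
    (2,), (3,), (2, 3), (2, 3, 4), (2, 3, 4, 5),
)

FAMILY_TAGS = (
    "poly2", "poly3", "poly23", "poly234", "poly2345", "frac", "ellipse", "cesaro",
)

_POLY_TAG_ORDERS = {
    "poly2": (2,), "poly3": (3,), "poly23": (2, 3),
    "poly234": (2, 3, 4), "poly2345": (2, 3, 4, 5),
}


# ---------------------------------------------------------------------------
# Configuration and results
# ---------------------------------------------------------------------------

@dataclass
class FitConfig:
    """Convergence controls shared by all families.

    ``alpha_bounds`` constrains the orientation nuisance angle (radians),
    typically the proximal-alignment range from preprocessing expressed
    relative to the trace's current pose.  ``projection_tol`` is the
    orthogonality tolerance of node projections (mm); ``rss_rel_tol`` the
    relative RSS change that terminates the alternation.  All randomness
    (multistart perturbations) flows from ``seed``.
    """

    alpha_bounds: OrientationBounds | tuple[float, float] = (-0.35, 0.35)
    projection_tol: float = 1e-8
    rss_rel_tol: float = 1e-12
    max_iterations: int = 5
    multistart_count: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.projection_tol <= 0 or self.rss_rel_tol <= 0:
            raise ConfigurationError("tolerances must be positive")
        if self.max_iterations < 1:
            raise ConfigurationError("max_iterations must be >= 1")

    @property
    def alpha_lo(self) -> float:
        b = self.alpha_bounds
        return b.alpha_min if isinstance(b, OrientationBounds) else float(b[0])

    @property
    def alpha_hi(self) -> float:
        b = self.alpha_bounds
        return b.alpha_max if isinstance(b, OrientationBounds) else float(b[1])


@dataclass
class FitResult:
    """A fitted model with its orthogonal residuals.

    ``signed_residuals`` are per-node distances to the curve, positive when
    the node lies on the left of the oriented curve (above, for a whisker
    running along +x).  ``t_params`` are the per-node projection parameters
    (arc coordinates for the Cesaro family).  ``theta`` packs all free
    parameters, including alpha / psi0, for determinism checks.
    """

    family: str
    model: object
    alpha: float
    rss: float
    signed_residuals: np.ndarray
    t_params: np.ndarray
    converged: bool
    n_iter: int = 0
    extra: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.signed_residuals)

    @property
    def sum_r(self) -> float:
        """Signed residual sum (the outer fractional-exponent criterion uses its square)."""
        return float(self.signed_residuals.sum())

    @property
    def theta(self) -> np.ndarray:
        m = self.model
        if isinstance(m, PolynomialModel):
            core = list(m.coeffs)
        elif isinstance(m, FractionalModel):
            core = [m.beta, m.a_beta]
        elif isinstance(m, EllipseModel):
            core = [m.A, m.B]
        elif isinstance(m, CesaroModel):
            return np.array([m.A, m.B, m.psi0])
        else:  # pragma: no cover
            core = []
        return np.array(core + [self.alpha])


@dataclass
class SpeciesBetaFit:
    """A species-level shared exponent beta* with per-whisker coefficients."""

    beta_star: float
    fits: list[FitResult]
    outer_objective: float  # sum over whiskers of (sum_i r_i)^2 at beta*
    total_rss: float
    at_boundary: bool = False


# ---------------------------------------------------------------------------
# Parametric curve kernels (curve frame; data are rotated by -alpha instead)
# ---------------------------------------------------------------------------

class _PolyCurve:
    def __init__(self, orders: tuple[int, ...], t_hi: float):
        self.orders = orders
        self.n_params = len(orders)
        self.domain = (0.0, t_hi)

    def xy(self, t, th):
        y = np.zeros_like(t)
        for k, c in zip(self.orders, th):
            y += c * t**k
        return np.stack([t, y], axis=-1)

    def dxy(self, t, th):
        dy = np.zeros_like(t)
        for k, c in zip(self.orders, th):
            dy += c * k * t ** (k - 1)
        return np.stack([np.ones_like(t), dy], axis=-1)

    def d2xy(self, t, th):
        d2 = np.zeros_like(t)
        for k, c in zip(self.orders, th):
            if k >= 2:
                d2 += c * k * (k - 1) * t ** (k - 2)
        return np.stack([np.zeros_like(t), d2], axis=-1)


class _FracCurve:
    def __init__(self, beta: float, t_hi: float):
        self.beta = beta
        self.n_params = 1
        self.domain = (0.0, t_hi)

    def xy(self, t, th):
        return np.stack([t, th[0] * t**self.beta], axis=-1)

    def dxy(self, t, th):
        tt = np.maximum(t, 1e-12)
        return np.stack(
            [np.ones_like(t), th[0] * self.beta * tt ** (self.beta - 1)], axis=-1
        )

    def d2xy(self, t, th):
        tt = np.maximum(t, 1e-9)
        b = self.beta
        return np.stack(
            [np.zeros_like(t), th[0] * b * (b - 1) * tt ** (b - 2)], axis=-1
        )


class _EllipseCurve:
    def __init__(self, t_hi: float = 0.995 * np.pi):
        self.n_params = 2
        self.domain = (0.0, t_hi)

    def xy(self, t, th):
        A, B = th
        return np.stack([A * np.sin(t), B * (1.0 - np.cos(t))], axis=-1)

    def dxy(self, t, th):
        A, B = th
        return np.stack([A * np.cos(t), B * np.sin(t)], axis=-1)

    def d2xy(self, t, th):
        A, B = th
        return np.stack([-A * np.sin(t), B * np.cos(t)], axis=-1)


def _rotate(points: np.ndarray, angle: float) -> np.ndarray:
    """Rotate row-vector points CCW by ``angle``."""
    c, s = np.cos(angle), np.sin(angle)
    return points @ np.array([[c, s], [-s, c]])


# ---------------------------------------------------------------------------
# Orthogonal projection
# ---------------------------------------------------------------------------

def _project_newton(curve, theta, Q, t0, max_iter: int = 60):
    """Newton iterations on the orthogonality condition (p - q) . p' = 0."""
    lo, hi = curve.domain
    span = hi - lo
    t = np.clip(np.asarray(t0, dtype=float), lo, hi)
    for _ in range(max_iter):
        p = curve.xy(t, theta)
        dp = curve.dxy(t, theta)
        d2p = curve.d2xy(t, theta)
        r = p - Q
        g = np.einsum("ij,ij->i", r, dp)
        sp2 = np.einsum("ij,ij->i", dp, dp)
        gp = sp2 + np.einsum("ij,ij->i", r, d2p)
        gp = np.where(gp > 1e-9 * (sp2 + 1e-30), gp, sp2 + 1e-30)
        step = np.clip(-g / gp, -span / 6, span / 6)
        t_new = np.clip(t + step, lo, hi)
        if np.abs(t_new - t).max() < 1e-14 * max(1.0, hi):
            t = t_new
            break
        t = t_new
    return t


def _project_nodes(curve, theta, Q, t_warm=None, grid: int = 96,
                   safeguard: bool = True):
    """Project every node onto the curve; returns (t, dist, signed_residual).

    A warm Newton pass handles the common case; with ``safeguard`` enabled,
    nodes whose Newton result is beaten by a coarse grid scan (wrong
    branch, boundary) are restarted from the grid argmin.  Sign convention:
    positive on the left of the oriented curve.
    """
    lo, hi = curve.domain
    if t_warm is None:
        tg = np.linspace(lo, hi, grid)
        P = curve.xy(tg, theta)  # (grid, 2)
        d2 = ((Q[:, None, :] - P[None, :, :]) ** 2).sum(axis=2)
        t_warm = tg[np.argmin(d2, axis=1)]
    t = _project_newton(curve, theta, Q, t_warm)
    if safeguard:
        tg = np.linspace(lo, hi, grid)
        P = curve.xy(tg, theta)
        d2 = ((Q[:, None, :] - P[None, :, :]) ** 2).sum(axis=2)
        ibest = np.argmin(d2, axis=1)
        p = curve.xy(t, theta)
        dist2 = ((p - Q) ** 2).sum(axis=1)
        bad = dist2 > d2[np.arange(len(Q)), ibest] + 1e-18
        if bad.any():
            t_alt = _project_newton(curve, theta, Q[bad], tg[ibest[bad]])
            p_alt = curve.xy(t_alt, theta)
            d_alt = ((p_alt - Q[bad]) ** 2).sum(axis=1)
            better = d_alt < dist2[bad]
            t_bad = t[bad]
            t_bad[better] = t_alt[better]
            t[bad] = t_bad
    p = curve.xy(t, theta)
    r = Q - p
    dp = curve.dxy(t, theta)
    dist = np.hypot(r[:, 0], r[:, 1])
    sign = np.sign(dp[:, 0] * r[:, 1] - dp[:, 1] * r[:, 0])
    sign[sign == 0] = 1.0
    return t, dist, sign * dist


def project_point(model, q, t_init: float | None = None, alpha: float = 0.0,
                  t_max: float | None = None):
    """Orthogonally project a single point onto a model curve.

    ``model`` is a :class:`PolynomialModel`, :class:`FractionalModel` or
    :class:`EllipseModel`; the curve is rotated by ``alpha``.  Returns
    ``(t_star, signed_residual)`` where the residual is positive when the
    point lies on the left of the oriented curve.  A dense grid scan plus
    Newton refinement makes the result match a brute-force parameter sweep
    to well below 1e-6 mm.
    """
    q = np.asarray(q, dtype=float).reshape(1, 2)
    curve, theta = _curve_for_model(model, t_max)
    qr = _rotate(q, -alpha)
    lo, hi = curve.domain
    tg = np.linspace(lo, hi, 4096)
    P = curve.xy(tg, theta)
    d2 = ((qr - P) ** 2).sum(axis=1)
    t0 = tg[int(np.argmin(d2))] if t_init is None else float(t_init)
    t = _project_newton(curve, theta, qr, np.array([t0]))
    # also refine from the grid argmin and keep the better of the two
    t2 = _project_newton(curve, theta, qr, np.array([tg[int(np.argmin(d2))]]))
    cand = np.array([t[0], t2[0]])
    dists = np.hypot(*(curve.xy(cand, theta) - qr).T)
    k = int(np.argmin(dists))
    t_star = float(cand[k])
    p = curve.xy(np.array([t_star]), theta)[0]
    dp = curve.dxy(np.array([t_star]), theta)[0]
    r = qr[0] - p
    sign = np.sign(dp[0] * r[1] - dp[1] * r[0]) or 1.0
    return t_star, float(sign * np.hypot(*r))


def _curve_for_model(model, t_max: float | None):
    if isinstance(model, PolynomialModel):
        hi = t_max if t_max is not None else 100.0
        return _PolyCurve(model.orders, hi), np.asarray(model.coeffs, float)
    if isinstance(model, FractionalModel):
        hi = t_max if t_max is not None else 100.0
        return _FracCurve(model.beta, hi), np.array([model.a_beta])
    if isinstance(model, EllipseModel):
        hi = t_max if t_max is not None else 0.995 * np.pi
        return _EllipseCurve(hi), np.array([model.A, model.B])
    raise ConfigurationError(f"no parametric projection for {type(model).__name__}")


# ---------------------------------------------------------------------------
# The ODR alternation
# ---------------------------------------------------------------------------

def _odr_alternate(curve, Q, theta0, alpha0, theta_bounds, config: FitConfig):
    """Alternate node projection and constrained RSS minimization.

    The parameter step minimizes the orthogonal RSS with the projections
    refreshed (warm-started Newton) at every residual evaluation, so the
    two problems are solved to joint stationarity; a full safeguarded
    re-projection then confirms convergence, repeating the cycle if the
    safeguard moved any node to a different branch.

    Returns (theta, alpha, t, rss, signed_residuals, converged, n_iter).
    """
    theta = np.asarray(theta0, dtype=float).copy()
    alpha = float(np.clip(alpha0, config.alpha_lo, config.alpha_hi))
    lob = np.asarray([b[0] for b in theta_bounds] + [config.alpha_lo], float)
    hib = np.asarray([b[1] for b in theta_bounds] + [config.alpha_hi], float)
    # initial safeguarded projection
    t, dist, _ = _project_nodes(curve, theta, _rotate(Q, -alpha))
    rss = float(dist @ dist)
    warm = {"t": t}
    converged = False
    n_iter = 0
    for n_iter in range(1, config.max_iterations + 1):

        def resid(params):
            th, al = params[:-1], params[-1]
            Qr = _rotate(Q, -al)
            tt, _, signed = _project_nodes(curve, th, Qr, t_warm=warm["t"],
                                           safeguard=False)
            warm["t"] = tt
            return signed

        x0 = np.clip(np.concatenate([theta, [alpha]]), lob, hib)
        sol = least_squares(
            resid, x0, bounds=(lob, hib), method="trf",
            xtol=1e-15, ftol=1e-15, gtol=1e-14,
        )
        theta, alpha = sol.x[:-1], float(sol.x[-1])
        t, dist, signed = _project_nodes(curve, theta, _rotate(Q, -alpha),
                                         t_warm=warm["t"])
        warm["t"] = t
        rss_new = float(dist @ dist)
        # converged when the safeguarded re-projection confirms the
        # optimizer's own residuals (no node changed branch) or the RSS
        # stopped moving between cycles
        if (abs(rss_new - 2.0 * sol.cost) <= config.rss_rel_tol * max(rss_new, 1e-30)
                or abs(rss - rss_new) <= config.rss_rel_tol * max(rss_new, 1e-30)):
            rss = rss_new
            converged = True
            break
        rss = rss_new
    t, dist, signed = _project_nodes(curve, theta, _rotate(Q, -alpha), t_warm=t)
    rss = float(dist @ dist)
    return theta, alpha, t, rss, signed, converged, n_iter


def _run_multistart(curve, Q, starts, theta_bounds, config: FitConfig):
    best = None
    for theta0, alpha0 in starts:
        out = _odr_alternate(curve, Q, theta0, alpha0, theta_bounds, config)
        if best is None or out[3] < best[3]:
            best = out
    if best is None:  # pragma: no cover
        raise FitError("no starts supplied")
    return best


def _perturbed_starts(base_theta, base_alpha, config: FitConfig, scale=0.3):
    """Seeded multistart list: the base start plus random perturbations."""
    rng = np.random.default_rng(config.seed)
    starts = [(np.asarray(base_theta, float), base_alpha)]
    for _ in range(max(0, config.multistart_count - 1)):
        fac = 1.0 + scale * rng.standard_normal(len(base_theta))
        da = 0.25 * (config.alpha_hi - config.alpha_lo) * rng.standard_normal()
        starts.append((np.asarray(base_theta, float) * fac,
                       float(np.clip(base_alpha + da, config.alpha_lo, config.alpha_hi))))
    return starts


def _nodes_of(trace) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(trace, Trace):
        return trace.nodes, trace.s
    nodes = np.asarray(trace, dtype=float)
    d = np.hypot(*np.diff(nodes, axis=0).T)
    return nodes, np.concatenate([[0.0], np.cumsum(d)])


def _t_hi_for(Q: np.ndarray) -> float:
    return 1.4 * float(np.abs(Q[:, 0]).max()) + 1.0


# ---------------------------------------------------------------------------
# Family fits
# ---------------------------------------------------------------------------

def fit_polynomial(trace, orders: Sequence[int], config: FitConfig | None = None,
                   extra_starts: Sequence[tuple] = ()) -> FitResult:
    """Fit y = sum a_i x^i (orders from ``orders``) by orthogonal distance."""
    config = config or FitConfig()
    Q, s = _nodes_of(trace)
    orders = tuple(orders)
    curve = _PolyCurve(orders, _t_hi_for(Q))
    V = np.column_stack([Q[:, 0] ** k for k in orders])
    theta0, *_ = np.linalg.lstsq(V, Q[:, 1], rcond=None)
    bounds = [(-np.inf, np.inf)] * len(orders)
    starts = _perturbed_starts(theta0, 0.0, config) + list(extra_starts)
    theta, alpha, t, rss, signed, conv, it = _run_multistart(
        curve, Q, starts, bounds, config
    )
    model = PolynomialModel(orders=orders, coeffs=tuple(theta))
    return FitResult("poly" + "".join(map(str, orders)), model, alpha, rss,
                     signed, t, conv, it)


def fit_polynomials(trace, order_sets: Sequence[tuple[int, ...]] = POLY_ORDER_SETS,
                    config: FitConfig | None = None) -> dict[tuple[int, ...], FitResult]:
    """Fit every polynomial order set; nested sets warm-start from their subsets.

    Warm starting guarantees the nested-model property
    RSS(superset) <= RSS(subset) up to optimizer tolerance.
    """
    config = config or FitConfig()
    results: dict[tuple[int, ...], FitResult] = {}
    for orders in order_sets:
        orders = tuple(orders)
        extra = []
        for prev_orders, prev in results.items():
            if set(prev_orders) <= set(orders):
                pad = np.array([
                    prev.model.coeffs[prev_orders.index(k)] if k in prev_orders else 0.0
                    for k in orders
                ])
                extra.append((pad, prev.alpha))
        results[orders] = fit_polynomial(trace, orders, config, extra_starts=extra)
    return results


def fit_fractional_fixed_beta(trace, beta: float, config: FitConfig | None = None,
                              warm: FitResult | None = None) -> FitResult:
    """Inner fractional fit: optimize (a_beta, alpha) at fixed beta by least RSS."""
    config = config or FitConfig()
    Q, s = _nodes_of(trace)
    curve = _FracCurve(beta, _t_hi_for(Q))
    x = np.maximum(Q[:, 0], 0.0)
    denom = float((x ** (2 * beta)).sum())
    a0 = float((x**beta @ Q[:, 1]) / denom) if denom > 0 else 1e-3
    if warm is not None:
        # continuation from an adjacent beta: the warm start alone suffices
        starts = [(np.array([warm.model.a_beta]), warm.alpha)]
    else:
        starts = _perturbed_starts([max(a0, 1e-8)], 0.0, config)
    theta, alpha, t, rss, signed, conv, it = _run_multistart(
        curve, Q, starts, [(1e-12, np.inf)], config
    )
    model = FractionalModel(beta=beta, a_beta=float(theta[0]))
    return FitResult("frac", model, alpha, rss, signed, t, conv, it)


def _golden_min(f: Callable[[float], float], a: float, b: float,
                tol: float) -> float:
    """Golden-section minimization of f on [a, b] to bracket width ``tol``."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return 0.5 * (a + b)


def fit_fractional(trace, config: FitConfig | None = None,
                   beta_bounds: tuple[float, float] = (1.2, 4.5),
                   scan_step: float = 0.15,
                   outer_tol: float = 1e-3) -> FitResult:
    """Nested fractional-exponent fit of a single whisker.

    Inner: (a_beta, alpha) minimizing the RSS at fixed beta.  Outer: beta
    minimizing the squared signed-residual sum (sum r_i)^2, located by a
    coarse scan followed by golden-section refinement.  On noise-free data
    the outer criterion has an exact zero at the generating exponent;
    near-zero scan minima are disambiguated by the inner RSS.
    """
    config = config or FitConfig()
    lo, hi = beta_bounds
    betas = np.arange(lo, hi + scan_step / 2, scan_step)
    cache: dict[float, FitResult] = {}
    warm_holder: list[FitResult | None] = [None]

    def inner(beta: float) -> FitResult:
        b = round(float(beta), 12)
        if b not in cache:
            cache[b] = fit_fractional_fixed_beta(trace, b, config, warm=warm_holder[0])
            warm_holder[0] = cache[b]
        return cache[b]

    sums = np.array([inner(b).sum_r for b in betas])
    objs = sums**2
    # Every sign change of the residual sum brackets an exact zero of the
    # outer objective (sum r)^2.  All such zeros are global minimizers of
    # the outer criterion, so each is located by bisection and the tie
    # between them is broken by the inner RSS.
    roots: list[tuple[float, float, float]] = []  # (obj, rss, beta)
    for i in np.flatnonzero(np.sign(sums[:-1]) * np.sign(sums[1:]) < 0):
        a, b = float(betas[i]), float(betas[i + 1])
        fa = sums[i]
        while b - a > outer_tol:
            m = 0.5 * (a + b)
            fm = inner(m).sum_r
            if fa * fm <= 0:
                b = m
            else:
                a, fa = m, fm
        r = inner(0.5 * (a + b))
        roots.append((r.sum_r ** 2, r.rss, 0.5 * (a + b)))
    i_best = int(np.argmin(objs))
    blo = float(betas[max(i_best - 1, 0)])
    bhi = float(betas[min(i_best + 1, len(betas) - 1)])
    b0 = _golden_min(lambda b: inner(b).sum_r ** 2, blo, bhi, outer_tol)
    r0 = inner(b0)
    cands = list(roots)
    if not roots or r0.sum_r ** 2 <= max(r[0] for r in roots):
        cands.append((r0.sum_r ** 2, r0.rss, b0))
    beta_star = round(min(cands, key=lambda c: c[1])[2], 12)
    res = inner(beta_star)
    res.extra["beta_at_boundary"] = bool(
        beta_star - lo < 2 * outer_tol or hi - beta_star < 2 * outer_tol
    )
    res.extra["outer_objective"] = res.sum_r ** 2
    return res


def fit_fractional_species(traces: Sequence, config: FitConfig | None = None,
                           beta_bounds: tuple[float, float] = (1.2, 4.5),
                           scan_step: float = 0.15,
                           outer_tol: float = 1e-3) -> SpeciesBetaFit:
    """Species-level fractional fit: all whiskers share one exponent beta*.

    Inner: each whisker's (a_beta, alpha) minimizing its own RSS at the
    shared beta.  Outer: beta* minimizing the summed squared residual sums,
    sum over whiskers of (sum_i r_i)^2.
    """
    config = config or FitConfig()
    if len(traces) < 1:
        raise ConfigurationError("need at least one trace")
    lo, hi = beta_bounds
    warms: list[FitResult | None] = [None] * len(traces)
    cache: dict[float, tuple[list[FitResult], float, float]] = {}

    def inner(beta: float):
        b = round(float(beta), 12)
        if b not in cache:
            fits = []
            for i, tr in enumerate(traces):
                fr = fit_fractional_fixed_beta(tr, b, config, warm=warms[i])
                warms[i] = fr
                fits.append(fr)
            obj = float(sum(fr.sum_r ** 2 for fr in fits))
            rss = float(sum(fr.rss for fr in fits))
            cache[b] = (fits, obj, rss)
        return cache[b]

    betas = np.arange(lo, hi + scan_step / 2, scan_step)
    objs = np.array([inner(b)[1] for b in betas])
    rsss = np.array([inner(round(float(b), 12))[2] for b in betas])
    near_zero = objs <= 1e-10 * max(objs.max(), 1e-300)
    if near_zero.sum() >= 2:
        idx = np.flatnonzero(near_zero)
        i_best = int(idx[np.argmin(rsss[idx])])
    else:
        i_best = int(np.argmin(objs))
    blo = betas[max(i_best - 1, 0)]
    bhi = betas[min(i_best + 1, len(betas) - 1)]
    beta_star = round(
        _golden_min(lambda b: inner(b)[1], float(blo), float(bhi), outer_tol), 12
    )
    fits, obj, rss = inner(beta_star)
    return SpeciesBetaFit(
        beta_star=float(beta_star), fits=fits, outer_objective=obj, total_rss=rss,
        at_boundary=bool(beta_star - lo < 2 * outer_tol or hi - beta_star < 2 * outer_tol),
    )


def fit_ellipse(trace, config: FitConfig | None = None) -> FitResult:
    """Fit an elliptical arc (A, B, alpha) to a full, possibly backwards, trace.

    The tip's projection parameter becomes ``t_end``, from which the
    quarter-arc fraction is derived.  Semi-axes are bounded below at 1 mm;
    hitting that bound is flagged.
    """
    config = config or FitConfig()
    Q, s = _nodes_of(trace)
    curve = _EllipseCurve()
    xm = max(float(Q[:, 0].max()), 1.0)
    ym = max(float(Q[:, 1].max()), 0.5)
    starts = []
    for te in (0.5, 0.9, 1.4, 2.2):
        A0 = xm / np.sin(min(te, np.pi / 2))
        B0 = ym / (1.0 - np.cos(te))
        starts.append((np.array([max(A0, 1.0), max(B0, 1.0)]), 0.0))
    rng = np.random.default_rng(config.seed)
    for _ in range(max(0, config.multistart_count - 1)):
        fac = np.exp(0.4 * rng.standard_normal(2))
        starts.append((np.array([xm, ym * 2]) * fac, 0.0))
    bounds = [(1.0, 1e5), (1.0, 1e5)]
    theta, alpha, t, rss, signed, conv, it = _run_multistart(
        curve, Q, starts, bounds, config
    )
    t_end = float(t[-1])
    model = EllipseModel(A=float(theta[0]), B=float(theta[1]), t_end=t_end)
    res = FitResult("ellipse", model, alpha, rss, signed, t, conv, it)
    res.extra["axis_at_bound"] = bool(min(theta) <= 1.0 + 1e-9)
    return res


def fit_cesaro(trace, config: FitConfig | None = None) -> FitResult:
    """Coordinate-free Cesaro fit: kappa(s) = A s + B.

    A curve of equal arc length is generated from the candidate (A, B),
    anchored at the trace base with free initial tangent psi0, and compared
    to the observed nodes at matching arc coordinates (no projection).  The
    objective is the summed Euclidean distance, smoothed infinitesimally
    for differentiability; coefficients are invariant to rigid motion of
    the input because psi0 and the anchoring absorb pose.
    """
    config = config or FitConfig()
    Q, s = _nodes_of(trace)
    base = Q[0]
    # canonical frame: rotate about the base so the first chord lies on +x.
    # The optimization then sees an identical problem for any rigid pose of
    # the input, making the recovered (A, B) pose-invariant to rounding.
    first = int(np.argmax(s > 1e-9))
    phi_c = float(np.arctan2(Q[first, 1] - base[1], Q[first, 0] - base[0]))
    Qc = _rotate(Q - base, -phi_c)
    kap = discrete_curvature(Qc, s)
    AB0 = np.polyfit(s, kap, 1)  # [A, B]
    eps = 1e-20

    def resid_sq(params):
        # smooth warm-up objective: plain coordinate residuals
        A, B, psi0 = params
        return (_cesaro_xy(A, B, psi0, s[1:]) - Qc[1:]).ravel()

    def resid(params):
        A, B, psi0 = params
        pred = _cesaro_xy(A, B, psi0, s[1:])
        d2 = ((pred - Qc[1:]) ** 2).sum(axis=1)
        return (d2 + eps) ** 0.25  # sum of squares ~= sum of distances

    rng = np.random.default_rng(config.seed)
    starts = [np.array([AB0[0], AB0[1], 0.0])]
    for _ in range(max(0, config.multistart_count - 1)):
        starts.append(starts[0] + np.array([
            0.3 * abs(AB0[0]) + 1e-4, 0.3 * abs(AB0[1]) + 1e-3, 0.1,
        ]) * rng.standard_normal(3))
    lob = np.array([-1.0, -2.0, -np.pi])
    hib = np.array([1.0, 2.0, np.pi])
    best = None
    for x0 in starts:
        warm = least_squares(
            resid_sq, np.clip(x0, lob, hib), bounds=(lob, hib), method="trf",
            xtol=1e-15, ftol=1e-15, gtol=1e-14,
        )
        sol = least_squares(
            resid, warm.x, bounds=(lob, hib), method="trf",
            xtol=1e-15, ftol=1e-15, gtol=1e-14, max_nfev=2000,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    A, B, psi0c = best.x
    pred = np.vstack([[0.0, 0.0], _cesaro_xy(A, B, psi0c, s[1:])])
    diff = Qc - pred
    dist = np.hypot(diff[:, 0], diff[:, 1])
    theta_tan = psi0c + B * s + 0.5 * A * s * s
    cross = np.cos(theta_tan) * diff[:, 1] - np.sin(theta_tan) * diff[:, 0]
    sign = np.sign(cross)
    sign[sign == 0] = 1.0
    model = CesaroModel(A=float(A), B=float(B), psi0=float(psi0c + phi_c))
    return FitResult(
        "cesaro", model, 0.0, float(dist @ dist), sign * dist, s.copy(),
        bool(best.status > 0), int(best.nfev),
        extra={"sum_abs_residual": float(dist.sum())},
    )


def fit_parametric(trace, family: str, config: FitConfig | None = None) -> FitResult:
    """Dispatch a fit by family tag.

    Tags: poly2, poly3, poly23, poly234, poly2345, frac, ellipse, cesaro.
    Polynomial and fractional families expect a trace already truncated of
    any backwards segment.
    """
    if family in _POLY_TAG_ORDERS:
        return fit_polynomial(trace, _POLY_TAG_ORDERS[family], config)
    if family == "frac":
        return fit_fractional(trace, config)
    if family == "ellipse":
        return fit_ellipse(trace, config)
    if family == "cesaro":
        return fit_cesaro(trace, config)
    raise ConfigurationError(f"unknown family {family!r}; expected one of {FAMILY_TAGS}")
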