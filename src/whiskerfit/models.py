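"""The four whisker curve families and curvature utilities.

Families
--------
* Polynomial: y = sum_i a_i x^i over a chosen set of orders (2..5); the
  constant and linear terms vanish by the standard-orientation convention.
* Fractional exponent: y = a_beta x^beta with a real exponent beta, bridging
  the quadratic (beta=2) and cubic (beta=3) shapes.
* Elliptical arc: x^2/A^2 + (y-B)^2/B^2 = 1, starting at the origin moving
  along +x into the first quadrant.
* Cesaro (linear intrinsic curvature): kappa(s) = A s + B, a coordinate-free
  description; such curves are Euler spirals (clothoids).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import fresnel

from ._exceptions import ConfigurationError

_SQRT_PI = np.sqrt(np.pi)

# 5-point Gauss-Legendre nodes/weights on [0, 1]
_GL_X, _GL_W = np.polynomial.legendre.leggauss(5)
_GL_X = (_GL_X + 1.0) / 2.0
_GL_W = _GL_W / 2.0


# ---------------------------------------------------------------------------
# Model parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PolynomialModel:
    """y = sum_k coeffs[k] * x**orders[k]; units of a_i are mm^(1-i)."""

    orders: tuple[int, ...]
    coeffs: tuple[float, ...]

    def __post_init__(self):
        if len(self.orders) != len(self.coeffs):
            raise ConfigurationError("orders and coeffs must have equal length")
        if min(self.orders) < 2:
            raise ConfigurationError("standard orientation fixes a0 = a1 = 0")

    def y(self, x):
        x = np.asarray(x, dtype=float)
        return sum(c * x**k for k, c in zip(self.orders, self.coeffs))

    def dy(self, x):
        x = np.asarray(x, dtype=float)
        return sum(c * k * x ** (k - 1) for k, c in zip(self.orders, self.coeffs))

    def d2y(self, x):
        x = np.asarray(x, dtype=float)
        return sum(
            c * k * (k - 1) * x ** (k - 2) for k, c in zip(self.orders, self.coeffs)
        )


@dataclass(frozen=True)
class FractionalModel:
    """y = a_beta * x**beta with a real (fractional) exponent beta > 1."""

    beta: float
    a_beta: float

    def y(self, x):
        return self.a_beta * np.asarray(x, dtype=float) ** self.beta

    def dy(self, x):
        x = np.asarray(x, dtype=float)
        return self.a_beta * self.beta * np.maximum(x, 1e-300) ** (self.beta - 1)

    def d2y(self, x):
        x = np.asarray(x, dtype=float)
        return (
            self.a_beta * self.beta * (self.beta - 1)
            * np.maximum(x, 1e-12) ** (self.beta - 2)
        )


@dataclass(frozen=True)
class EllipseModel:
    """Elliptical arc x^2/A^2 + (y-B)^2/B^2 = 1 from the origin into quadrant 1.

    A and B are the semi-axes along x and y (mm); ``t_end`` is the
    parametric angle reached by the whisker tip, in (0, pi).
    """

    A: float
    B: float
    t_end: float = np.pi / 2


@dataclass(frozen=True)
class CesaroModel:
    """Linear intrinsic curvature kappa(s) = A s + B.

    A (mm^-2) is the curvature slope, B (mm^-1) the curvature at the base.
    ``psi0`` is the initial tangent angle, a nuisance parameter that makes
    generated curves comparable with traces in an arbitrary frame.
    """

    A: float
    B: float
    psi0: float = 0.0

    def kappa(self, s):
        return self.A * np.asarray(s, dtype=float) + self.B


@dataclass(frozen=True)
class ShapeClass:
    """Sign-based shape category of a Cesaro curve.

    ``quadrant`` locates (B, A) in coefficient space (1: B>0,A>0; 2: B<0,A>0;
    3: B<0,A<0; 4: B>0,A<0; zeros count as positive).  ``inflection_inside``
    flags a curvature zero crossing strictly inside (0, S); ``all_positive``
    means kappa > 0 along the whole whisker.
    """

    quadrant: int
    inflection_inside: bool
    all_positive: bool


# ---------------------------------------------------------------------------
# Curvature
# ---------------------------------------------------------------------------

def curvature_cartesian(dy_dx, d2y_dx2):
    """Signed curvature kappa = y'' / (1 + y'^2)^(3/2)."""
    dy_dx = np.asarray(dy_dx, dtype=float)
    d2y_dx2 = np.asarray(d2y_dx2, dtype=float)
    return d2y_dx2 / (1.0 + dy_dx**2) ** 1.5


def discrete_curvature(nodes, s=None, spacing_rtol: float = 0.05):
    """Signed curvature of a uniformly spaced node sequence.

    Uses the turning of chord angles: the direction angle of each segment is
    attributed to the segment midpoint and differentiated with respect to
    arc length.  For a clothoid the chord direction equals the tangent at
    the arc midpoint up to a constant O(ds^2) offset that cancels in the
    difference, so linear kappa(s) profiles are recovered almost exactly.
    Endpoint values are linearly extrapolated from the interior.
    """
    nodes = np.asarray(nodes, dtype=float)
    if len(nodes) < 3:
        raise ConfigurationError("need at least 3 nodes for discrete curvature")
    d = np.diff(nodes, axis=0)
    seglen = np.hypot(d[:, 0], d[:, 1])
    if s is None:
        s = np.concatenate([[0.0], np.cumsum(seglen)])
    else:
        s = np.asarray(s, dtype=float)
    ds = np.diff(s)
    interior = ds[:-1] if len(ds) > 1 else ds
    if np.abs(interior - np.median(interior)).max() > spacing_rtol * np.median(interior):
        raise ConfigurationError("discrete_curvature requires uniform node spacing")
    phi = np.unwrap(np.arctan2(d[:, 1], d[:, 0]))
    smid = (s[:-1] + s[1:]) / 2.0
    kappa_in = np.diff(phi) / np.diff(smid)  # value at nodes 1..n-2
    kappa = np.empty(len(nodes))
    kappa[1:-1] = kappa_in
    if len(kappa_in) >= 2:
        kappa[0] = kappa_in[0] - (kappa_in[1] - kappa_in[0]) * (
            (s[1] - s[0]) / (s[2] - s[1])
        )
        kappa[-1] = kappa_in[-1] + (kappa_in[-1] - kappa_in[-2]) * (
            (s[-1] - s[-2]) / (s[-2] - s[-3])
        )
    else:
        kappa[0] = kappa[-1] = kappa_in[0]
    return kappa


# ---------------------------------------------------------------------------
# Ellipse
# ---------------------------------------------------------------------------

def ellipse_arc(model: EllipseModel, t):
    """Point(s) on the elliptical arc: (A sin t, B (1 - cos t)).

    At t = 0 this is the origin with tangent +x; t = pi/2 is the quarter-arc
    point (A, B).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < -1e-12) or np.any(t > model.t_end + 1e-12):
        raise ConfigurationError("t outside [0, t_end]")
    return np.stack([model.A * np.sin(t), model.B * (1.0 - np.cos(t))], axis=-1)


def ellipse_curvature(model: EllipseModel, t):
    """Curvature along the arc, kappa = A^4 B^4 / (A^4 yc^2 + B^4 x^2)^(3/2).

    ``yc`` is the ordinate measured from the ellipse center (y - B in
    whisker coordinates); with that reading the formula reduces to 1/R on a
    circle A = B = R.
    """
    t = np.asarray(t, dtype=float)
    x = model.A * np.sin(t)
    yc = -model.B * np.cos(t)  # (y - B)
    A4, B4 = model.A**4, model.B**4
    return A4 * B4 / (A4 * yc**2 + B4 * x**2) ** 1.5


def quarter_fraction(model: EllipseModel) -> float:
    """Percentage of a quarter elliptical arc occupied by the whisker.

    100 * t_end / (pi/2); values above 100% flag "backwards" whiskers whose
    tips run in the -x direction in standard orientation.
    """
    return float(100.0 * model.t_end / (np.pi / 2.0))


def ellipse_arc_length(model: EllipseModel, t_end: float | None = None) -> float:
    """Arc length from t=0 to t_end by fine Gauss-Legendre quadrature."""
    te = model.t_end if t_end is None else t_end
    edges = np.linspace(0.0, te, 257)
    h = np.diff(edges)
    tt = edges[:-1, None] + h[:, None] * _GL_X[None, :]
    speed = np.hypot(model.A * np.cos(tt), model.B * np.sin(tt))
    return float((speed @ _GL_W * h).sum())


# ---------------------------------------------------------------------------
# Cesaro curves and the universal Euler spiral
# ---------------------------------------------------------------------------

def _cesaro_xy(A: float, B: float, psi0: float, s: np.ndarray) -> np.ndarray:
    """Positions of the unit-speed curve with tangent angle psi0 + B s + A s^2/2.

    Integrates (cos theta, sin theta) with 5-point Gauss-Legendre quadrature
    on each interval between consecutive requested arc coordinates (plus the
    segment from 0 to s[0]), which is exact to ~1e-12 at 0.25 mm steps for
    whisker-scale coefficients.  ``s`` must be non-decreasing, starting at
    any value >= 0; the curve starts at the origin at s = 0.
    """
    s = np.asarray(s, dtype=float)
    edges = np.concatenate([[0.0], s])
    h = np.diff(edges)
    t = edges[:-1, None] + h[:, None] * _GL_X[None, :]
    theta = psi0 + B * t + 0.5 * A * t * t
    x = np.cumsum((np.cos(theta) @ _GL_W) * h)
    y = np.cumsum((np.sin(theta) @ _GL_W) * h)
    return np.stack([x, y], axis=-1)


def generate_cesaro_curve(model: CesaroModel, S: float, spacing: float = 0.25):
    """Generate a unit-speed Cesaro curve of arc length S from the origin.

    Returns ``(nodes, s)`` with nodes at arc-length spacing ``spacing`` (the
    last segment may be shorter so that the total length is exactly S).
    """
    if S <= 0 or spacing <= 0:
        raise ConfigurationError("S and spacing must be positive")
    s = np.arange(0.0, S, spacing)
    if S - s[-1] > 1e-9:
        s = np.concatenate([s, [S]])
    nodes = np.vstack([[0.0, 0.0], _cesaro_xy(model.A, model.B, model.psi0, s[1:])])
    return nodes, s


def universal_spiral_point(s_hat):
    """Point(s) on the universal Euler spiral, kappa(s_hat) = s_hat.

    The tangent angle is theta = s_hat^2 / 2, so the coordinates are Fresnel
    integrals: (int cos(tau^2/2) dtau, int sin(tau^2/2) dtau) from 0 to
    s_hat.  Negative s_hat traverses the odd-symmetric branch.
    """
    z = np.asarray(s_hat, dtype=float) / _SQRT_PI
    S_f, C_f = fresnel(z)
    return np.stack([_SQRT_PI * C_f, _SQRT_PI * S_f], axis=-1)


# ---------------------------------------------------------------------------
# Shape classification and summaries
# ---------------------------------------------------------------------------

#: coefficients smaller than these are treated as zero (axis cases)
A_ZERO_TOL = 1e-8  # mm^-2
B_ZERO_TOL = 1e-8  # mm^-1


def classify_shape(model: CesaroModel, S: float) -> ShapeClass:
    """Classify a Cesaro curve by the signs of (B, A) and its inflection.

    The quadrant refers to the (B, A) coefficient plane; e.g. quadrant 1
    (B>0, A>0) is a whisker whose curvature is positive at the base and
    increases towards the tip.  Coefficients within the zero tolerances
    count as positive, so the map is total and single-valued.
    """
    if S <= 0:
        raise ConfigurationError("S must be positive")
    A = 0.0 if abs(model.A) < A_ZERO_TOL else model.A
    B = 0.0 if abs(model.B) < B_ZERO_TOL else model.B
    if B >= 0:
        quadrant = 1 if A >= 0 else 4
    else:
        quadrant = 2 if A >= 0 else 3
    inflection_inside = A != 0.0 and 0.0 < -B / A < S
    k0, kS = model.B, model.A * S + model.B
    all_positive = k0 > 0 and kS > 0
    return ShapeClass(quadrant, bool(inflection_inside), bool(all_positive))


def mean_curvature(model: CesaroModel, S: float) -> float:
    """Curvature averaged over arc length: kappa_bar = A S / 2 + B."""
    if S <= 0:
        raise ConfigurationError("S must be positive")
    return float(model.A * S / 2.0 + model.B)
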