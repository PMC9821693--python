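"""Synthetic whisker traces, populations, and arrays.

Every stage of the pipeline is testable without the original flatbed scans
by generating traces with the statistical structure real whisker data
carries: smooth planar curves from each model family (arc lengths roughly
5-300 mm), pixelation noise from quantizing coordinates to a scanner grid
(half-pixel uniform error at a stated dpi), arbitrary rigid placement on
the scanner bed, whisker-array row/column identity with the caudal-to-
rostral length gradient, and per-species fractional-exponent distributions
(truncated normal beta, with the coefficient a_beta shrinking with whisker
length as a_beta = c * S^-(beta-1) times lognormal scatter, so short
whiskers carry large, variable coefficients).

All randomness flows from the spec seed; the same spec always reproduces
the same trace bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import ConfigurationError
from .models import CesaroModel, EllipseModel, FractionalModel, PolynomialModel, _cesaro_xy
from .traces import MM_PER_INCH, RawTrace, WhiskerId

FAMILIES = ("poly", "frac", "ellipse", "cesaro")


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic whisker trace.

    ``family`` is one of poly/frac/ellipse/cesaro with ``params`` the model
    parameters (poly: orders+coeffs; frac: beta, a_beta; ellipse: A, B;
    cesaro: A, B).  ``S`` is the target arc length (mm); ``sample_spacing``
    the arc distance between generated points (the dense digitized trace,
    not the 0.25 mm analysis nodes).  ``noise_dpi`` quantizes coordinates
    to a scanner pixel grid; ``rotation``/``translation`` apply a rigid
    placement after the noise, mimicking an arbitrarily posed scan.
    """

    family: str
    params: dict
    S: float = 30.0
    sample_spacing: float = 0.05
    noise_dpi: float | None = None
    rotation: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)
    seed: int = 0
    species: str = "synthetic"
    animal_id: str = "sim"
    whisker_id: WhiskerId | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(f"unknown family {self.family!r}")
        if self.S <= 0 or self.sample_spacing <= 0:
            raise ConfigurationError("S and sample_spacing must be positive")


@dataclass
class ArraySpec:
    """Recipe for a whisker array / species population.

    The length law S(row, column) decreases caudal->rostral (higher column
    numbers are more rostral and shorter), with a mild dorsoventral row
    gradient.  beta is drawn from a normal truncated to [1.5, 4]; a_beta
    follows c * S^-(beta-1) with lognormal scatter.

    Cesaro curvature is drawn as a dimensionless *shape*: a = A S^2 and
    b = B S, independent of (row, column) and of S, with the dimensional
    coefficients A = a/S^2, B = b/S.  This mirrors the scaling of real
    whiskers (short whiskers carry larger, more variable coefficients) and
    makes the Euler-spiral location b/sqrt(a) + sqrt(a)/2 a function of
    shape alone, so spiral-location correlations with identity and length
    are null by construction.
    """

    rows: tuple[str, ...] = ("A", "B", "C", "D", "E")
    columns: int = 6
    S_caudal: float = 50.0  # arc length of a column-1 whisker (mm)
    column_ratio: float = 0.75  # length shrink factor per column, caudal->rostral
    row_slope: float = 0.05  # relative length increase per row (A->E)
    beta_mean: float = 2.5
    beta_sd: float = 0.15
    beta_range: tuple[float, float] = (1.5, 4.0)
    a_coef: float = 0.6  # c in a_beta = c * S^-(beta-1)
    a_sigma: float = 0.25  # lognormal sigma of a_beta scatter
    cesaro_a_mean: float = 1.4  # dimensionless A*S^2
    cesaro_a_sd: float = 1.0
    cesaro_b_mean: float = 0.30  # dimensionless B*S
    cesaro_b_sd: float = 0.25
    noise_dpi: float | None = 6400.0
    sample_spacing: float = 0.05
    species: str = "synthetic"
    seed: int = 0

    def length_law(self, row: str, column: int) -> float:
        r = list(self.rows).index(row)
        S = self.S_caudal * self.column_ratio ** (column - 1) * (1 + self.row_slope * r)
        return max(S, 5.0)


# ---------------------------------------------------------------------------
# Single whiskers
# ---------------------------------------------------------------------------

def _model_from_spec(spec: SyntheticSpec):
    p = spec.params
    if spec.family == "poly":
        return PolynomialModel(tuple(p["orders"]), tuple(p["coeffs"]))
    if spec.family == "frac":
        return FractionalModel(float(p["beta"]), float(p["a_beta"]))
    if spec.family == "ellipse":
        return EllipseModel(float(p["A"]), float(p["B"]))
    return CesaroModel(float(p["A"]), float(p["B"]), float(p.get("psi0", 0.0)))


def _dense_curve(spec: SyntheticSpec) -> np.ndarray:
    """Noise-free points at ~sample_spacing arc increments, total length S."""
    model = _model_from_spec(spec)
    h = spec.sample_spacing
    n = int(np.ceil(spec.S / h))
    if spec.family == "cesaro":
        s = np.linspace(0.0, spec.S, n + 1)
        return np.vstack([[0.0, 0.0], _cesaro_xy(model.A, model.B, model.psi0, s[1:])])
    if spec.family == "ellipse":
        # march t at unit speed: dt/ds = 1/|p'(t)|
        t = 0.0
        ts = [0.0]
        for _ in range(n):
            def speed(tt):
                return np.hypot(model.A * np.cos(tt), model.B * np.sin(tt))
            k1 = 1.0 / speed(t)
            k2 = 1.0 / speed(t + 0.5 * h * k1)
            k3 = 1.0 / speed(t + 0.5 * h * k2)
            k4 = 1.0 / speed(t + h * k3)
            t += h * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
            if t >= np.pi:
                raise ConfigurationError("requested S exceeds half the ellipse")
            ts.append(t)
        ts = np.asarray(ts)
        return np.stack([model.A * np.sin(ts), model.B * (1 - np.cos(ts))], axis=-1)
    # graph families: march x at unit arc speed, dx/ds = 1/sqrt(1+y'^2)
    x = 0.0
    xs = [0.0]
    for _ in range(n):
        def inv_speed(xx):
            return 1.0 / np.hypot(1.0, float(np.asarray(model.dy(max(xx, 0.0)))))
        k1 = inv_speed(x)
        k2 = inv_speed(x + 0.5 * h * k1)
        k3 = inv_speed(x + 0.5 * h * k2)
        k4 = inv_speed(x + h * k3)
        x += h * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
        xs.append(x)
    xs = np.asarray(xs)
    return np.stack([xs, np.asarray(model.y(xs))], axis=-1)


def generate_whisker(spec: SyntheticSpec) -> RawTrace:
    """Generate one synthetic whisker trace from its spec.

    The noise-free curve is sampled densely; pixel quantization (round to
    the 25.4/dpi grid, uniform error of at most half a pixel) is applied
    when ``noise_dpi`` is set; the rigid placement comes last.  Fully
    deterministic in the spec.
    """
    pts = _dense_curve(spec)
    if spec.noise_dpi:
        px = MM_PER_INCH / spec.noise_dpi
        pts = np.round(pts / px) * px
    if spec.rotation or spec.translation != (0.0, 0.0):
        c, s = np.cos(spec.rotation), np.sin(spec.rotation)
        pts = pts @ np.array([[c, s], [-s, c]]) + np.asarray(spec.translation)
    return RawTrace(
        points=pts, unit="mm", species=spec.species, animal_id=spec.animal_id,
        whisker_id=spec.whisker_id,
        meta={"family": spec.family, "params": dict(spec.params), "S": spec.S,
              "noise_dpi": spec.noise_dpi, "seed": spec.seed},
    )


# ---------------------------------------------------------------------------
# Populations and arrays
# ---------------------------------------------------------------------------

def _truncated_normal(rng, mean, sd, lo, hi, size=None):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def generate_population(array_spec: ArraySpec, n_whiskers: int,
                        family: str = "frac") -> tuple[list[RawTrace], pd.DataFrame]:
    """Draw a species population of whiskers with ground-truth parameters.

    Each whisker gets a random (row, column) identity, its arc length from
    the length law (with 10% lognormal scatter), and family parameters from
    the species laws: for 'frac', beta ~ truncated Normal and
    a_beta = c S^-(beta-1) * lognormal; for 'cesaro', (A, B) from the
    independent coefficient distributions.  Returns the traces and a truth
    table aligned with them.
    """
    rng = np.random.default_rng(array_spec.seed)
    traces, truth = [], []
    for i in range(n_whiskers):
        row = array_spec.rows[rng.integers(len(array_spec.rows))]
        col = int(rng.integers(1, array_spec.columns + 1))
        S = array_spec.length_law(row, col) * float(np.exp(0.1 * rng.standard_normal()))
        side = "L" if rng.integers(2) == 0 else "R"
        wid = WhiskerId(side, row, col)
        rot = float(rng.uniform(-np.pi, np.pi))
        shift = tuple(rng.uniform(-50, 50, size=2))
        if family == "frac":
            beta = float(_truncated_normal(rng, array_spec.beta_mean,
                                           array_spec.beta_sd,
                                           *array_spec.beta_range))
            a_beta = (array_spec.a_coef * S ** (1.0 - beta)
                      * float(np.exp(array_spec.a_sigma * rng.standard_normal())))
            params = {"beta": beta, "a_beta": a_beta}
        elif family == "cesaro":
            a = float(array_spec.cesaro_a_mean
                      + array_spec.cesaro_a_sd * rng.standard_normal())
            b = float(array_spec.cesaro_b_mean
                      + array_spec.cesaro_b_sd * rng.standard_normal())
            params = {"A": a / S**2, "B": b / S}
        else:
            raise ConfigurationError("population families: 'frac' or 'cesaro'")
        spec = SyntheticSpec(
            family=family, params=params, S=S,
            sample_spacing=array_spec.sample_spacing,
            noise_dpi=array_spec.noise_dpi,
            rotation=0.0 if family == "frac" else rot,
            translation=(0.0, 0.0) if family == "frac" else shift,
            species=array_spec.species, animal_id=f"sim{i:03d}",
            whisker_id=wid, seed=int(array_spec.seed * 100003 + i),
        )
        traces.append(generate_whisker(spec))
        truth.append({"index": i, "species": array_spec.species,
                      "side": side, "row": row, "column": col, "S": S, **params})
    return traces, pd.DataFrame(truth)


def generate_array(array_spec: ArraySpec) -> tuple[list[RawTrace], pd.DataFrame]:
    """Generate one animal's full whisker array (one whisker per row x column).

    Arc lengths follow the length law exactly; Cesaro coefficients are
    drawn independently of identity, so any correlation between spiral
    location and row/column is null by construction.
    """
    rng = np.random.default_rng(array_spec.seed)
    traces, truth = [], []
    i = 0
    for row in array_spec.rows:
        for col in range(1, array_spec.columns + 1):
            S = array_spec.length_law(row, col)
            A = float(array_spec.cesaro_a_mean
                      + array_spec.cesaro_a_sd * rng.standard_normal()) / S**2
            B = float(array_spec.cesaro_b_mean
                      + array_spec.cesaro_b_sd * rng.standard_normal()) / S
            spec = SyntheticSpec(
                family="cesaro", params={"A": A, "B": B}, S=S,
                sample_spacing=array_spec.sample_spacing,
                noise_dpi=array_spec.noise_dpi,
                rotation=float(rng.uniform(-np.pi, np.pi)),
                translation=tuple(rng.uniform(-50, 50, size=2)),
                species=array_spec.species, animal_id="array0",
                whisker_id=WhiskerId("L", row, col),
                seed=int(array_spec.seed * 100003 + i),
            )
            traces.append(generate_whisker(spec))
            truth.append({"index": i, "species": array_spec.species, "side": "L",
                          "row": row, "column": col, "S": S, "A": A, "B": B})
            i += 1
    return traces, pd.DataFrame(truth)
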