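"""Contact-mechanics factor along the whisker: r_F^2 / sin(theta).

For a rigidly rotating whisker contacted by a frictionless external force,
the ratio of the centripetal reaction at the base to the external force
splits into a constant prefactor (mass, inertia, center-of-mass geometry,
time step) and a purely geometric factor evaluated at the contact point:

    factor(s) = r_F(s)^2 / sin(theta(s))

where r_F is the straight-line distance from the base to the contact node
and theta the angle of the curve tangent to the x-axis.  Near the base of
a standard-oriented whisker theta -> 0 and the factor diverges; nodes with
|sin theta| below a threshold are masked (reported as NaN), not clipped.
The constant prefactor is exogenous and set to 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._exceptions import ConfigurationError
from .models import CesaroModel, EllipseModel, FractionalModel, PolynomialModel, _cesaro_xy
from .traces import Trace, resample_trace

#: tangent angles with |sin theta| below this are treated as singular
SIN_THETA_MASK = 1e-3


@dataclass
class MechanicsProfile:
    """Per-node contact geometry of one whisker shape."""

    s: np.ndarray
    r_F: np.ndarray  # base-to-contact chord (mm)
    theta: np.ndarray  # tangent angle to the x-axis (rad)
    factor: np.ndarray  # r_F^2/sin(theta), NaN where masked

    @property
    def masked(self) -> np.ndarray:
        return ~np.isfinite(self.factor)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"s": self.s, "r_F": self.r_F, "theta": self.theta, "factor": self.factor}
        )


def tangent_angles(nodes: np.ndarray) -> np.ndarray:
    """Per-node tangent angle to the x-axis, in (-pi, pi].

    Central differences of position against node index (one-sided at the
    ends), so uniform node spacing is assumed.
    """
    nodes = np.asarray(nodes, dtype=float)
    if len(nodes) < 3:
        raise ConfigurationError("need at least 3 nodes")
    dx = np.gradient(nodes[:, 0])
    dy = np.gradient(nodes[:, 1])
    return np.arctan2(dy, dx)


def contact_factor_profile(nodes: np.ndarray, s: np.ndarray | None = None) -> MechanicsProfile:
    """Geometric contact factor r_F^2/sin(theta) at every node.

    ``nodes`` must be in standard orientation (base at origin).  Nodes where
    |sin theta| < 1e-3 -- including every node of a perfectly straight
    whisker -- are masked as NaN.
    """
    nodes = np.asarray(nodes, dtype=float)
    if s is None:
        d = np.hypot(*np.diff(nodes, axis=0).T)
        s = np.concatenate([[0.0], np.cumsum(d)])
    theta = tangent_angles(nodes)
    r_F = np.hypot(nodes[:, 0] - nodes[0, 0], nodes[:, 1] - nodes[0, 1])
    sin_t = np.sin(theta)
    factor = np.where(np.abs(sin_t) >= SIN_THETA_MASK, r_F**2 / sin_t, np.nan)
    if not np.isfinite(factor).any():
        warnings.warn("all nodes masked (straight whisker?): empty mechanics profile")
    return MechanicsProfile(s=np.asarray(s, float), r_F=r_F, theta=theta, factor=factor)


def _model_nodes(fit, S: float, spacing: float, base: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Equally spaced nodes of a fitted model curve, in the trace's frame."""
    model = fit.model
    if isinstance(model, CesaroModel):
        s = np.arange(0.0, S, spacing)
        if S - s[-1] > 1e-9:
            s = np.concatenate([s, [S]])
        pts = np.vstack([[0.0, 0.0], _cesaro_xy(model.A, model.B, model.psi0, s[1:])])
        return base + pts, s
    if isinstance(model, EllipseModel):
        t = np.linspace(0.0, model.t_end, 4096)
        dense = np.stack([model.A * np.sin(t), model.B * (1 - np.cos(t))], axis=-1)
    elif isinstance(model, (PolynomialModel, FractionalModel)):
        # march x so that the dense polyline covers arc length ~S
        x_hi = _x_for_arclength(model, S)
        x = np.linspace(0.0, x_hi, 4096)
        dense = np.stack([x, model.y(x)], axis=-1)
    else:  # pragma: no cover
        raise ConfigurationError(f"cannot generate nodes for {type(model).__name__}")
    c, sn = np.cos(fit.alpha), np.sin(fit.alpha)
    dense = dense @ np.array([[c, sn], [-sn, c]])
    tr = resample_trace(dense, spacing=spacing)
    keep = tr.s <= S + spacing / 2
    return tr.nodes[keep], tr.s[keep]


def _x_for_arclength(model, S: float) -> float:
    x, step = 0.0, max(S / 2048.0, 1e-4)
    acc = 0.0
    while acc < S and x < 10 * S:
        dydx = float(np.asarray(model.dy(x + step / 2)))
        acc += step * np.hypot(1.0, dydx)
        x += step
    return x


def model_factor_comparison(trace: Trace, fits: dict, spacing: float = 0.25) -> dict:
    """Contact-factor profiles for the raw trace and each fitted model.

    ``fits`` maps family tag -> FitResult.  Each model is regenerated as an
    equally spaced node sequence over the trace's arc length (in the
    trace's own frame, so profiles share the s axis); the raw trace's
    profile is included under 'raw'.
    """
    profiles = {"raw": contact_factor_profile(trace.nodes, trace.s)}
    base = trace.nodes[0]
    for family, fit in fits.items():
        nodes, s = _model_nodes(fit, trace.S, spacing, base)
        profiles[family] = contact_factor_profile(nodes, s)
    return profiles
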