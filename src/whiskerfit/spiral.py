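"""Conforming Cesaro-fitted whiskers onto the universal Euler spiral.

Any curve with kappa(s) = A s + B (A != 0) can be rescaled by sqrt(|A|)
into a piece of the universal Euler spiral kappa(s_hat) = s_hat.  The
affine map s_hat(s) locates each whisker as an interval on that single
curve; this module computes those intervals and tests whether their mean
locations correlate with whisker identity or geometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import ConfigurationError, NotConformableError
from .models import CesaroModel, universal_spiral_point


@dataclass(frozen=True)
class SpiralSegment:
    """The interval of the universal spiral a whisker occupies.

    ``s_hat_start``/``s_hat_end`` are dimensionless spiral arc coordinates
    (base and tip); ``orientation`` is 'forward' for A > 0 and 'reversed'
    for A < 0, where the whisker runs along the spiral in decreasing s_hat
    (equivalently, its mirror image runs forward -- the spiral's odd
    symmetry makes the two congruent).  ``scale`` = sqrt(|A|) converts
    whisker mm to spiral units.
    """

    s_hat_start: float
    s_hat_end: float
    orientation: str
    scale: float

    @property
    def length(self) -> float:
        return abs(self.s_hat_end - self.s_hat_start)


def conform(model: CesaroModel, S: float) -> SpiralSegment:
    """Map a Cesaro-fitted whisker onto the universal Euler spiral.

    For A > 0 the map is s_hat(s) = sqrt(A) s + B/sqrt(A) (forward); for
    A < 0 it is s_hat(s) = -sqrt(|A|) s + B/sqrt(|A|) (reversed traversal).
    Either way the segment length is sqrt(|A|) * S.  Constant-curvature
    whiskers (A = 0) are circles and cannot lie on the spiral.
    """
    if S <= 0:
        raise ConfigurationError("S must be positive")
    if model.A == 0:
        raise NotConformableError(
            "A = 0: a constant-curvature whisker cannot be conformed"
        )
    root = np.sqrt(abs(model.A))
    if model.A > 0:
        return SpiralSegment(model.B / root, root * S + model.B / root,
                             "forward", root)
    return SpiralSegment(model.B / root, model.B / root - root * S,
                         "reversed", root)


def conform_nodes(model: CesaroModel, S: float, spacing: float = 0.25):
    """Spiral arc coordinates and spiral points for each node of a whisker.

    Returns ``(s_hat, points)`` where ``points[i]`` is the universal-spiral
    position of the node at whisker arc coordinate i*spacing.  The scaled
    whisker is congruent to this point sequence (via its mirror image when
    A < 0).
    """
    seg = conform(model, S)
    s = np.arange(0.0, S, spacing)
    if S - s[-1] > 1e-9:
        s = np.concatenate([s, [S]])
    sign = 1.0 if seg.orientation == "forward" else -1.0
    s_hat = seg.s_hat_start + sign * seg.scale * s
    return s_hat, universal_spiral_point(s_hat)


def mean_location(segment: SpiralSegment) -> float:
    """Midpoint of the occupied interval; independent of traversal direction."""
    return 0.5 * (segment.s_hat_start + segment.s_hat_end)


ROW_INDEX = {letter: i + 1 for i, letter in enumerate("ABCDEFGH")}


def spiral_correlations(segments: Sequence[SpiralSegment],
                        metadata: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations of spiral mean location with identity/geometry.

    ``metadata`` must have one row per segment with columns ``row`` (letter,
    dorsal-to-ventral A=1, B=2, ...), ``column`` (integer), ``S`` (arc
    length, mm) and ``kappa_bar`` (mean curvature, mm^-1).  Rows whose
    letter is not a single A-H letter (e.g. Greek straddlers) are excluded.
    Returns a table of (variable, rho, p, n); constant variables yield NaN
    with a flag in the ``note`` column.
    """
    if len(segments) != len(metadata):
        raise ConfigurationError("segments and metadata must align")
    if len(segments) < 5:
        raise ConfigurationError("need at least 5 whiskers")
    locs = np.array([mean_location(seg) for seg in segments])
    md = metadata.reset_index(drop=True)
    row_idx = md["row"].map(lambda r: ROW_INDEX.get(str(r).upper(), np.nan))
    variables = {
        "row": row_idx.to_numpy(dtype=float),
        "column": md["column"].to_numpy(dtype=float),
        "S": md["S"].to_numpy(dtype=float),
        "kappa_bar": md["kappa_bar"].to_numpy(dtype=float),
    }
    rows = []
    for name, vals in variables.items():
        ok = np.isfinite(vals)
        note = ""
        if ok.sum() < 3 or np.ptp(vals[ok]) == 0:
            rho, p = np.nan, np.nan
            note = "constant or insufficient metadata"
        else:
            rho, p = stats.pearsonr(locs[ok], vals[ok])
        rows.append((name, float(rho), float(p), int(ok.sum()), note))
    return pd.DataFrame(rows, columns=["variable", "rho", "p", "n", "note"])
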