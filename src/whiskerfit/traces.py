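"""Loading, smoothing, resampling and orienting planar whisker traces.

A whisker trace is an ordered list of 2D points digitized from a flatbed
scan, running from the follicle (base) to the tip.  This module turns raw
point lists into the canonical representation used by every downstream fit:
a smoothed curve resampled into equally spaced nodes (0.25 mm by default),
placed in *standard orientation* -- base at the origin, a proximal fraction
of the whisker aligned with the +x axis, and the curve concave up so the
bulk of its area lies in the first quadrant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._exceptions import ConfigurationError, DegenerateTraceError, FormatError

MM_PER_INCH = 25.4

#: CSV columns required by :func:`read_traces` (one row per digitized point).
TRACE_CSV_COLUMNS = [
    "species", "animal_id", "side", "row", "column", "point_index", "x", "y",
]


@dataclass(frozen=True)
class WhiskerId:
    """Identity of a whisker within an array: side (L/R), row letter, column number."""

    side: str
    row: str
    column: int

    def __str__(self) -> str:  # e.g. "L-B2"
        return f"{self.side}-{self.row}{self.column}"


@dataclass
class RawTrace:
    """An ordered 2D point list as digitized, before smoothing/resampling.

    Points run base -> tip.  Coordinates are in mm, or in pixels together
    with the scan resolution (``dpi``) needed to convert them.
    """

    points: np.ndarray  # (n, 2)
    unit: str = "mm"  # {"mm", "px"}
    dpi: float | None = None
    species: str = ""
    animal_id: str = ""
    whisker_id: WhiskerId | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise FormatError("points must be an (n, 2) array")
        if len(self.points) < 3:
            raise DegenerateTraceError(
                f"trace {self.label} has {len(self.points)} points; need >= 3"
            )
        if self.unit not in ("mm", "px"):
            raise ConfigurationError(f"unknown unit {self.unit!r}")
        if self.unit == "px" and not self.dpi:
            raise ConfigurationError("unit='px' requires a dpi value")

    @property
    def label(self) -> str:
        wid = str(self.whisker_id) if self.whisker_id else "?"
        return f"{self.species}/{self.animal_id}/{wid}"

    def points_mm(self) -> np.ndarray:
        """Coordinates converted to mm (25.4/dpi mm per pixel)."""
        if self.unit == "mm":
            return self.points.copy()
        return self.points * (MM_PER_INCH / float(self.dpi))


@dataclass
class Trace:
    """A smoothed trace resampled into equally spaced nodes.

    ``nodes[i]`` are mm coordinates; consecutive nodes are ``spacing`` apart
    (the final segment may be shorter).  ``s[i]`` is the arc-length
    coordinate of node *i* measured along the node polyline, so ``s[0] = 0``
    and ``s[-1]`` is the total arc length ``S``.
    """

    nodes: np.ndarray  # (n, 2)
    s: np.ndarray  # (n,)
    spacing: float = 0.25

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        if len(self.nodes) != len(self.s):
            raise ConfigurationError("nodes and s must have equal length")

    @property
    def S(self) -> float:
        """Total arc length (mm)."""
        return float(self.s[-1])

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


@dataclass
class StandardOrientedTrace(Trace):
    """A :class:`Trace` rigidly moved into standard orientation.

    ``alpha`` is the rotation that was applied (radians, positive CCW) after
    translating the base to the origin; ``flipped`` records whether y was
    negated to make the whisker concave up; ``aligned_fraction`` is the
    proximal arc-length fraction whose least-squares line the rotation
    aligned with the +x axis (when applicable).
    """

    alpha: float = 0.0
    flipped: bool = False
    aligned_fraction: float | None = None


@dataclass(frozen=True)
class OrientationBounds:
    """Feasible range for the orientation nuisance angle alpha (radians)."""

    alpha_min: float
    alpha_max: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.alpha_min) and np.isfinite(self.alpha_max)):
            raise ConfigurationError("orientation bounds must be finite")
        if self.alpha_min > self.alpha_max:
            raise ConfigurationError("alpha_min must not exceed alpha_max")

    def shifted(self, delta: float) -> "OrientationBounds":
        return OrientationBounds(self.alpha_min + delta, self.alpha_max + delta)


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def read_traces(path, unit: str = "mm", dpi: float | None = None) -> list[RawTrace]:
    """Read whisker traces from a long-format CSV (one row per point).

    Required columns: species, animal_id, side, row, column, point_index,
    x, y.  Points are ordered by ``point_index`` within each whisker, base
    first.  ``unit='px'`` requires ``dpi``; pixel coordinates are converted
    to mm downstream via :meth:`RawTrace.points_mm`.
    """
    if unit == "px" and not dpi:
        raise ConfigurationError("unit='px' requires a dpi value")
    df = pd.read_csv(path)
    missing = set(TRACE_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"trace CSV is missing columns: {sorted(missing)}")
    traces = []
    keys = ["species", "animal_id", "side", "row", "column"]
    for (species, animal, side, row, col), grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("point_index")
        pts = grp[["x", "y"]].to_numpy(dtype=float)
        pts = _drop_duplicate_points(pts, label=f"{species}/{animal}/{side}-{row}{col}")
        traces.append(
            RawTrace(
                points=pts,
                unit=unit,
                dpi=dpi,
                species=str(species),
                animal_id=str(animal),
                whisker_id=WhiskerId(str(side), str(row), int(col)),
            )
        )
    return traces


def traces_to_frame(traces: Sequence[RawTrace]) -> pd.DataFrame:
    """Inverse of :func:`read_traces`: long-format DataFrame of all points."""
    recs = []
    for t in traces:
        wid = t.whisker_id or WhiskerId("L", "A", 1)
        for i, (x, y) in enumerate(t.points):
            recs.append(
                (t.species, t.animal_id, wid.side, wid.row, wid.column, i, x, y)
            )
    return pd.DataFrame(recs, columns=TRACE_CSV_COLUMNS)


def _drop_duplicate_points(pts: np.ndarray, label: str = "") -> np.ndarray:
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.any(np.diff(pts, axis=0) != 0.0, axis=1)
    if not keep.all():
        warnings.warn(
            f"trace {label}: collapsed {int((~keep).sum())} duplicate consecutive point(s)"
        )
    return pts[keep]


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------

def smooth_trace(raw: RawTrace | np.ndarray, window_mm: float = 4.0) -> np.ndarray:
    """Local-regression (degree-2 LOESS) smoothing of a trace.

    x(u) and y(u) are smoothed independently against the cumulative chord
    length u, with a moving window spanning ``window_mm`` of chord length
    and tricube weights.  Endpoints are retained (asymmetric edge windows).
    A degree-2 local fit reproduces any quadratic exactly, so noise-free
    straight lines and parabolas pass through unchanged.

    Falls back to a single global quadratic fit (with a warning) when the
    whole trace is shorter than the window.
    """
    pts = raw.points_mm() if isinstance(raw, RawTrace) else np.asarray(raw, float)
    pts = _drop_duplicate_points(pts)
    if len(pts) < 3:
        raise DegenerateTraceError("need at least 3 distinct points to smooth")
    if window_mm <= 0:
        raise ConfigurationError("window_mm must be positive")
    u = np.concatenate([[0.0], np.cumsum(np.hypot(*np.diff(pts, axis=0).T))])
    if u[-1] < window_mm:
        warnings.warn(
            f"trace chord length {u[-1]:.3g} mm shorter than smoothing window "
            f"{window_mm:g} mm; falling back to a global quadratic fit"
        )
        V = np.vander(u, 3)
        coef, *_ = np.linalg.lstsq(V, pts, rcond=None)
        return V @ coef

    half = window_mm / 2.0
    out = np.empty_like(pts)
    for i, ui in enumerate(u):
        lo = np.searchsorted(u, ui - half, side="left")
        hi = np.searchsorted(u, ui + half, side="right")
        if hi - lo < 4:  # need a few points for a stable quadratic
            lo = max(0, i - 2)
            hi = min(len(u), i + 3)
        du = u[lo:hi] - ui
        dmax = np.abs(du).max()
        w = (1.0 - np.minimum(np.abs(du) / (dmax * (1 + 1e-9)), 1.0) ** 3) ** 3
        sw = np.sqrt(w)
        V = np.column_stack([np.ones_like(du), du, du * du]) * sw[:, None]
        coef, *_ = np.linalg.lstsq(V, pts[lo:hi] * sw[:, None], rcond=None)
        out[i] = coef[0]
    return out


# ---------------------------------------------------------------------------
# Resampling and arc length
# ---------------------------------------------------------------------------

def resample_trace(points: np.ndarray, spacing: float = 0.25) -> Trace:
    """Resample a polyline into nodes an equal chord distance apart.

    Walks the input polyline placing each new node exactly ``spacing`` mm
    (Euclidean) from the previous one, by intersecting a circle of radius
    ``spacing`` with the polyline ahead.  The tip is always kept, so the
    final segment may be shorter than ``spacing``.
    """
    if spacing <= 0:
        raise ConfigurationError("spacing must be positive")
    pts = _drop_duplicate_points(np.asarray(points, dtype=float))
    if len(pts) < 2:
        raise DegenerateTraceError("need at least 2 distinct points to resample")
    seg = np.diff(pts, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    if spacing > seglen.sum():
        raise DegenerateTraceError(
            f"spacing {spacing:g} mm exceeds the trace length {seglen.sum():.3g} mm"
        )

    nodes = [pts[0]]
    k = 0  # current segment index
    t = 0.0  # position within segment k, in [0, 1)
    while True:
        c = nodes[-1]
        found = False
        kk, tt = k, t
        while kk < len(seg):
            p = pts[kk]
            d = seg[kk]
            # |p + t d - c|^2 = spacing^2, t in (tt, 1]
            a = d @ d
            b = 2.0 * d @ (p - c)
            cc = (p - c) @ (p - c) - spacing * spacing
            disc = b * b - 4 * a * cc
            if disc >= 0:
                root = (-b + np.sqrt(disc)) / (2 * a)  # forward intersection
                if tt < root <= 1.0 + 1e-12:
                    nodes.append(p + min(root, 1.0) * d)
                    k, t = kk, min(root, 1.0)
                    found = True
                    break
            kk += 1
            tt = -np.inf
        if not found:
            break
    nodes = np.asarray(nodes)
    # keep the tip; drop it only if it coincides with the last node
    tip = pts[-1]
    tail = np.hypot(*(tip - nodes[-1]))
    if tail > 1e-9:
        nodes = np.vstack([nodes, tip])
    d = np.hypot(*np.diff(nodes, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(d)])
    return Trace(nodes=nodes, s=s, spacing=spacing)


def arc_length(trace: Trace | np.ndarray) -> float:
    """Total arc length: sum of the lengths of segments between adjacent nodes.

    Distinct from (and never less than) the straight base-to-tip chord.
    """
    nodes = trace.nodes if isinstance(trace, Trace) else np.asarray(trace, float)
    return float(np.hypot(*np.diff(nodes, axis=0).T).sum())


# ---------------------------------------------------------------------------
# Orientation
# ---------------------------------------------------------------------------

def proximal_alignment_angle(trace: Trace, fraction: float) -> float:
    """Rotation angle that aligns the proximal ``fraction`` of the trace with +x.

    The proximal direction is the principal axis (total least squares line)
    of all nodes with s <= fraction * S, signed to point away from the base;
    the returned alpha is minus that direction's angle.
    """
    sel = trace.s <= fraction * trace.S + 1e-12
    pts = trace.nodes[sel]
    if len(pts) < 2:
        raise DegenerateTraceError(
            f"fewer than 2 nodes within the proximal fraction {fraction:g}"
        )
    c = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - c, full_matrices=False)
    direction = vt[0]
    if direction @ (pts[-1] - pts[0]) < 0:
        direction = -direction
    return float(-np.arctan2(direction[1], direction[0]))


def orientation_bounds(
    trace: Trace, min_fraction: float = 0.01, max_fraction: float = 0.20,
    step: float = 0.01,
) -> OrientationBounds:
    """Bounds on the orientation angle alpha from proximal alignment.

    For each fraction f on a grid from ``min_fraction`` to ``max_fraction``
    the alignment angle of the proximal least-squares line is computed; the
    extremes over the grid bound the nuisance rotation used during fitting.
    Fractions too small to contain two nodes (short whiskers at coarse node
    spacing) are skipped; if no fraction on the grid contains two nodes the
    trace is degenerate.
    """
    n = int(round((max_fraction - min_fraction) / step)) + 1
    fractions = min_fraction + step * np.arange(n)
    angles = []
    for f in fractions:
        try:
            angles.append(proximal_alignment_angle(trace, f))
        except DegenerateTraceError:
            continue
    if not angles:
        raise DegenerateTraceError(
            "no proximal fraction up to "
            f"{max_fraction:g} contains 2 nodes; trace too short"
        )
    return OrientationBounds(float(np.min(angles)), float(np.max(angles)))


def standardize(trace: Trace, alpha: float,
                aligned_fraction: float | None = None) -> StandardOrientedTrace:
    """Place a trace in standard orientation.

    Translates the base to the origin, rotates by ``alpha``, then negates y
    if the arc-length-weighted signed area (integral of y ds) is negative,
    so the whisker is concave up with most of its area in the first
    quadrant.  Weighting by arc length rather than dx keeps the rule
    well-defined for backwards whiskers, whose return stroke would dominate
    a trapezoidal integral of y dx with the wrong sign.
    """
    if not np.isfinite(alpha):
        raise ConfigurationError("alpha must be finite")
    pts = trace.nodes - trace.nodes[0]
    ca, sa = np.cos(alpha), np.sin(alpha)
    rot = pts @ np.array([[ca, sa], [-sa, ca]])  # row-vector rotation by +alpha
    area = float(np.trapezoid(rot[:, 1], trace.s))
    flipped = area < 0
    if flipped:
        rot = rot * np.array([1.0, -1.0])
    return StandardOrientedTrace(
        nodes=rot, s=trace.s.copy(), spacing=trace.spacing,
        alpha=alpha, flipped=flipped, aligned_fraction=aligned_fraction,
    )


def truncate_backwards(trace: StandardOrientedTrace,
                       min_nodes: int = 10) -> StandardOrientedTrace:
    """Truncate a standard-oriented whisker where it starts curving backwards.

    Returns the prefix of nodes up to (but excluding) the first node whose x
    coordinate falls below the running maximum of x; whiskers that never
    curve backwards are returned unchanged.  Needed by the single-valued
    y(x) model families (polynomial, fractional exponent).
    """
    x = trace.nodes[:, 0]
    runmax = np.maximum.accumulate(x)
    back = np.nonzero(x < runmax - 1e-12)[0]
    if back.size == 0:
        return trace
    cut = int(back[0])
    if cut < min_nodes:
        raise DegenerateTraceError(
            f"truncation at node {cut} would leave fewer than {min_nodes} nodes"
        )
    return replace(
        trace, nodes=trace.nodes[:cut].copy(), s=trace.s[:cut].copy(),
    )


# ---------------------------------------------------------------------------
# Pipeline convenience
# ---------------------------------------------------------------------------

@dataclass
class PreprocessedWhisker:
    """A standard-oriented trace plus the fitting inputs derived from it."""

    trace: StandardOrientedTrace
    bounds: OrientationBounds  # residual alpha range, relative to the applied rotation
    raw: RawTrace | None = None


def preprocess(
    raw: RawTrace,
    spacing: float = 0.25,
    window_mm: float | None = 4.0,
    align_fraction: float = 0.15,
) -> PreprocessedWhisker:
    """Full preprocessing: smooth, resample, orient, and derive alpha bounds.

    ``window_mm=None`` skips smoothing (useful for noise-free synthetic
    input).  The trace is standardized using the alignment angle of the
    proximal ``align_fraction``.  The returned bounds are the curve
    rotations, relative to the standardized pose, that correspond to
    aligning some proximal fraction between 1% and 20%: rotating the model
    curve by alpha' = alpha0 - a_f re-creates the pose in which fraction f
    is aligned, so the feasible interval is [alpha0 - a_max, alpha0 - a_min].
    """
    pts = raw.points_mm()
    if window_mm is not None:
        pts = smooth_trace(pts, window_mm=window_mm)
    trace = resample_trace(pts, spacing=spacing)
    bounds = orientation_bounds(trace)
    alpha0 = proximal_alignment_angle(trace, align_fraction)
    std = standardize(trace, alpha0, aligned_fraction=align_fraction)
    rel = OrientationBounds(alpha0 - bounds.alpha_max, alpha0 - bounds.alpha_min)
    return PreprocessedWhisker(trace=std, bounds=rel, raw=raw)
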