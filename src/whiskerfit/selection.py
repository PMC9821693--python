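"""Model selection and cross-species statistics.

Implements the 90% RSS-reduction rule for polynomial order selection, the
parameter-count-adjusted RSS used to compare families, residual-skewness
diagnostics, percentile-based exponent outlier filtering, and pooled-variance
t-tests of pairwise species separability in the fractional exponent beta.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import ConfigurationError

#: a higher-order model is accepted iff it retains at most this fraction
#: of the lower-order model's RSS (i.e. eliminates >= 90% of it)
RETAIN_THRESHOLD = 0.10

#: polynomial order sets walked by the selection rule, low to high
SELECTION_LADDER: tuple[tuple[int, ...], ...] = ((2,), (2, 3), (2, 3, 4), (2, 3, 4, 5))


@dataclass
class OrderSelectionResult:
    """Outcome of walking the polynomial ladder with the 90% rule."""

    rss_by_order: tuple[float, ...]
    retained_fractions: tuple[float, ...]  # RSS_high / RSS_low per transition
    chosen_orders: tuple[int, ...]


@dataclass
class SeparabilityMatrix:
    """Pairwise two-sample t-test results between species."""

    species: tuple[str, ...]
    p_values: np.ndarray  # symmetric, nan on the diagonal
    classes: np.ndarray  # object array: 'strong' | 'separable' | 'not separable'

    @property
    def n_pairs(self) -> int:
        k = len(self.species)
        return k * (k - 1) // 2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.p_values, index=self.species, columns=self.species)


def adjusted_rss(rss: float, n_nodes: int, n_params: int) -> float:
    """RSS normalized by residual degrees of freedom: rss / (n - p).

    Puts fits with different parameter counts on a common footing.
    """
    if n_nodes <= n_params:
        raise ConfigurationError("need more nodes than parameters")
    return float(rss) / (n_nodes - n_params)


def select_polynomial_order(rss_by_order: Sequence[float]) -> OrderSelectionResult:
    """Walk increasing polynomial order sets, applying the 90% rule.

    ``rss_by_order`` lists the RSS for the order sets (2), (2,3), (2,3,4),
    (2,3,4,5) in that order (a shorter list walks a shorter ladder).  A
    higher set is accepted iff its RSS is at most 10% of the previous
    accepted set's RSS; the walk stops at the first rejection.
    """
    rss = [float(r) for r in rss_by_order]
    if not rss:
        raise ConfigurationError("rss_by_order must be non-empty")
    chosen = SELECTION_LADDER[0]
    fractions = []
    for i in range(1, len(rss)):
        frac = rss[i] / rss[i - 1] if rss[i - 1] > 0 else 1.0
        fractions.append(frac)
        if frac <= RETAIN_THRESHOLD:
            chosen = SELECTION_LADDER[i]
        else:
            break
    return OrderSelectionResult(tuple(rss), tuple(fractions), chosen)


def residual_skewness(signed_residuals: Sequence[float]) -> float:
    """Normalized third central moment of the signed orthogonal residuals.

    Near zero for an unbiased fit; systematically one-sided fits (e.g. a
    pure quadratic fit to a between-quadratic-and-cubic whisker) skew away
    from zero.  Raises on zero variance.
    """
    r = np.asarray(signed_residuals, dtype=float)
    if len(r) < 3:
        raise ConfigurationError("need at least 3 residuals")
    if np.var(r) == 0:
        raise ConfigurationError("skewness undefined for zero-variance residuals")
    return float(stats.skew(r, bias=True))


def filter_beta_outliers(betas: Sequence[float], ids: Sequence | None = None,
                         min_n: int = 20):
    """Drop exponents outside the central 95% percentile interval.

    Returns ``(kept_values, excluded_ids, exclusion_fraction)``.  With fewer
    than ``min_n`` values, filtering is skipped with a warning.  By
    construction at most ~5% of values are removed.
    """
    b = np.asarray(betas, dtype=float)
    ids = np.asarray(ids if ids is not None else np.arange(len(b)))
    if len(b) < min_n:
        warnings.warn(f"only {len(b)} values; skipping exponent outlier filtering")
        return b, ids[:0], 0.0
    lo, hi = np.percentile(b, [2.5, 97.5])
    keep = (b >= lo) & (b <= hi)
    return b[keep], ids[~keep], float((~keep).mean())


def pairwise_separability(beta_by_species: Mapping[str, Sequence[float]],
                          strong_p: float = 0.01,
                          separable_p: float = 0.1) -> SeparabilityMatrix:
    """Pooled-variance two-sample t-tests of beta between every species pair.

    The null is that both samples come from normal distributions with equal
    means and variances (classic Student test, not Welch).  Pairs are
    classed 'strong' (p < 0.01), 'separable' (p < 0.1) or 'not separable';
    no multiple-testing correction is applied.  Species with fewer than 3
    values are excluded with a warning.
    """
    usable = {}
    for sp, vals in beta_by_species.items():
        v = np.asarray(vals, dtype=float)
        if len(v) < 3:
            warnings.warn(f"species {sp!r} has {len(v)} values (<3); excluded")
            continue
        usable[sp] = v
    species = tuple(usable)
    if len(species) < 2:
        raise ConfigurationError("need at least 2 species with >= 3 values")
    k = len(species)
    p = np.full((k, k), np.nan)
    cls = np.full((k, k), "", dtype=object)
    for (i, a), (j, b) in combinations(enumerate(species), 2):
        res = stats.ttest_ind(usable[a], usable[b], equal_var=True)
        p[i, j] = p[j, i] = res.pvalue
        label = (
            "strong" if res.pvalue < strong_p
            else "separable" if res.pvalue < separable_p
            else "not separable"
        )
        cls[i, j] = cls[j, i] = label
    return SeparabilityMatrix(species, p, cls)


def coefficient_length_profile(fits: Sequence[tuple[float, float]],
                               n_bins: int = 4) -> pd.DataFrame:
    """Dispersion of a fitted coefficient across whisker-length bands.

    ``fits`` is a sequence of (S, coefficient) pairs.  Arc lengths are
    binned into quantile bands; each band reports the median and
    inter-quartile range of the coefficient, quantifying the tendency of
    short whiskers to carry noisier, larger coefficients.
    """
    if len(fits) < 10:
        raise ConfigurationError("need at least 10 fits for a length profile")
    arr = np.asarray(fits, dtype=float)
    S, coef = arr[:, 0], arr[:, 1]
    if np.ptp(S) == 0:
        return pd.DataFrame({
            "S_lo": [S[0]], "S_hi": [S[0]], "n": [len(S)],
            "median": [np.median(coef)],
            "iqr": [np.subtract(*np.percentile(coef, [75, 25]))],
        })
    edges = np.unique(np.quantile(S, np.linspace(0, 1, n_bins + 1)))
    idx = np.clip(np.searchsorted(edges, S, side="right") - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        sel = idx == b
        if not sel.any():
            continue
        q75, q25 = np.percentile(coef[sel], [75, 25])
        rows.append((edges[b], edges[b + 1], int(sel.sum()),
                     float(np.median(coef[sel])), float(q75 - q25)))
    return pd.DataFrame(rows, columns=["S_lo", "S_hi", "n", "median", "iqr"])
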