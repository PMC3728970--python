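"""Validation statistics for least-cost connectivity models.

The headline model-comparison statistic is

    statistic = area_pct / points_pct

where ``area_pct`` is the percentage of a convex polygon (drawn around all
GPS movement points) covered by the model mask, and ``points_pct`` the
percentage of movement points falling inside the mask.  A compact model
that still contains the observed movements scores low, which is preferred.
Supporting tests: chi-square goodness of fit of land-cover use against
area-proportional availability (with subdivided one-degree-of-freedom
partitions), a paired t-test of Euclidean vs actual path length, a
Mann-Whitney test of observed vs random-point distances, and a two-segment
(breakpoint) regression of distance-to-feature on distance-to-habitat.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import MultiPoint, Polygon
import shapely

from .landscape import LandCoverRaster, ResistanceTable

__all__ = [
    "ComparisonResult",
    "ChiSquareResult",
    "SegmentedRegression",
    "SegmentedRegressionResults",
    "convex_polygon",
    "comparison_statistic",
    "chisq_gof",
    "paired_t",
    "mann_whitney",
    "random_matrix_points",
    "breakpoint_regression",
    "rank_use",
    "truncate_2dp",
]


def truncate_2dp(x: float) -> float:
    """Truncate toward zero at two decimals (the convention of the original
    field reports, where 42/81 appears as 0.51)."""
    return math.trunc(x * 100.0) / 100.0


@dataclass
class ComparisonResult:
    """Area-vs-points test statistic for one connectivity model."""

    model_name: str
    area_pct: float
    points_pct: float

    @property
    def statistic(self) -> float | None:
        """area_pct / points_pct at full precision; None when no point
        falls inside the mask (undefined)."""
        if self.points_pct == 0:
            return None
        return self.area_pct / self.points_pct

    @property
    def statistic_2dp(self) -> float | None:
        s = self.statistic
        return None if s is None else truncate_2dp(s)


@dataclass
class ChiSquareResult:
    chi2: float
    df: int
    pvalue: float
    subdivided: pd.DataFrame  # per-group 1-df (group vs rest) partition


def convex_polygon(points: np.ndarray) -> Polygon:
    """Convex hull of the movement points, as a polygon in world metres."""
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(points) < 3:
        raise ValueError("need at least 3 points for a convex polygon")
    hull = MultiPoint(points).convex_hull
    if not isinstance(hull, Polygon) or hull.area == 0:
        raise ValueError("points are collinear; convex polygon is degenerate")
    return hull


def comparison_statistic(mask_obj, polygon: Polygon, movement_points: np.ndarray,
                         model_name: str = "") -> ComparisonResult:
    """Compare one model mask against the GPS movement points.

    ``mask_obj`` is any of the connectivity masks (an object with ``mask``,
    ``cell_size`` and ``origin``).  Area percentages are computed on the
    raster: cells whose centre lies inside the polygon form the reference
    area; the model's share of those cells is ``area_pct``.
    """
    if polygon.area == 0:
        raise ValueError("zero-area polygon")
    mask = mask_obj.mask
    cs = mask_obj.cell_size
    ox, oy = mask_obj.origin
    nr, nc = mask.shape
    xs = ox + (np.arange(nc) + 0.5) * cs
    ys = oy - (np.arange(nr) + 0.5) * cs
    gx, gy = np.meshgrid(xs, ys)
    in_poly = shapely.contains_xy(polygon, gx.ravel(), gy.ravel()).reshape(nr, nc)
    if not in_poly.any():
        raise ValueError("polygon does not cover any raster cell centre")
    area_pct = 100.0 * np.count_nonzero(mask & in_poly) / np.count_nonzero(in_poly)

    pts = np.asarray(movement_points, dtype=float).reshape(-1, 2)
    c = np.floor((pts[:, 0] - ox) / cs).astype(int)
    r = np.floor((oy - pts[:, 1]) / cs).astype(int)
    ok = (r >= 0) & (r < nr) & (c >= 0) & (c < nc)
    inside = np.zeros(len(pts), dtype=bool)
    inside[ok] = mask[r[ok], c[ok]]
    points_pct = 100.0 * inside.sum() / len(pts) if len(pts) else 0.0
    res = ComparisonResult(model_name, float(area_pct), float(points_pct))
    if res.statistic is None:
        warnings.warn(f"{model_name or 'model'}: no points inside mask; "
                      "statistic undefined", stacklevel=2)
    return res


def chisq_gof(observed, expected_weights) -> ChiSquareResult:
    """Chi-square goodness of fit with a subdivided per-group partition.

    ``observed`` and ``expected_weights`` are aligned mappings/Series of
    group -> count and group -> availability weight.  Expected counts are
    the weights scaled to the observed total; the subdivided tests pit each
    group against the pooled rest (1 df each), recomputed independently of
    the full-table statistic.
    """
    obs = pd.Series(observed, dtype=float)
    wts = pd.Series(expected_weights, dtype=float).reindex(obs.index)
    if wts.isna().any() or (wts <= 0).any():
        raise ValueError("every group needs a positive expected weight")
    n = obs.sum()
    if n < 1:
        raise ValueError("observed counts sum to zero")
    expected = wts / wts.sum() * n
    if (expected < 1).any():
        warnings.warn("some expected counts are < 1; consider merging groups",
                      stacklevel=2)
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = len(obs) - 1
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    rows = []
    for g in obs.index:
        o2 = np.array([obs[g], n - obs[g]])
        e2 = np.array([expected[g], n - expected[g]])
        c2 = float(((o2 - e2) ** 2 / e2).sum())
        rows.append({"group": g, "chi2": c2, "df": 1,
                     "pvalue": float(stats.chi2.sf(c2, 1))})
    return ChiSquareResult(chi2, df, p, pd.DataFrame(rows).set_index("group"))


def paired_t(series_a, series_b) -> tuple[float, int, float]:
    """Two-sided paired t-test on the differences a - b.

    With a = Euclidean and b = actual path length, longer actual paths give
    a negative t.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length 1-D samples of size >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0):
        raise ValueError("zero-variance differences; t undefined")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), len(a) - 1, float(res.pvalue)


def mann_whitney(sample_obs, sample_ref) -> tuple[float, float]:
    """Mann-Whitney U (midrank ties) with normal-approximation p, two-sided."""
    x = np.asarray(sample_obs, dtype=float)
    y = np.asarray(sample_ref, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def random_matrix_points(
    lc: LandCoverRaster, rt: ResistanceTable, n: int, seed: int
) -> np.ndarray:
    """``n`` points uniform over the non-habitat (matrix) area, reproducible
    under ``seed``; the reference sample for the distance tests."""
    habitat_codes = [c for c, lab in lc.category_names.items()
                     if lab in rt.habitat_labels]
    matrix = ~np.isin(lc.grid, habitat_codes)
    rr, cc = np.nonzero(matrix)
    if len(rr) == 0:
        raise ValueError("raster has no matrix (non-habitat) cells")
    rng = np.random.default_rng(seed)
    if n == 0:
        return np.empty((0, 2))
    pick = rng.integers(0, len(rr), size=n)
    jitter = rng.random((n, 2))
    x = lc.origin[0] + (cc[pick] + jitter[:, 0]) * lc.cell_size
    y = lc.origin[1] - (rr[pick] + jitter[:, 1]) * lc.cell_size
    return np.column_stack([x, y])


class SegmentedRegression:
    """Two-segment continuous piecewise-linear ("broken-stick") model.

    Fits ``y = a + b1 * x + b2 * max(0, x - c)`` by least squares, choosing
    the breakpoint ``c`` by exhaustive search over the observed unique x
    values (with at least two points strictly on each side).  The model is
    continuous at the break; the right-hand slope is ``b1 + b2``.

    Examples
    --------
    >>> x = np.linspace(0, 100, 200)
    >>> y = np.where(x < 40, 2 * x, 80 + 0.1 * (x - 40))
    >>> res = SegmentedRegression(x, y).fit()
    >>> round(res.breakpoint_m, 1)
    40.0
    """

    def __init__(self, x, y):
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be equal-length 1-D arrays")
        if len(self.x) < 8:
            raise ValueError("need at least 8 observations")
        if np.unique(self.x).size < 4:
            raise ValueError("x is (nearly) degenerate: too few distinct values")

    def _candidates(self) -> np.ndarray:
        ux = np.unique(self.x)
        # keep >= 2 points strictly on each side of any candidate break
        return ux[(ux > ux[1]) & (ux < ux[-2])]

    def fit(self) -> "SegmentedRegressionResults":
        x, y = self.x, self.y
        # single-line reference fit
        X0 = np.column_stack([np.ones_like(x), x])
        beta0, rss0 = _ols(X0, y)
        best = (np.inf, None, None)
        for c in self._candidates():
            X = np.column_stack([np.ones_like(x), x, np.maximum(0.0, x - c)])
            beta, rss = _ols(X, y)
            if rss < best[0] - 1e-12:
                best = (rss, c, beta)
        rss, c, beta = best
        if c is None:
            raise ValueError("no admissible breakpoint candidate")
        a, b1, b2 = beta
        return SegmentedRegressionResults(
            model=self,
            breakpoint_m=float(c),
            left_intercept=float(a),
            left_slope=float(b1),
            right_slope=float(b1 + b2),
            right_intercept=float(a + b1 * c - (b1 + b2) * c),
            rss=float(rss),
            rss_linear=float(rss0),
            linear_params=tuple(float(v) for v in beta0),
            nobs=len(x),
        )


@dataclass
class SegmentedRegressionResults:
    """Fit results for :class:`SegmentedRegression`."""

    model: SegmentedRegression
    breakpoint_m: float
    left_intercept: float
    left_slope: float
    right_slope: float
    right_intercept: float
    rss: float
    rss_linear: float
    linear_params: tuple[float, float]
    nobs: int

    @property
    def improvement(self) -> float:
        """Fractional RSS reduction of the broken-stick fit over a single
        line; near zero means the break is unsupported."""
        if self.rss_linear <= 0:
            return 0.0
        return 1.0 - self.rss / self.rss_linear

    @property
    def break_pvalue(self) -> float:
        """Approximate F-test (2 extra parameters) of the broken-stick fit
        against a single line.  The breakpoint is searched, so the p-value
        is anti-conservative; it is a screening diagnostic, not an exact
        test."""
        df2 = self.nobs - 4
        if df2 <= 0 or self.rss_linear <= 0:
            return 1.0
        if self.rss <= 0:
            return 0.0
        f = ((self.rss_linear - self.rss) / 2.0) / (self.rss / df2)
        return float(stats.f.sf(f, 2, df2))

    @property
    def supported(self) -> bool:
        return self.break_pvalue < 0.01

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return (self.left_intercept + self.left_slope * x
                + (self.right_slope - self.left_slope)
                * np.maximum(0.0, x - self.breakpoint_m))

    def summary(self) -> str:
        lines = [
            "Segmented (breakpoint) regression",
            "=" * 40,
            f"n obs               {self.nobs:>12d}",
            f"breakpoint (m)      {self.breakpoint_m:>12.3f}",
            f"left slope          {self.left_slope:>12.4f}",
            f"right slope         {self.right_slope:>12.4f}",
            f"left intercept      {self.left_intercept:>12.4f}",
            f"RSS (segmented)     {self.rss:>12.4f}",
            f"RSS (single line)   {self.rss_linear:>12.4f}",
            f"RSS improvement     {self.improvement:>12.1%}",
            f"break supported     {str(self.supported):>12s}",
        ]
        return "\n".join(lines)


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def breakpoint_regression(x, y) -> SegmentedRegressionResults:
    """Convenience wrapper: fit :class:`SegmentedRegression` on (x, y)."""
    return SegmentedRegression(x, y).fit()


def rank_use(observed, expected) -> pd.DataFrame:
    """Rank groups by observed/expected use ratio, descending.

    Ties break alphabetically; a group with observations but zero
    expectation gets an infinite ratio and ranks first.
    """
    obs = pd.Series(observed, dtype=float)
    exp = pd.Series(expected, dtype=float).reindex(obs.index)
    if exp.isna().any():
        raise ValueError("observed and expected group sets differ")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = obs / exp
    ratio[(exp == 0) & (obs > 0)] = np.inf
    ratio[(exp == 0) & (obs == 0)] = 0.0
    frame = pd.DataFrame({"observed": obs, "expected": exp, "ratio": ratio})
    order = np.lexsort((frame.index.astype(str), -frame["ratio"].to_numpy()))
    frame = frame.iloc[order]
    frame["rank"] = np.arange(1, len(frame) + 1)
    return frame
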