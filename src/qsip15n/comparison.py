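"""Method-comparison statistics: Passing-Bablok regression and group tests.

Passing-Bablok regression estimates the structural relationship between
two measurement methods from the median of pairwise slopes; it assumes a
linear, highly correlated relationship and is robust to outliers.  Two
estimators are provided: the classical shifted-median rule and an
equivariant angle-median variant that is exactly invariant under
exchanging the axes.  Confidence intervals come from a quantile
bootstrap over paired observations; a slope CI excluding 1 indicates a
proportional difference between methods, an intercept CI excluding 0 a
constant difference (closed intervals).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)

Estimator = Literal["equivariant", "classical"]


def _pairwise_diffs(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices(len(x), k=1)
    dx = x[iu[1]] - x[iu[0]]
    dy = y[iu[1]] - y[iu[0]]
    return dx, dy


def passing_bablok(
    x, y, equivariant: bool = True
) -> tuple[float, float]:
    """Passing-Bablok slope and intercept.

    Classical mode: slope is the shifted median of all pairwise slopes
    S = dy/dx (h < l), excluding S == -1 and pairs with dx == 0, with
    offset K = #{S < -1}.  Equivariant mode: slope = tan(median of
    pairwise angles atan2(dy, dx) mapped to (-pi/2, pi/2]); pairs with
    dx == 0, dy != 0 contribute angle pi/2.  Both use intercept =
    median(y - slope * x).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and aligned")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("all x identical: slope undefined")
    dx, dy = _pairwise_diffs(x, y)
    nonzero = ~((dx == 0) & (dy == 0))
    dx, dy = dx[nonzero], dy[nonzero]

    if equivariant:
        theta = np.arctan2(dy, dx)
        # fold direction: map to (-pi/2, pi/2]
        theta = np.mod(theta + np.pi / 2.0, np.pi) - np.pi / 2.0
        theta[theta == -np.pi / 2.0] = np.pi / 2.0
        med = float(np.median(theta))
        if np.isclose(abs(med), np.pi / 2.0):
            raise ValueError("median pairwise angle is vertical: slope undefined")
        slope = float(np.tan(med))
    else:
        ok = dx != 0
        s = dy[ok] / dx[ok]
        s = s[s != -1.0]
        if len(s) == 0:
            raise ValueError("no valid pairwise slopes")
        s.sort()
        k = int(np.sum(s < -1.0))
        n = len(s)
        if n % 2 == 1:
            idx = (n - 1) // 2 + k
            if idx >= n:
                raise ValueError("shifted median index out of range (too many slopes < -1)")
            slope = float(s[idx])
        else:
            i1, i2 = n // 2 - 1 + k, n // 2 + k
            if i2 >= n:
                raise ValueError("shifted median index out of range (too many slopes < -1)")
            slope = float(0.5 * (s[i1] + s[i2]))
    intercept = float(np.median(y - slope * x))
    return slope, intercept


def interpret_comparison(
    slope_ci: tuple[float, float], intercept_ci: tuple[float, float]
) -> tuple[bool, bool]:
    """(proportional_difference, constant_difference) from closed 95% CIs.

    A proportional difference is declared when the slope CI does not
    include 1; a constant difference when the intercept CI does not
    include 0.  Bounds touching the reference value count as inclusion.
    """
    prop = not (slope_ci[0] <= 1.0 <= slope_ci[1])
    const = not (intercept_ci[0] <= 0.0 <= intercept_ci[1])
    return prop, const


@dataclass(frozen=True)
class PassingBablokResults:
    """Fitted Passing-Bablok regression with bootstrap CIs and verdicts."""

    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    n: int
    pearson_r: float
    estimator: str
    n_boot: int
    level: float
    proportional_difference: bool
    constant_difference: bool

    def summary(self) -> str:
        lines = [
            "Passing-Bablok method comparison",
            "=" * 44,
            f"estimator            {self.estimator}",
            f"n pairs              {self.n}",
            f"slope                {self.slope:.4f}  "
            f"({100 * self.level:.0f}% CI {self.slope_ci[0]:.4f}, {self.slope_ci[1]:.4f})",
            f"intercept            {self.intercept:.4f}  "
            f"({100 * self.level:.0f}% CI {self.intercept_ci[0]:.4f}, {self.intercept_ci[1]:.4f})",
            f"Pearson r            {self.pearson_r:.4f}",
            f"proportional diff.   {'yes (slope CI excludes 1)' if self.proportional_difference else 'no'}",
            f"constant diff.       {'yes (intercept CI excludes 0)' if self.constant_difference else 'no'}",
            f"bootstrap            quantile, B={self.n_boot}",
        ]
        return "\n".join(lines)


class PassingBablok:
    """Model object for a paired method comparison.

    Parameters
    ----------
    x, y : array-like
        Paired measurements of the same quantity by two methods
        (x: reference/first method, y: comparison method).
    estimator : {'equivariant', 'classical'}
        Slope estimator variant; the equivariant angle-median form is
        the default and is exactly invariant under axis exchange.
    """

    def __init__(self, x, y, estimator: Estimator = "equivariant"):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        keep = np.isfinite(x) & np.isfinite(y)
        self.x, self.y = x[keep], y[keep]
        if len(self.x) < 3:
            raise ValueError("need at least 3 complete pairs")
        if estimator not in ("equivariant", "classical"):
            raise ValueError(f"unknown estimator {estimator!r}")
        self.estimator = estimator

    def fit(
        self, n_boot: int = 1999, level: float = 0.95, seed: int | None = None
    ) -> PassingBablokResults:
        """Fit and bootstrap the regression.

        Pairs are resampled with replacement ``n_boot`` times; the CI is
        the (alpha/2, 1-alpha/2) quantile of the bootstrap estimates.
        Degenerate resamples (all x equal) are redrawn, capped at 10x
        ``n_boot`` attempts.  Deterministic given ``seed``.
        """
        if len(self.x) < 10:
            warnings.warn("fewer than 10 pairs: bootstrap CIs are unreliable")
        eq = self.estimator == "equivariant"
        slope, intercept = passing_bablok(self.x, self.y, equivariant=eq)
        rng = np.random.default_rng(seed)
        n = len(self.x)
        slopes = np.empty(n_boot)
        intercepts = np.empty(n_boot)
        attempts = 0
        i = 0
        while i < n_boot:
            if attempts > 10 * n_boot:
                raise RuntimeError("too many degenerate bootstrap resamples")
            attempts += 1
            idx = rng.integers(0, n, size=n)
            bx, by = self.x[idx], self.y[idx]
            if np.ptp(bx) == 0:
                continue
            try:
                b, a = passing_bablok(bx, by, equivariant=eq)
            except ValueError:
                continue
            slopes[i], intercepts[i] = b, a
            i += 1
        alpha = 1.0 - level
        s_ci = tuple(np.quantile(slopes, [alpha / 2, 1 - alpha / 2]))
        a_ci = tuple(np.quantile(intercepts, [alpha / 2, 1 - alpha / 2]))
        r = float(stats.pearsonr(self.x, self.y).statistic) if np.ptp(self.y) > 0 else float("nan")
        prop, const = interpret_comparison(s_ci, a_ci)
        return PassingBablokResults(
            slope=slope,
            intercept=intercept,
            slope_ci=(float(s_ci[0]), float(s_ci[1])),
            intercept_ci=(float(a_ci[0]), float(a_ci[1])),
            n=n,
            pearson_r=r,
            estimator=self.estimator,
            n_boot=n_boot,
            level=level,
            proportional_difference=prop,
            constant_difference=const,
        )


_F_CAP = 1e12


def genus_group_test(values_a, values_b) -> tuple[float, float]:
    """One-way fixed-effects ANOVA between two groups of replicate values.

    Equivalent to the pooled-variance t-test squared.  Missing values
    are dropped; each group needs >= 2 values.  Degenerate cases: equal
    constant groups give (0, 1); separated constant groups give a large
    finite F with p computed from it.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    na, nb = len(a), len(b)
    grand = (a.sum() + b.sum()) / (na + nb)
    ssb = na * (a.mean() - grand) ** 2 + nb * (b.mean() - grand) ** 2
    ssw = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    df1, df2 = 1, na + nb - 2
    if ssw == 0:
        if ssb == 0:
            return 0.0, 1.0
        f = _F_CAP
    else:
        f = (ssb / df1) / (ssw / df2)
    p = float(stats.f.sf(f, df1, df2))
    return float(f), p


def significance_tier(p: float) -> str:
    """Marker tiers used in per-genus annotation: . / * / ** / ***."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    if p <= 0.10:
        return "."
    return ""
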