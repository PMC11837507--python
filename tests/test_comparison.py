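import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qsip15n.comparison import (
    PassingBablok,
    genus_group_test,
    interpret_comparison,
    passing_bablok,
    significance_tier,
)


def brute_force_classical_pb(x, y):
    """Independent enumeration oracle: all pairwise slopes, shifted median.

    Returns None when the shifted-median index falls outside the slope
    list (heavily negative relationships, where the estimator is
    undefined).
    """
    slopes = []
    n = len(x)
    for h in range(n):
        for l in range(h + 1, n):
            dx, dy = x[l] - x[h], y[l] - y[h]
            if dx == 0:
                continue
            s = dy / dx
            if s != -1.0:
                slopes.append(s)
    if not slopes:
        return None
    slopes.sort()
    k = sum(1 for s in slopes if s < -1.0)
    m = len(slopes)
    if m % 2 == 1:
        if (m - 1) // 2 + k >= m:
            return None
        b = slopes[(m - 1) // 2 + k]
    else:
        if m // 2 + k >= m:
            return None
        b = 0.5 * (slopes[m // 2 - 1 + k] + slopes[m // 2 + k])
    a = float(np.median([yy - b * xx for xx, yy in zip(x, y)]))
    return b, a


class TestEstimators:
    def test_exact_line(self):
        for eq in (True, False):
            b, a = passing_bablok([1, 2, 3], [1, 2, 3], equivariant=eq)
            assert b == pytest.approx(1.0) and a == pytest.approx(0.0)

    def test_three_point_example(self):
        # pairwise slopes {1, 1.5, 2} -> median 1.5; intercept median(y-1.5x)=0.5
        b, a = passing_bablok([1, 2, 3], [2, 3, 5], equivariant=False)
        assert b == pytest.approx(1.5) and a == pytest.approx(0.5)

    def test_long_noiseless_line(self):
        x = np.linspace(0, 5, 50)
        for eq in (True, False):
            b, a = passing_bablok(x, 2 * x + 1, equivariant=eq)
            assert b == pytest.approx(2.0, abs=1e-12)
            assert a == pytest.approx(1.0, abs=1e-12)

    def test_all_x_identical_raises(self):
        with pytest.raises(ValueError, match="identical|undefined"):
            passing_bablok([1, 1, 1], [1, 2, 3])

    @settings(max_examples=1000, deadline=None, derandomize=True)
    @given(n=st.integers(3, 6), seed=st.integers(0, 10**6))
    def test_classical_matches_brute_force(self, n, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, n)
        y = 0.8 * x + rng.normal(0, 0.5, n)
        oracle = brute_force_classical_pb(list(x), list(y))
        if oracle is None:
            with pytest.raises(ValueError):
                passing_bablok(x, y, equivariant=False)
            return
        b, a = passing_bablok(x, y, equivariant=False)
        assert b == pytest.approx(oracle[0], rel=1e-12)
        assert a == pytest.approx(oracle[1], rel=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6), n=st.integers(5, 25))
    def test_equivariant_swap_inverts_slope(self, seed, n):
        # strictly increasing x and y: all pairwise slopes positive, so
        # the angle map under axis exchange is order-reversing and the
        # median inverts exactly (odd pair counts only)
        if (n * (n - 1) // 2) % 2 == 0:
            return
        rng = np.random.default_rng(seed)
        x = np.cumsum(rng.uniform(0.05, 0.3, n))
        y = np.cumsum(rng.uniform(0.05, 0.3, n))
        b, _ = passing_bablok(x, y, equivariant=True)
        b_swap, _ = passing_bablok(y, x, equivariant=True)
        assert b_swap == pytest.approx(1.0 / b, rel=1e-9)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6), c=st.floats(0.1, 10))
    def test_scale_equivariance_classical(self, seed, c):
        # classical shifted median is scale equivariant only when no
        # pairwise slope crosses -1 under scaling; monotone data keeps
        # every slope positive, where the property is exact
        rng = np.random.default_rng(seed)
        x = np.cumsum(rng.uniform(0.05, 0.3, 15))
        y = np.cumsum(rng.uniform(0.05, 0.3, 15))
        b, a = passing_bablok(x, y, equivariant=False)
        bc, ac = passing_bablok(x, c * y, equivariant=False)
        assert bc == pytest.approx(c * b, rel=1e-9)
        assert ac == pytest.approx(c * a, rel=1e-9)

    def test_vertical_ties_handled(self):
        # dx == 0 pairs: angle pi/2 in equivariant mode, excluded classically
        x = [1.0, 1.0, 2.0, 3.0]
        y = [1.0, 2.0, 2.0, 3.0]
        b_eq, _ = passing_bablok(x, y, equivariant=True)
        b_cl, _ = passing_bablok(x, y, equivariant=False)
        assert np.isfinite(b_eq) and np.isfinite(b_cl)


class TestBootstrap:
    def test_noiseless_degenerate_ci(self):
        # classical estimator: pairwise slopes are exactly 1.0, so every
        # resample reproduces the point estimate bit-for-bit
        x = np.linspace(0, 1, 20)
        fit = PassingBablok(x, x, estimator="classical").fit(n_boot=199, seed=1)
        assert fit.slope_ci == (1.0, 1.0)
        assert fit.intercept_ci == (0.0, 0.0)
        assert not fit.proportional_difference and not fit.constant_difference

    def test_determinism(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 1, 30)
        y = 0.8 * x + rng.normal(0, 0.05, 30)
        f1 = PassingBablok(x, y).fit(n_boot=299, seed=42)
        f2 = PassingBablok(x, y).fit(n_boot=299, seed=42)
        assert f1.slope_ci == f2.slope_ci and f1.intercept_ci == f2.intercept_ci

    def test_coverage_at_study_effect_size(self):
        # y = 0.81 x + 0.01 + N(0, 0.02): CI should cover the true slope
        # in the large majority of replicates
        hits = 0
        runs = 20
        for seed in range(runs):
            rng = np.random.default_rng(1000 + seed)
            x = rng.uniform(0, 0.6, 500)
            y = 0.81 * x + 0.01 + rng.normal(0, 0.02, 500)
            fit = PassingBablok(x, y).fit(n_boot=199, seed=seed)
            if fit.slope_ci[0] <= 0.81 <= fit.slope_ci[1]:
                hits += 1
        assert hits >= 17

    def test_small_n_warns(self):
        with pytest.warns(UserWarning, match="fewer than 10"):
            PassingBablok([1, 2, 3, 4], [1, 2, 3, 5]).fit(n_boot=49, seed=0)

    def test_nonfinite_pairs_dropped(self):
        x = [1.0, 2.0, 3.0, np.nan, 5.0]
        y = [1.0, 2.0, 3.0, 4.0, np.nan]
        m = PassingBablok(x, y)
        assert len(m.x) == 3

    def test_summary_mentions_key_quantities(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 1, 40)
        y = 0.5 * x + 0.3 + rng.normal(0, 0.01, 40)
        s = PassingBablok(x, y).fit(n_boot=199, seed=0).summary()
        assert "slope" in s and "Pearson" in s and "intercept" in s


class TestInterpretation:
    def test_both_differences(self):
        assert interpret_comparison((0.76, 0.87), (0.001, 0.019)) == (True, True)

    def test_neither_difference(self):
        assert interpret_comparison((0.95, 1.02), (-0.0001, 0.000)) == (False, False)

    def test_closed_boundary_counts_as_inclusion(self):
        assert interpret_comparison((0.9, 1.0), (0.0, 0.01)) == (False, False)


class TestGroupTest:
    def test_identical_constant_groups(self):
        assert genus_group_test([1, 1, 1], [1, 1, 1]) == (0.0, 1.0)

    def test_complete_separation(self):
        f, p = genus_group_test([0, 0, 0], [1, 1, 1])
        assert math.isfinite(f) and f > 1e6
        assert p < 1e-10

    def test_closed_form_example(self):
        f, p = genus_group_test([1, 2, 3], [2, 3, 4])
        assert f == pytest.approx(1.5)
        assert p == pytest.approx(0.2878641, abs=1e-6)

    def test_matches_scipy_on_regular_data(self):
        from scipy.stats import f_oneway

        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 7), rng.normal(0.5, 1, 7)
        f, p = genus_group_test(a, b)
        ref = f_oneway(a, b)
        assert f == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_too_few_values(self):
        with pytest.raises(ValueError, match="at least 2"):
            genus_group_test([1.0], [1.0, 2.0])

    def test_tiers(self):
        assert significance_tier(0.0005) == "***"
        assert significance_tier(0.005) == "**"
        assert significance_tier(0.03) == "*"
        assert significance_tier(0.08) == "."
        assert significance_tier(0.5) == ""
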