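"""Rank tests and regression against brute-force enumeration oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trabmorph import compare_all, linear_regression_f, mann_whitney_u, paired_signflip_test


def brute_force_mwu_p(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all group assignments.

    U for sample x = number of (xi, yj) pairs with xi > yj. The p-value is
    the fraction of C(n1+n2, n1) label assignments whose min(U, n1*n2 - U)
    is at least as extreme as observed.
    """
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b)

    u_obs = u_stat(x, y)
    extreme_obs = min(u_obs, n1 * len(y) - u_obs)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = u_stat(xs, ys)
        if min(u, n1 * len(ys) - u) <= extreme_obs:
            count += 1
        total += 1
    return count / total


def brute_force_ols(x, y):
    """Slope/intercept/R^2/F from the normal equations, no library calls."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    sxx = ((x - x.mean()) ** 2).sum()
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    yhat = intercept + slope * x
    ss_res = ((y - yhat) ** 2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1 - ss_res / ss_tot
    f = (ss_tot - ss_res) / (ss_res / (n - 2))
    return slope, intercept, r2, f


class TestMannWhitney:
    def test_frozen_small_sample_oracle(self):
        """x={1,2}, y={3,4}: U=0, and 2 of the 6 assignments are as extreme."""
        r = mann_whitney_u([1.0, 2.0], [3.0, 4.0])
        assert r.U == 0
        assert r.p == pytest.approx(1.0 / 3.0)
        assert r.method == "exact"

    def test_identical_groups_p_one(self):
        x = np.arange(8, dtype=float)
        r = mann_whitney_u(x, x + 0.5)  # fully interleaved
        assert r.p > 0.5

    def test_fully_separated_eight_vs_eight(self):
        """Complete separation at n=8 vs 8: p = 2 / C(16, 8) = 2/12870."""
        r = mann_whitney_u(np.arange(8.0), np.arange(10.0, 18.0))
        assert r.method == "exact"
        assert r.p == pytest.approx(2.0 / 12870.0)

    def test_symmetry_u1_plus_u2(self):
        x = [0.3, 1.7, 2.2, 5.0]
        y = [0.9, 1.1, 4.0]
        a = mann_whitney_u(x, y)
        b = mann_whitney_u(y, x)
        assert a.U + b.U == len(x) * len(y)
        assert a.p == pytest.approx(b.p)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_exact_p_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=4)
        y = rng.normal(loc=0.8, size=4)
        r = mann_whitney_u(x, y)
        assert r.method == "exact"
        assert r.p == pytest.approx(brute_force_mwu_p(x, y), abs=1e-12)

    def test_ties_fall_back_to_normal_approximation(self):
        r = mann_whitney_u([1.0, 2.0, 2.0, 3.0], [2.0, 4.0, 5.0, 6.0])
        assert r.method == "normal_approx"
        assert 0 < r.p <= 1

    def test_normal_approximation_close_to_exact_at_n8(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=8)
        y = rng.normal(loc=0.5, size=8)
        exact = mann_whitney_u(x, y).p
        # force the asymptotic path by adding a distant tied pair to each group
        from scipy import stats as sps

        approx = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert approx == pytest.approx(exact, abs=0.02)

    def test_empty_sample_is_an_error(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestSignFlip:
    def test_zero_differences_p_one(self):
        assert paired_signflip_test([1, 2, 3], [1, 2, 3]) == 1.0

    def test_consistent_shift_is_extreme(self):
        x = np.arange(10, dtype=float)
        p = paired_signflip_test(x + 5.0, x)
        assert p == pytest.approx(2.0 / 2**10)


class TestRegression:
    def test_matches_normal_equations(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 10, 12)
        y = 2.5 * x + 1.0 + rng.normal(0, 0.5, 12)
        r = linear_regression_f(x, y)
        slope, intercept, r2, f = brute_force_ols(x, y)
        assert r.slope == pytest.approx(slope, abs=1e-10)
        assert r.intercept == pytest.approx(intercept, abs=1e-10)
        assert r.R2 == pytest.approx(r2, abs=1e-10)
        assert r.F == pytest.approx(f, rel=1e-10)

    @settings(max_examples=30, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=-100, max_value=100),
            min_size=5,
            max_size=12,
            unique=True,
        ),
        st.integers(min_value=0, max_value=1000),
    )
    def test_property_matches_normal_equations(self, xs, seed):
        x = np.asarray(xs)
        rng = np.random.default_rng(seed)
        y = 0.7 * x - 3.0 + rng.normal(0, 1.0, len(x))
        if np.ptp(y) == 0:
            return
        r = linear_regression_f(x, y)
        slope, intercept, r2, _ = brute_force_ols(x, y)
        assert r.slope == pytest.approx(slope, abs=1e-8)
        assert r.intercept == pytest.approx(intercept, abs=1e-8)
        assert r.R2 == pytest.approx(r2, abs=1e-8)

    def test_perfect_fit_reports_extreme_f(self):
        """Exactly collinear data: R^2 = 1 and the F statistic is infinite up
        to floating-point residual noise in the solver."""
        x = np.arange(5.0)
        r = linear_regression_f(x, 3 * x + 2)
        assert r.R2 == pytest.approx(1.0)
        assert math.isinf(r.F) or r.F > 1e15
        assert r.p_F < 1e-10

    def test_r2_invariant_under_affine_response(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1, 10)
        y = x + rng.normal(0, 0.2, 10)
        assert linear_regression_f(x, 5 * y - 7).R2 == pytest.approx(
            linear_regression_f(x, y).R2
        )

    def test_slope_equivariant_under_x_scaling(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 1, 10)
        y = x + rng.normal(0, 0.2, 10)
        assert linear_regression_f(2 * x, y).slope == pytest.approx(
            linear_regression_f(x, y).slope / 2
        )

    def test_confidence_band_narrowest_at_x_mean(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 10, 15)
        y = x + rng.normal(0, 1, 15)
        r = linear_regression_f(x, y)
        grid = np.array([x.mean() - 5, x.mean(), x.mean() + 5])
        yhat, lo, hi = r.confidence_band(grid)
        widths = hi - lo
        assert widths[1] < widths[0] and widths[1] < widths[2]
        assert np.all(lo < yhat) and np.all(yhat < hi)

    def test_too_few_points_is_an_error(self):
        with pytest.raises(ValueError, match="n >= 3"):
            linear_regression_f([1, 2], [1, 2])

    def test_constant_x_is_an_error(self):
        with pytest.raises(ValueError, match="constant"):
            linear_regression_f([1, 1, 1, 1], [1, 2, 3, 4])


def _pairs_frame(hi, lo, param="TbTh"):
    rows = []
    for i, v in enumerate(hi):
        rows.append({"branch": "hires", "voi": f"v{i}", param: v})
    for i, v in enumerate(lo):
        rows.append({"branch": "degraded", "voi": f"v{i}", param: v})
    return pd.DataFrame(rows)


class TestCompareAll:
    def test_zero_degradation_not_significant_slope_one(self):
        rng = np.random.default_rng(0)
        hi = rng.uniform(100, 300, 8)
        noise = rng.normal(0, 1e-6, 8)
        comps, means, regs = compare_all(_pairs_frame(hi, hi + noise))
        assert not comps[0].significant
        assert means.loc[0, "p_rank"] > 0.5
        assert regs.loc[0, "slope"] == pytest.approx(1.0, abs=1e-4)
        assert regs.loc[0, "R2"] == pytest.approx(1.0, abs=1e-6)

    def test_large_shift_detected(self):
        rng = np.random.default_rng(1)
        hi = rng.uniform(100, 120, 8)
        comps, means, _ = compare_all(_pairs_frame(hi, hi + 200.0))
        assert comps[0].significant
        assert bool(means.loc[0, "significant_strict"])
        assert means.loc[0, "p_rank"] == pytest.approx(2.0 / 12870.0)

    def test_nonfinite_pairs_dropped(self):
        hi = [1.0, 2.0, 3.0, 4.0, np.nan]
        lo = [1.1, 2.1, 3.1, 4.1, 5.0]
        comps, means, _ = compare_all(_pairs_frame(hi, lo))
        assert means.loc[0, "n"] == 4

    def test_two_vois_is_an_error(self):
        with pytest.raises(ValueError, match=">= 3"):
            compare_all(_pairs_frame([1.0, 2.0], [1.5, 2.5]))

    def test_mismatched_vois_is_an_error(self):
        df = _pairs_frame([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        df.loc[5, "voi"] = "other"
        with pytest.raises(ValueError, match="different VOIs"):
            compare_all(df)
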