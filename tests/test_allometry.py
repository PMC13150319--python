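"""SMA/OLS estimators: exact cases, independent oracles, invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

from widenedpipe import (
    BranchRecord,
    Dataset,
    SMA,
    SimConfig,
    fit_ols,
    fit_sma,
    length_effect,
    number_allometry,
    simulate_dataset,
    table1,
    widening_regression,
)
from widenedpipe.allometry import test_slope as sma_test_slope


def sma_slope_brute_force(x, y):
    """Independent SMA oracle: minimize the summed triangle areas.

    The triangle formed between a point and the line (via its vertical and
    horizontal projections) has area r_i^2 / (2|b|) with r_i the vertical
    residual.  For fixed slope the optimal intercept is ybar - b*xbar, so
    the problem reduces to a 1-d minimization over the slope, done
    numerically on each sign branch.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    Sxx, Syy, Sxy = (xc @ xc), (yc @ yc), (xc @ yc)

    def area(b):
        return (Syy - 2 * b * Sxy + b * b * Sxx) / (2 * abs(b))

    best = None
    for lo, hi in ((1e-12, 1e6), (-1e6, -1e-12)):
        res = optimize.minimize_scalar(
            area, bounds=(lo, hi), method="bounded", options={"xatol": 1e-12}
        )
        if best is None or res.fun < best.fun:
            best = res
    return float(best.x)


def random_xy(rng, n=10):
    x = rng.normal(0, 1, n)
    y = rng.normal(0, 1, n) + rng.uniform(-2, 2) * x
    if np.ptp(x) == 0 or np.ptp(y) == 0:  # pragma: no cover
        x[0] += 1.0
    return x, y


class TestFitSMA:
    def test_identity_data(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        f = fit_sma(x, x.copy())
        assert f.slope == pytest.approx(1.0, abs=1e-14)
        assert f.intercept == pytest.approx(0.0, abs=1e-14)
        assert f.r2 == pytest.approx(1.0, abs=1e-14)

    def test_five_point_worked_example(self):
        x = np.array([1, 2, 3, 4, 5], float)
        y = np.array([1.1, 1.9, 3.2, 4.1, 4.8])
        f = fit_sma(x, y)
        assert f.slope == pytest.approx(0.9648, abs=5e-4)
        assert f.r == pytest.approx(0.995, abs=5e-3)
        assert f.slope == pytest.approx(sma_slope_brute_force(x, y), abs=1e-6)

    def test_slope_matches_triangle_area_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            x, y = random_xy(rng)
            assert fit_sma(x, y).slope == pytest.approx(
                sma_slope_brute_force(x, y), abs=1e-6
            )

    def test_degenerate_and_short_inputs_raise(self):
        with pytest.raises(ValueError, match="zero variance"):
            fit_sma([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="at least 3"):
            fit_sma([1.0, 2.0], [1.0, 2.0])

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_identities_hold(self, seed):
        """b_SMA = b_OLS/|r|, axis-swap reciprocity, |b_OLS| <= |b_SMA|."""
        rng = np.random.default_rng(seed)
        x, y = random_xy(rng, n=12)
        f = fit_sma(x, y)
        b_ols = np.polyfit(x, y, 1)[0]
        assert f.slope == pytest.approx(b_ols / abs(f.r), rel=1e-12)
        assert f.slope == pytest.approx(1.0 / fit_sma(y, x).slope, rel=1e-12)
        assert abs(b_ols) <= abs(f.slope) + 1e-12
        assert f.slope_ci[0] <= f.slope <= f.slope_ci[1]


class TestSlopeTest:
    def test_exact_isometry_gives_p_one(self):
        x = np.array([1.0, 2.0, 4.0, 7.0])
        assert sma_test_slope(x, x + 3.0, b0=1.0) == 1.0

    def test_detects_steep_slope(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(50):
            x = rng.normal(0, 1, 200)
            y = 1.5 * x + rng.normal(0, 0.5, 200)
            if sma_test_slope(x, y, b0=1.0) < 0.001:
                hits += 1
        assert hits >= 49

    def test_two_sided_consistency_with_ci(self):
        rng = np.random.default_rng(1)
        x, y = random_xy(rng, n=50)
        res = SMA(x, y).fit()
        # p > alpha exactly when b0 inside the 95% CI, at the CI edges ~ 0.05
        for edge in res.slope_ci:
            assert res.test_slope(edge) == pytest.approx(0.05, abs=5e-3)


class TestFitOLS:
    def test_exact_linear_data(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (20, 2))
        y = 2 * X[:, 0] - 3 * X[:, 1] + 1
        m = fit_ols(y, X)
        assert m.coef("x1") == pytest.approx(2.0, abs=1e-10)
        assert m.coef("x2") == pytest.approx(-3.0, abs=1e-10)
        assert m.intercept == pytest.approx(1.0, abs=1e-10)
        assert m.r2 == pytest.approx(1.0, abs=1e-12)

    def test_six_point_normal_equations_oracle(self):
        # Small fixed design solved through the normal equations directly.
        X = np.array([[1.0, 2.0], [2.0, 1.0], [3.0, 5.0], [4.0, 2.0], [5.0, 7.0], [6.0, 3.0]])
        y = np.array([3.1, 2.9, 8.4, 5.2, 11.9, 7.0])
        D = np.column_stack([np.ones(6), X])
        beta = np.linalg.solve(D.T @ D, D.T @ y)
        m = fit_ols(y, X)
        assert m.intercept == pytest.approx(beta[0], rel=1e-10)
        assert m.coef("x1") == pytest.approx(beta[1], rel=1e-10)
        assert m.coef("x2") == pytest.approx(beta[2], rel=1e-10)

    def test_collinear_columns_named(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4, 5, 6], "b": [2.0, 4, 6, 8, 10, 12]})
        with pytest.raises(ValueError, match="collinear"):
            fit_ols(np.arange(6, dtype=float), X)


class TestStemAnalyses:
    def test_number_allometry_exact_null(self, noiseless_dataset):
        f = number_allometry(noiseless_dataset)
        assert f.slope == pytest.approx(1.0, abs=1e-12)
        assert f.intercept == pytest.approx(0.0, abs=1e-12)

    def test_number_allometry_recovers_isometry_with_noise(self):
        ds = simulate_dataset(SimConfig(seed=123, sigma_n=0.05))
        f = number_allometry(ds)
        assert 0.9 < f.slope < 1.1
        assert f.slope_ci[0] < 1.0 < f.slope_ci[1]

    def test_widening_exact_power_law(self):
        # D = 10 * dist^0.2 exactly at both sections
        records = []
        rng = np.random.default_rng(7)
        for i in range(40):
            db, dt = rng.uniform(100, 700), rng.uniform(5, 30)
            records.append(
                BranchRecord(
                    f"s{i}", 100, 100, 10 * db**0.2, 10 * dt**0.2, db, dt
                )
            )
        f = widening_regression(Dataset(records=records))
        assert f.slope == pytest.approx(0.2, abs=1e-10)
        assert f.r2 == pytest.approx(1.0, abs=1e-12)
        assert f.n == 80  # two pooled points per branch

    def test_widening_recovery_under_noise(self):
        ds = simulate_dataset(SimConfig(seed=9, sigma_d=0.25))
        f = widening_regression(ds)
        assert 0.15 < f.slope < 0.25

    def test_length_effect_null_is_nonsignificant(self, null_dataset):
        m = length_effect(null_dataset)
        lo, hi = m.conf_int.loc["length"]
        assert lo < 0 < hi

    def test_length_effect_detects_geometric_furcation(self):
        from widenedpipe import FurcationScenario

        ds = simulate_dataset(
            SimConfig(seed=21, scenario=FurcationScenario(kind="geometric"))
        )
        m = length_effect(ds)
        assert m.coef("length") > 0
        assert float(m.pvalues["length"]) < 1e-6

    def test_table1_shape_and_methods(self, null_dataset):
        t = table1(null_dataset)
        assert list(t.method) == ["SMA", "OLS", "OLS"]
        assert len(t) == 3
        assert t.loc[1, "length_pvalue"] == pytest.approx(
            float(length_effect(null_dataset).pvalues["length"])
        )

    def test_summary_prints_slope_and_p(self, null_dataset):
        df = null_dataset.to_frame()
        res = SMA(
            np.log10(df.n_base.astype(float)),
            np.log10(df.n_tip.astype(float)),
            names=("log10_n_base", "log10_n_tip"),
        ).fit()
        s = res.summary()
        assert "slope" in s and "P(b = 1)" in s
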