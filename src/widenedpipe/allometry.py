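"""Bivariate SMA and OLS estimators and the three stem-allometry analyses.

Standardized major axis (SMA, also called reduced major axis) regression
treats both variables symmetrically: the fitted slope is
``sign(r) * sd(y) / sd(x)``, the line that minimizes the summed areas of the
triangles formed between each point and the line.  It is the appropriate
model-II estimator when neither variable causes the other — here, conduit
counts at the tip and base of a stem segment, which are formed concurrently
by the cambium in response to the same leaf area.

The module follows the statsmodels convention: :class:`SMA` is a model built
from data whose :meth:`SMA.fit` returns an :class:`SMAResults` carrying the
estimates, their confidence intervals and hypothesis tests, and a
``summary()`` table.  The functional entry points (:func:`fit_sma`,
:func:`fit_ols`) and the three named analyses (:func:`number_allometry`,
:func:`length_effect`, :func:`widening_regression`) are thin wrappers.

All three named analyses work on log10-transformed variables: conduit
counts, diameters and lengths arise from multiplicative processes, and the
furcation hypothesis itself is multiplicative (tip counts growing as a power
of base counts).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .data import Dataset

__all__ = [
    "SMA",
    "SMAResults",
    "LinearFit",
    "MultiFit",
    "fit_sma",
    "test_slope",
    "fit_ols",
    "number_allometry",
    "length_effect",
    "widening_regression",
    "table1",
]


def _check_xy(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if x.size < 3:
        raise ValueError(f"need at least 3 points, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("x and y must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate input: zero variance in x or y")
    return x, y


@dataclass(frozen=True)
class LinearFit:
    """A fitted bivariate line (SMA or OLS) with inference.

    ``slope_ci``/``intercept_ci`` are at level ``1 - alpha``; ``pvalue`` is
    the two-sided test of zero association (r = 0).
    """

    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    r: float
    r2: float
    pvalue: float
    n: int
    method: str  # "SMA" or "OLS"
    alpha: float = 0.05

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "slope": self.slope,
            "slope_ci": list(self.slope_ci),
            "intercept": self.intercept,
            "intercept_ci": list(self.intercept_ci),
            "r": self.r,
            "r2": self.r2,
            "pvalue": self.pvalue,
            "n": self.n,
            "alpha": self.alpha,
        }
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


@dataclass(frozen=True)
class MultiFit:
    """A fitted multiple regression: per-predictor inference plus fit stats."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame  # columns lo, hi; index matches params
    r2: float
    n: int
    alpha: float = 0.05

    @property
    def intercept(self) -> float:
        return float(self.params["const"])

    def coef(self, name: str) -> float:
        return float(self.params[name])

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "bse": self.bse.to_dict(),
            "tvalues": self.tvalues.to_dict(),
            "pvalues": self.pvalues.to_dict(),
            "conf_int": {
                k: list(v) for k, v in self.conf_int.iterrows()
            },
            "r2": self.r2,
            "n": self.n,
            "alpha": self.alpha,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


class SMA:
    """Standardized major axis model for two symmetric variables.

    Parameters
    ----------
    x, y
        Equal-length 1-d vectors, already on the analysis scale (the three
        stem analyses pass log10-transformed values).
    names
        Optional (x, y) variable names used in the summary table.
    """

    def __init__(self, x, y, names: tuple[str, str] = ("x", "y")):
        self.x, self.y = _check_xy(x, y)
        self.names = names

    def fit(self, alpha: float = 0.05) -> "SMAResults":
        x, y = self.x, self.y
        n = x.size
        sx = x.std(ddof=1)
        sy = y.std(ddof=1)
        r = float(np.corrcoef(x, y)[0, 1])
        if r == 0:
            raise ValueError("r = 0: SMA slope sign undefined")
        b = float(np.sign(r) * sy / sx)
        a = float(y.mean() - b * x.mean())

        # Slope CI: b * (sqrt(B+1) +/- sqrt(B)) with
        # B = F(1-alpha; 1, n-2) * (1 - r^2) / (n - 2).
        F = stats.f.ppf(1 - alpha, 1, n - 2)
        B = F * (1 - r**2) / (n - 2)
        lo = b * (np.sqrt(B + 1) - np.sqrt(B))
        hi = b * (np.sqrt(B + 1) + np.sqrt(B))
        slope_ci = (min(lo, hi), max(lo, hi))

        # Intercept CI from Var(ybar - b*xbar): residual variance about the
        # SMA line plus the slope's contribution through xbar.
        resid = y - b * x
        var_b = b**2 * (1 - r**2) / (n - 2)
        var_a = np.sum((resid - resid.mean()) ** 2) / (n - 2) / n + (
            x.mean() ** 2
        ) * var_b
        tcrit = stats.t.ppf(1 - alpha / 2, n - 2)
        intercept_ci = (a - tcrit * np.sqrt(var_a), a + tcrit * np.sqrt(var_a))

        # Association test (r = 0), two-sided.
        tstat = r * np.sqrt((n - 2) / (1 - r**2)) if abs(r) < 1 else np.inf
        pvalue = float(2 * stats.t.sf(abs(tstat), n - 2))

        fit = LinearFit(
            slope=b,
            intercept=a,
            slope_ci=(float(slope_ci[0]), float(slope_ci[1])),
            intercept_ci=(float(intercept_ci[0]), float(intercept_ci[1])),
            r=r,
            r2=r**2,
            pvalue=pvalue,
            n=n,
            method="SMA",
            alpha=alpha,
        )
        return SMAResults(self, fit)


class SMAResults:
    """Results of an SMA fit; exposes the estimates and slope tests."""

    def __init__(self, model: SMA, fit: LinearFit):
        self.model = model
        self._fit = fit

    # -- pass-through estimate accessors ----------------------------------
    @property
    def slope(self) -> float:
        return self._fit.slope

    @property
    def intercept(self) -> float:
        return self._fit.intercept

    @property
    def slope_ci(self) -> tuple[float, float]:
        return self._fit.slope_ci

    @property
    def intercept_ci(self) -> tuple[float, float]:
        return self._fit.intercept_ci

    @property
    def r(self) -> float:
        return self._fit.r

    @property
    def r2(self) -> float:
        return self._fit.r2

    @property
    def pvalue(self) -> float:
        return self._fit.pvalue

    @property
    def n(self) -> int:
        return self._fit.n

    def as_fit(self) -> LinearFit:
        return self._fit

    def test_slope(self, b0: float) -> float:
        """Two-sided p-value for H0: slope = ``b0``.

        Under the SMA model the test is a zero-correlation test between the
        residual scores ``y - b0*x`` and the axis scores ``y + b0*x`` on
        n - 2 degrees of freedom: when the true slope is b0 those two
        rotated coordinates are uncorrelated.
        """
        if b0 == 0:
            raise ValueError("b0 must be nonzero")
        x, y = self.model.x, self.model.y
        n = x.size
        u, v = y - b0 * x, y + b0 * x
        if np.ptp(u) == 0 or np.ptp(v) == 0:
            # Data lie exactly on a line of slope +/- b0: zero residual-axis
            # correlation, no evidence against H0.
            return 1.0
        rr = float(np.corrcoef(u, v)[0, 1])
        if abs(rr) >= 1:
            return 0.0
        t = rr * np.sqrt((n - 2) / (1 - rr**2))
        return float(2 * stats.t.sf(abs(t), n - 2))

    def test_intercept_zero(self) -> float:
        """Two-sided p-value for H0: intercept = 0 (t on n - 2 df)."""
        f = self._fit
        tcrit = stats.t.ppf(1 - f.alpha / 2, f.n - 2)
        half = (f.intercept_ci[1] - f.intercept_ci[0]) / 2
        se = half / tcrit
        if se == 0:
            return 0.0 if f.intercept != 0 else 1.0
        return float(2 * stats.t.sf(abs(f.intercept / se), f.n - 2))

    def summary(self) -> str:
        f = self._fit
        xn, yn = self.model.names
        lines = [
            "Standardized Major Axis Regression",
            "=" * 44,
            f"{yn} ~ {xn}   (n = {f.n})",
            f"slope      {f.slope: .4f}  "
            f"[{f.slope_ci[0]:.4f}, {f.slope_ci[1]:.4f}]",
            f"intercept  {f.intercept: .4f}  "
            f"[{f.intercept_ci[0]:.4f}, {f.intercept_ci[1]:.4f}]",
            f"r2         {f.r2: .4f}",
            f"P(r = 0)   {_fmt_p(f.pvalue)}",
            f"P(b = 1)   {_fmt_p(self.test_slope(1.0))}",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<SMAResults slope={self.slope:.4g} "
            f"intercept={self.intercept:.4g} r2={self.r2:.3f} n={self.n}>"
        )


def _fmt_p(p: float, floor: float = 2.2e-16) -> str:
    """Conventional p-value display with a 2.2e-16 floor."""
    return f"< {floor:.1e}" if p < floor else f"{p:.3g}"


# --------------------------------------------------------------------------
# Functional surface
# --------------------------------------------------------------------------


def fit_sma(x, y, alpha: float = 0.05) -> LinearFit:
    """Fit a standardized major axis line; see :class:`SMA`."""
    return SMA(x, y).fit(alpha=alpha).as_fit()


def test_slope(x, y, b0: float) -> float:
    """Two-sided SMA test of slope = ``b0`` (residual-vs-axis correlation)."""
    return SMA(x, y).fit().test_slope(b0)


def fit_ols(y, X, alpha: float = 0.05, names: list[str] | None = None) -> MultiFit:
    """Ordinary least squares with an intercept, via statsmodels.

    ``X`` is an (n, p) predictor matrix or DataFrame (no constant column);
    rank deficiency raises with the offending columns named.
    """
    y = np.asarray(y, dtype=float)
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        if Xv.ndim == 1:
            Xv = Xv[:, None]
        names = names or [f"x{i + 1}" for i in range(Xv.shape[1])]
    n, p = Xv.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={p})")
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(n), Xv]))
    if rank < p + 1:
        # Identify columns that do not raise the rank of the rest.
        bad = []
        for j in range(p):
            others = np.column_stack(
                [np.ones(n)] + [Xv[:, k] for k in range(p) if k != j]
            )
            if np.linalg.matrix_rank(np.column_stack([others, Xv[:, j]])) == (
                np.linalg.matrix_rank(others)
            ):
                bad.append(names[j])
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    Xdf = pd.DataFrame(Xv, columns=names)
    res = sm.OLS(y, sm.add_constant(Xdf)).fit()
    ci = res.conf_int(alpha=alpha)
    ci.columns = ["lo", "hi"]
    return MultiFit(
        params=res.params,
        bse=res.bse,
        tvalues=res.tvalues,
        pvalues=res.pvalues,
        conf_int=ci,
        r2=float(res.rsquared),
        n=n,
        alpha=alpha,
    )


# --------------------------------------------------------------------------
# The three stem analyses
# --------------------------------------------------------------------------


def number_allometry(dataset: Dataset, alpha: float = 0.05) -> LinearFit:
    """SMA of log10 tip conduit count on log10 base conduit count.

    No furcation predicts a slope of 1 (isometry: the same conduits run the
    length of the segment); furcation, being multiplicative, predicts a
    slope above 1.
    """
    df = dataset.to_frame()
    return fit_sma(
        np.log10(df.n_base.to_numpy(float)),
        np.log10(df.n_tip.to_numpy(float)),
        alpha=alpha,
    )


def length_effect(
    dataset: Dataset, alpha: float = 0.05, log_length: bool = True
) -> MultiFit:
    """OLS of log10 tip count on log10 base count + segment length.

    If conduits furcate cumulatively along the stem, longer segments have
    had more branching opportunities and the length coefficient should be
    significantly positive; under constant conduit number it is null.
    ``log_length=True`` (default) enters segment length as log10(cm),
    matching the log transform applied to every analysis variable;
    ``log_length=False`` uses raw cm.
    """
    df = dataset.to_frame()
    L = df.segment_length_cm.to_numpy(float)
    X = pd.DataFrame(
        {
            "log10_n_base": np.log10(df.n_base.to_numpy(float)),
            "length": np.log10(L) if log_length else L,
        }
    )
    return fit_ols(np.log10(df.n_tip.to_numpy(float)), X, alpha=alpha)


def widening_regression(dataset: Dataset, alpha: float = 0.05) -> LinearFit:
    """OLS of log10 mean conduit diameter on log10 distance from the apex.

    Pools both sections of every branch (tip point at ``dist_tip_cm``, base
    point at ``dist_base_cm``), giving 2n points.  Hydraulic-optimality
    theory predicts a slope near 0.2: diameters widen tip-to-base as a
    power ~0.2 of the path distance from the apex.

    Returned as a :class:`LinearFit` with ``method="OLS"`` so it sits in the
    same summary table as the SMA rows.
    """
    df = dataset.to_frame()
    dist = np.concatenate(
        [df.dist_tip_cm.to_numpy(float), df.dist_base_cm.to_numpy(float)]
    )
    diam = np.concatenate(
        [df.d_tip_um.to_numpy(float), df.d_base_um.to_numpy(float)]
    )
    x = np.log10(dist)
    y = np.log10(diam)
    m = fit_ols(y, x[:, None], alpha=alpha, names=["log10_dist"])
    r = float(np.corrcoef(x, y)[0, 1])
    return LinearFit(
        slope=m.coef("log10_dist"),
        intercept=m.intercept,
        slope_ci=tuple(m.conf_int.loc["log10_dist"]),
        intercept_ci=tuple(m.conf_int.loc["const"]),
        r=r,
        r2=m.r2,
        pvalue=float(m.pvalues["log10_dist"]),
        n=x.size,
        method="OLS",
        alpha=alpha,
    )


def table1(dataset: Dataset, alpha: float = 0.05) -> pd.DataFrame:
    """The three-analysis summary table (one row per regression).

    Columns mirror the standard report: response, predictors, slope with CI,
    intercept with CI, r2 and the association p-value; the multiple
    regression row reports the base-count coefficient as its slope and the
    segment-length p-value separately.
    """
    sma = number_allometry(dataset, alpha=alpha)
    multi = length_effect(dataset, alpha=alpha)
    wid = widening_regression(dataset, alpha=alpha)
    rows = [
        {
            "response": "log10_n_tip",
            "predictors": "log10_n_base",
            "method": "SMA",
            "slope": sma.slope,
            "slope_lo": sma.slope_ci[0],
            "slope_hi": sma.slope_ci[1],
            "intercept": sma.intercept,
            "intercept_lo": sma.intercept_ci[0],
            "intercept_hi": sma.intercept_ci[1],
            "r2": sma.r2,
            "pvalue": sma.pvalue,
            "length_pvalue": np.nan,
            "n": sma.n,
        },
        {
            "response": "log10_n_tip",
            "predictors": "log10_n_base + segment_length",
            "method": "OLS",
            "slope": multi.coef("log10_n_base"),
            "slope_lo": multi.conf_int.loc["log10_n_base", "lo"],
            "slope_hi": multi.conf_int.loc["log10_n_base", "hi"],
            "intercept": multi.intercept,
            "intercept_lo": multi.conf_int.loc["const", "lo"],
            "intercept_hi": multi.conf_int.loc["const", "hi"],
            "r2": multi.r2,
            "pvalue": float(multi.pvalues["log10_n_base"]),
            "length_pvalue": float(multi.pvalues["length"]),
            "n": multi.n,
        },
        {
            "response": "log10_diameter",
            "predictors": "log10_dist_from_apex",
            "method": "OLS",
            "slope": wid.slope,
            "slope_lo": wid.slope_ci[0],
            "slope_hi": wid.slope_ci[1],
            "intercept": wid.intercept,
            "intercept_lo": wid.intercept_ci[0],
            "intercept_hi": wid.intercept_ci[1],
            "r2": wid.r2,
            "pvalue": wid.pvalue,
            "length_pvalue": np.nan,
            "n": wid.n,
        },
    ]
    return pd.DataFrame(rows)
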