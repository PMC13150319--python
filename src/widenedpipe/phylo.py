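"""Phylogenetic reduced major axis regression under Brownian motion.

Closely related species are not independent data points: under a Brownian
motion (BM) model of trait evolution the expected covariance between two
species' traits is proportional to their shared root-to-ancestor path
length.  Pagel's lambda relaxes pure BM by scaling the off-diagonal
covariances: lambda = 0 means species behave independently, lambda = 1 full
Brownian covariance.

:class:`PhyloRMA` fits a reduced major axis (model II) line between two
traits with that covariance structure: phylogenetic generalized
least-squares means replace the sample means, the evolutionary trait
covariance matrix replaces the sample covariance, and a single lambda
common to both traits is estimated by maximizing the bivariate Brownian
log-likelihood on [0, 1].
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from scipy import optimize

from .data import Dataset, Phylogeny, normalize_species_name

__all__ = [
    "PhyloRMA",
    "PhyloRMAFit",
    "phylo_vcv",
    "lambda_transform",
    "fit_phyl_rma",
    "phylo_number_allometry",
]


def phylo_vcv(tree: Phylogeny) -> tuple[list[str], np.ndarray]:
    """Brownian covariance matrix of a tree: entry (i, j) is the shared
    root-to-MRCA path length; the diagonal is the tree depth."""
    return tree.vcv()


def lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    """Scale off-diagonal covariances by Pagel's lambda, diagonal unchanged."""
    if not 0 <= lam <= 1:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    C = np.asarray(C, dtype=float)
    out = lam * C
    np.fill_diagonal(out, np.diag(C))
    return out


class PhyloRMAFit:
    """Fitted phylogenetic RMA: estimates, lambda-hat, log-likelihood."""

    def __init__(
        self,
        slope: float,
        intercept: float,
        lambda_hat: float,
        loglik: float,
        n: int,
        trait_names: tuple[str, str],
        pruned_tips: list[str],
        gls_means: tuple[float, float],
        evol_vcv: np.ndarray,
        model: "PhyloRMA | None" = None,
    ):
        self.slope = slope
        self.intercept = intercept
        self.lambda_hat = lambda_hat
        self.loglik = loglik
        self.n = n
        self.trait_names = trait_names
        self.pruned_tips = pruned_tips
        self.gls_means = gls_means
        self.evol_vcv = evol_vcv
        self.model = model

    def loglik_at(self, lam: float) -> float:
        """Profile log-likelihood at an arbitrary fixed lambda."""
        if self.model is None:
            raise ValueError("fit is detached from its model")
        return self.model._loglik(lam)

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "lambda_hat": self.lambda_hat,
            "loglik": self.loglik,
            "n": self.n,
            "traits": list(self.trait_names),
            "pruned_tips": list(self.pruned_tips),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def summary(self) -> str:
        xn, yn = self.trait_names
        return "\n".join(
            [
                "Phylogenetic Reduced Major Axis Regression (Brownian motion)",
                "=" * 60,
                f"{yn} ~ {xn}   (n = {self.n} matched tips, "
                f"{len(self.pruned_tips)} pruned)",
                f"slope       {self.slope: .4f}",
                f"intercept   {self.intercept: .4f}",
                f"lambda_hat  {self.lambda_hat: .6g}",
                f"logLik      {self.loglik: .4f}",
            ]
        )

    def __repr__(self) -> str:
        return (
            f"<PhyloRMAFit slope={self.slope:.4g} "
            f"lambda={self.lambda_hat:.3g} n={self.n}>"
        )


class PhyloRMA:
    """Model-II line between two species traits with phylogenetic covariance.

    Parameters
    ----------
    x, y
        Traits keyed by species label: pandas Series, or dicts.  Labels are
        normalized (whitespace/underscore) before matching against tree
        tips.
    tree
        Ultrametric :class:`~widenedpipe.data.Phylogeny`.  Tips without
        trait data are pruned before the covariance matrix is built; at
        least 4 matched tips are required.
    names
        Trait names for reporting.
    """

    #: coarse pre-scan grid to avoid local optima in a flat likelihood
    GRID = np.linspace(0.0, 1.0, 11)

    def __init__(self, x, y, tree: Phylogeny, names=("x", "y")):
        x = pd.Series(x, dtype=float)
        y = pd.Series(y, dtype=float)
        x.index = [normalize_species_name(i) for i in x.index]
        y.index = [normalize_species_name(i) for i in y.index]
        if x.index.has_duplicates or y.index.has_duplicates:
            raise ValueError("duplicate species labels in traits")
        tree_labels = {normalize_species_name(t): t for t in tree.tip_labels}
        common = [
            lbl
            for lbl in x.index
            if lbl in tree_labels and lbl in y.index
        ]
        if len(common) < 4:
            raise ValueError(
                f"need >= 4 tips with both traits and a tree match, "
                f"got {len(common)}"
            )
        self.labels = common
        self.pruned_tips = sorted(set(tree.tip_labels) - {tree_labels[l] for l in common})
        subtree = (
            tree.prune_to([tree_labels[l] for l in common])
            if self.pruned_tips
            else tree
        )
        order = [tree_labels[l] for l in common]
        _, self.C = subtree.vcv(order)
        self.T = np.column_stack(
            [x.loc[common].to_numpy(), y.loc[common].to_numpy()]
        )
        self.names = tuple(names)
        self.n = len(common)

    # -- likelihood machinery ---------------------------------------------

    def _components(self, lam: float):
        """GLS means, evolutionary covariance and log-likelihood at lambda."""
        n, m = self.T.shape
        C = lambda_transform(self.C, lam)
        try:
            L = np.linalg.cholesky(C)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"C(lambda={lam}) is singular") from exc
        ones = np.ones((n, 1))
        # Solve through the Cholesky factor; never form the inverse.
        Ci_T = np.linalg.solve(L.T, np.linalg.solve(L, self.T))
        Ci_1 = np.linalg.solve(L.T, np.linalg.solve(L, ones))
        denom = float((ones.T @ Ci_1).item())
        a = (ones.T @ Ci_T).ravel() / denom  # GLS trait means
        E = self.T - ones * a
        Ci_E = np.linalg.solve(L.T, np.linalg.solve(L, E))
        V = (E.T @ Ci_E) / (n - 1)  # evolutionary trait covariance
        logdet_C = 2.0 * float(np.sum(np.log(np.diag(L))))
        sign, logdet_V = np.linalg.slogdet(V)
        if sign <= 0:
            raise ValueError("evolutionary covariance not positive-definite")
        # Bivariate BM likelihood with the (n-1)-denominator covariance
        # plugged in; the quadratic form then collapses to m*(n-1).
        loglik = -0.5 * (
            n * m * np.log(2 * np.pi)
            + n * logdet_V
            + m * logdet_C
            + m * (n - 1)
        )
        return a, V, float(loglik)

    def _loglik(self, lam: float) -> float:
        return self._components(lam)[2]

    def fit(self, fix_lambda: float | None = None, xatol: float = 1e-8) -> PhyloRMAFit:
        """Estimate the RMA line, maximizing over lambda unless fixed.

        The profile likelihood in lambda can be nearly flat (especially
        near 0 when there is no phylogenetic signal), so a coarse 11-point
        grid scan brackets the optimum before bounded scalar maximization.
        """
        if fix_lambda is not None:
            lam_hat = float(fix_lambda)
            if not 0 <= lam_hat <= 1:
                raise ValueError("fix_lambda must lie in [0, 1]")
        else:
            grid_ll = [self._loglik(l) for l in self.GRID]
            i = int(np.argmax(grid_ll))
            lo = self.GRID[max(i - 1, 0)]
            hi = self.GRID[min(i + 1, len(self.GRID) - 1)]
            if lo == hi:  # single-point degenerate bracket
                lam_hat = float(lo)
            else:
                res = optimize.minimize_scalar(
                    lambda l: -self._loglik(l),
                    bounds=(lo, hi),
                    method="bounded",
                    options={"xatol": xatol},
                )
                lam_hat = float(res.x)
                # The bounded optimizer cannot land exactly on the
                # boundary; take it if it is at least as good.
                for edge in (lo, hi):
                    if self._loglik(edge) >= self._loglik(lam_hat):
                        lam_hat = float(edge)
        a, V, loglik = self._components(lam_hat)
        slope = float(np.sign(V[0, 1]) * np.sqrt(V[1, 1] / V[0, 0]))
        intercept = float(a[1] - slope * a[0])
        return PhyloRMAFit(
            slope=slope,
            intercept=intercept,
            lambda_hat=lam_hat,
            loglik=loglik,
            n=self.n,
            trait_names=self.names,
            pruned_tips=self.pruned_tips,
            gls_means=(float(a[0]), float(a[1])),
            evol_vcv=V,
            model=self,
        )


def fit_phyl_rma(
    x, y, tree: Phylogeny, fix_lambda: float | None = None, names=("x", "y")
) -> PhyloRMAFit:
    """Functional wrapper over :class:`PhyloRMA`."""
    return PhyloRMA(x, y, tree, names=names).fit(fix_lambda=fix_lambda)


def phylo_number_allometry(
    dataset: Dataset,
    tree: Phylogeny,
    fix_lambda: float | None = None,
    log10: bool = True,
) -> PhyloRMAFit:
    """Phylogenetic RMA of tip conduit count on base conduit count.

    Counts are log10-transformed by default, matching the standard
    (non-phylogenetic) analysis; ``log10=False`` fits raw counts.
    """
    df = dataset.to_frame().set_index("species_id")
    x = df.n_base.astype(float)
    y = df.n_tip.astype(float)
    if log10:
        x, y = np.log10(x), np.log10(y)
    return fit_phyl_rma(
        x,
        y,
        tree,
        fix_lambda=fix_lambda,
        names=("log10_n_base", "log10_n_tip") if log10 else ("n_base", "n_tip"),
    )
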