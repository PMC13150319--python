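"""Synthetic branch datasets, pure-birth trees and Brownian traits.

The generator emulates the measurement design of the stem-furcation study:
one terminal branch per species, 0.6–7.7 m long, with conduit diameters
following tip-to-base widening D proportional to (distance from apex)**0.2
with lognormal noise, lognormally spread basal conduit counts, and — under
the null — tip counts equal to base counts up to small multiplicative
noise.  A furcation scenario can be injected instead of the null, in which
case tip counts follow that scenario's predictor.

Every stochastic operation is a pure function of its configuration and
seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd
from dendropy.model import birthdeath

from .data import BranchRecord, Dataset, Phylogeny
from .furcation import FurcationScenario, predict_record

__all__ = [
    "SimConfig",
    "simulate_dataset",
    "simulate_tree",
    "simulate_bm_traits",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic branch generator.

    Defaults mirror the study conditions: 112 species, branch lengths
    log-uniform over 60–770 cm, widening exponent 0.2, and a leafy-tip
    section 5–30 cm below the apex.  ``widening_ref_log10`` sets the
    diameter power-law intercept so diameters span roughly 10–300 um over
    that distance range; ``log10_nbase_range`` is a generator default (the
    study never reports its count range).  ``sigma_n`` is the log10 sd of
    tip counts about base counts under the null.
    """

    n_species: int = 112
    length_range_cm: tuple[float, float] = (60.0, 770.0)
    tip_offset_range_cm: tuple[float, float] = (5.0, 30.0)
    widening_exponent: float = 0.2
    widening_ref_log10: float = 1.2
    sigma_d: float = 0.25
    log10_nbase_range: tuple[float, float] = (1.5, 4.0)
    sigma_n: float = 0.06
    scenario: FurcationScenario | None = None
    seed: int = 0

    def __post_init__(self):
        for name in ("length_range_cm", "tip_offset_range_cm", "log10_nbase_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be an ordered (lo, hi) pair")
        if self.tip_offset_range_cm[1] >= self.length_range_cm[0]:
            raise ValueError(
                "tip offset must stay below the shortest branch length"
            )
        if self.sigma_d < 0 or self.sigma_n < 0:
            raise ValueError("noise sds must be >= 0")
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")


def simulate_dataset(config: SimConfig) -> Dataset:
    """Draw one synthetic branch per species under ``config``.

    Per species: the base section sits at a log-uniform apex distance in
    ``length_range_cm``; the tip section at a uniform 5–30 cm offset; each
    section's mean diameter is ``10**(ref + b*log10(dist) + eps)`` with
    independent Normal(0, sigma_d) noise; the base count is log-uniform
    over ``log10_nbase_range``; and the tip count is the base count times
    ``10**Normal(0, sigma_n)`` under the null, or the injected scenario's
    prediction when ``config.scenario`` is set.  Counts are rounded to
    integers with a floor of 1.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_species
    lo, hi = np.log10(config.length_range_cm)
    dist_base = 10.0 ** rng.uniform(lo, hi, size=n)
    dist_tip = rng.uniform(*config.tip_offset_range_cm, size=n)

    def diameter(dist):
        eps = rng.normal(0.0, config.sigma_d, size=n) if config.sigma_d else 0.0
        return 10.0 ** (
            config.widening_ref_log10
            + config.widening_exponent * np.log10(dist)
            + eps
        )

    d_tip = diameter(dist_tip)
    d_base = diameter(dist_base)
    n_base = np.maximum(
        1, np.rint(10.0 ** rng.uniform(*config.log10_nbase_range, size=n))
    ).astype(int)
    eta = rng.normal(0.0, config.sigma_n, size=n) if config.sigma_n else np.zeros(n)

    records = []
    for i in range(n):
        rec = BranchRecord(
            species_id=f"sp{i + 1:03d}",
            n_base=int(n_base[i]),
            n_tip=int(n_base[i]),  # placeholder, set below
            d_base_um=float(d_base[i]),
            d_tip_um=float(d_tip[i]),
            dist_base_cm=float(dist_base[i]),
            dist_tip_cm=float(dist_tip[i]),
        )
        if config.scenario is None:
            n_tip = max(1, int(np.rint(n_base[i] * 10.0 ** eta[i])))
        else:
            pred = predict_record(rec, config.scenario)
            n_tip = max(1, int(np.rint(min(pred.n_tip_pred, 1e12))))
        records.append(
            BranchRecord(
                species_id=rec.species_id,
                n_base=rec.n_base,
                n_tip=n_tip,
                d_base_um=rec.d_base_um,
                d_tip_um=rec.d_tip_um,
                dist_base_cm=rec.dist_base_cm,
                dist_tip_cm=rec.dist_tip_cm,
            )
        )
    scenario = "null" if config.scenario is None else config.scenario.label()
    return Dataset(
        records=records,
        provenance=f"simulated(seed={config.seed}, scenario={scenario})",
    )


def simulate_tree(n_tips: int, seed: int) -> Phylogeny:
    """Pure-birth (Yule) ultrametric tree with depth rescaled to 1.

    Tips are labeled ``t1 ... t<n>``; the same seed always yields the same
    topology and branch lengths.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = random.Random(seed)
    tree = birthdeath.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=rng,
    )
    # The simulator stops exactly at the n-th speciation, leaving the two
    # newest sibling tips with zero-length edges (a singular covariance).
    # Extend every tip edge by the exponential waiting time to the next,
    # uncommitted, speciation — the correct Yule tail.
    tail = rng.expovariate(n_tips * 1.0)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + tail
    # Drop the root stem edge so depth is measured from the first split,
    # then rescale to unit depth.
    tree.seed_node.edge.length = 0.0
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"t{i + 1}"
    depth = max(l.distance_from_root() for l in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= depth
    # Pure-birth trees are exactly ultrametric; tolerate float error only.
    return Phylogeny(tree)


def simulate_bm_traits(
    tree: Phylogeny,
    rate_matrix,
    lam: float = 1.0,
    seed: int = 0,
    root_mean=(0.0, 0.0),
) -> pd.DataFrame:
    """Bivariate traits under Brownian motion with Pagel's lambda.

    Trait columns x, y are drawn jointly from a multivariate normal whose
    covariance is ``kron(rate_matrix, C_lambda)`` about ``root_mean``,
    where C is the tree's Brownian covariance with off-diagonals scaled by
    ``lam``.  Returns a DataFrame indexed by tip label.
    """
    from .phylo import lambda_transform  # local import to avoid cycle

    A = np.asarray(rate_matrix, dtype=float)
    if A.shape != (2, 2):
        raise ValueError("rate_matrix must be 2x2")
    try:
        La = np.linalg.cholesky(A)
    except np.linalg.LinAlgError as exc:
        raise ValueError("rate_matrix must be positive-definite") from exc
    labels, C = tree.vcv()
    Clam = lambda_transform(C, lam)
    Lc = np.linalg.cholesky(Clam)
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((len(labels), 2))
    # X[i, a] = sum_j Lc[i, j] Z[j, b] La[a, b]  =>  cov = kron(A, C_lam)
    X = Lc @ Z @ La.T + np.asarray(root_mean, dtype=float)
    return pd.DataFrame(X, index=labels, columns=["x", "y"])
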