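"""Furcation baseline models: predicted tip conduit counts under branching.

If conduits in a stem furcate — each parent conduit dividing into ``b``
narrower daughters at discrete branching events — the tip count is

    N_tip = N_base * b**n

with ``n`` the number of branching events along the segment.  Four
baselines for ``n`` (or for the count ratio directly) are implemented:

``fixed``
    Branching events regularly spaced every ``L_b`` cm: n = L_segment / L_b.
``geometric``
    Internode length contracts by a factor ``lambda_len`` per level (the
    architecture of classic plant-network models, where distal internodes
    are shorter).  The internode lengths form a geometric series whose sum
    is the segment length; fixing the distalmost internode at ``L_n``
    (default 1 cm) determines both the basal internode length and ``n``.
``davinci``
    Conservation of summed cross-sectional area across levels:
    N_tip = R**2 * N_base with R = d_base / d_tip.
``murray``
    Conservation of the summed cube of radii (minimum pumping work subject
    to volume cost): N_tip = R**3 * N_base.

Counts explode as 2**n, so every product is carried in log10 space; the raw
count is materialized only when it is representable (below 1e15).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import BranchRecord, Dataset

__all__ = [
    "FurcationScenario",
    "Prediction",
    "n_events_fixed",
    "predict_fixed",
    "l0_geometric",
    "n_events_geometric",
    "predict_geometric",
    "predict_conservation",
    "predict_record",
    "sweep_fixed",
    "compare_scenarios",
    "DEFAULT_LB_GRID",
]

#: The reference fixed-internode sweep: 3 to 30 cm in 3 cm steps.
DEFAULT_LB_GRID = tuple(range(3, 31, 3))

#: Raw counts larger than this are reported only as log10.
MATERIALIZE_LIMIT = 1e15


@dataclass(frozen=True)
class FurcationScenario:
    """Parameterization of one furcation baseline.

    kind
        One of ``fixed``, ``geometric``, ``davinci``, ``murray``.
    b
        Branching ratio (daughter conduits per parent), integer >= 2;
        the reference analyses assume symmetric bifurcation (b = 2).
    L_b
        Fixed internode length in cm (``fixed`` only).
    lambda_len
        Per-level internode contraction factor in (0, 1)
        (``geometric`` only; 0.7 means daughters are 70% as long).
    L_n
        Distalmost internode length in cm (``geometric`` only).
    """

    kind: str
    b: int = 2
    L_b: float | None = None
    lambda_len: float = 0.7
    L_n: float = 1.0

    KINDS = ("fixed", "geometric", "davinci", "murray")

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown scenario kind: {self.kind!r}")
        if not (isinstance(self.b, (int, np.integer)) and self.b >= 2):
            raise ValueError(f"branching ratio b must be an integer >= 2, got {self.b}")
        if self.kind == "fixed":
            if self.L_b is None or self.L_b <= 0:
                raise ValueError("fixed scenario requires L_b > 0")
        if self.kind == "geometric":
            if not 0 < self.lambda_len < 1:
                raise ValueError("lambda_len must lie in (0, 1)")
            if self.L_n <= 0:
                raise ValueError("L_n must be positive")

    @property
    def p(self) -> int | None:
        """Radius-moment exponent of the conservation kinds (2 or 3)."""
        return {"davinci": 2, "murray": 3}.get(self.kind)

    def label(self) -> str:
        if self.kind == "fixed":
            return f"fixed(L_b={self.L_b:g})"
        if self.kind == "geometric":
            return f"geometric(lambda={self.lambda_len:g})"
        return self.kind


@dataclass(frozen=True)
class Prediction:
    """Predicted tip count for one branch under one scenario.

    ``log10_n_tip_pred`` is always exact; ``n_tip_pred`` is the
    materialized count, or ``inf`` when it exceeds the representable limit.
    ``log10_ratio`` is log10(predicted / observed) when an observed tip
    count is available.
    """

    species_id: str
    scenario: FurcationScenario
    n_events: float
    log10_n_tip_pred: float
    n_tip_obs: int | None = None
    flags: tuple[str, ...] = ()

    @property
    def n_tip_pred(self) -> float:
        v = 10.0 ** self.log10_n_tip_pred
        return v if v < MATERIALIZE_LIMIT else math.inf

    @property
    def log10_ratio(self) -> float | None:
        if self.n_tip_obs is None:
            return None
        return self.log10_n_tip_pred - math.log10(self.n_tip_obs)

    @property
    def overpredicts(self) -> bool | None:
        """Strictly exceeds the observed tip count (ties are not over)."""
        r = self.log10_ratio
        return None if r is None else r > 0


# --------------------------------------------------------------------------
# Event counts
# --------------------------------------------------------------------------


def n_events_fixed(L_segment: float, L_b: float) -> float:
    """Number of branching events with regular spacing: L_segment / L_b.

    Kept continuous; the formulas place no integrality constraint on n.
    """
    if L_segment < 0:
        raise ValueError(f"L_segment must be >= 0, got {L_segment}")
    if L_b <= 0:
        raise ValueError(f"L_b must be > 0, got {L_b}")
    return L_segment / L_b


def l0_geometric(L_segment: float, lambda_len: float = 0.7, L_n: float = 1.0) -> float:
    """Basal internode length under geometric contraction.

    With internode lengths L_0, lambda*L_0, ..., L_n summing to L_segment,
    the finite geometric series gives L_0 = (1 - lambda)*L_segment +
    lambda*L_n.
    """
    if not 0 < lambda_len < 1:
        raise ValueError("lambda_len must lie in (0, 1)")
    if L_segment <= L_n:
        raise ValueError(
            f"L_segment ({L_segment}) must exceed the distalmost internode "
            f"L_n ({L_n}): no room for contraction"
        )
    return (1 - lambda_len) * L_segment + lambda_len * L_n


def n_events_geometric(
    L_segment: float, lambda_len: float = 0.7, L_n: float = 1.0
) -> float:
    """Branching events under geometric internode contraction.

    Inverts the finite geometric series
    ``L_segment = L_0 * sum_{k=0}^{n} lambda**k``:

        n = log_lambda(1 - L_segment*(1 - lambda)/L_0) - 1
          = log_lambda(L_n / L_0)

    so that the distalmost internode L_0 * lambda**n equals L_n exactly.
    Continuous, >= 0.
    """
    L0 = l0_geometric(L_segment, lambda_len, L_n)
    # 1 - L_segment*(1 - lambda)/L_0 equals lambda*L_n/L_0 exactly (by the
    # definition of L_0); the latter form avoids catastrophic cancellation
    # when the distalmost internode is tiny relative to the segment.
    arg = lambda_len * L_n / L0
    if arg <= 0:
        raise ValueError(
            f"log argument non-positive (arg={arg}): inconsistent inputs"
        )
    return math.log(arg) / math.log(lambda_len) - 1


# --------------------------------------------------------------------------
# Predictions
# --------------------------------------------------------------------------


def _mk_prediction(
    species_id, scenario, n_events, log10_pred, n_tip_obs, flags=()
) -> Prediction:
    return Prediction(
        species_id=str(species_id),
        scenario=scenario,
        n_events=float(n_events),
        log10_n_tip_pred=float(log10_pred),
        n_tip_obs=None if n_tip_obs is None else int(n_tip_obs),
        flags=tuple(flags),
    )


def predict_fixed(
    n_base: float,
    L_segment: float,
    L_b: float,
    b: int = 2,
    species_id: str = "",
    n_tip_obs: int | None = None,
) -> Prediction:
    """Tip count under regularly spaced furcation: N_base * b**(L_seg/L_b)."""
    scenario = FurcationScenario(kind="fixed", b=b, L_b=L_b)
    n = n_events_fixed(L_segment, L_b)
    log10_pred = math.log10(n_base) + n * math.log10(b)
    return _mk_prediction(species_id, scenario, n, log10_pred, n_tip_obs)


def predict_geometric(
    n_base: float,
    L_segment: float,
    scenario: FurcationScenario | None = None,
    species_id: str = "",
    n_tip_obs: int | None = None,
) -> Prediction:
    """Tip count under geometrically contracting internodes.

    Degenerate segments no longer than the distalmost internode get
    n = 0 (no branching room) rather than an error.
    """
    scenario = scenario or FurcationScenario(kind="geometric")
    if scenario.kind != "geometric":
        raise ValueError("scenario.kind must be 'geometric'")
    if L_segment <= scenario.L_n:
        n = 0.0
    else:
        n = n_events_geometric(L_segment, scenario.lambda_len, scenario.L_n)
    log10_pred = math.log10(n_base) + n * math.log10(scenario.b)
    return _mk_prediction(species_id, scenario, n, log10_pred, n_tip_obs)


def predict_conservation(
    n_base: float,
    d_base_um: float,
    d_tip_um: float,
    p: int,
    species_id: str = "",
    n_tip_obs: int | None = None,
) -> Prediction:
    """Tip count conserving the summed p-th radius moment: R**p * N_base.

    p = 2 is da Vinci's rule (area conservation); p = 3 is Murray's law.
    R = d_base/d_tip <= 1 (no widening) still yields a prediction but the
    record is flagged ``no-widening``.
    """
    if p not in (2, 3):
        raise ValueError(f"p must be 2 (davinci) or 3 (murray), got {p}")
    if d_base_um <= 0 or d_tip_um <= 0:
        raise ValueError("diameters must be positive")
    kind = "davinci" if p == 2 else "murray"
    scenario = FurcationScenario(kind=kind)
    R = d_base_um / d_tip_um
    flags = () if R > 1 else ("no-widening",)
    log10_pred = math.log10(n_base) + p * math.log10(R)
    # Conservation rules fix the count ratio directly; the implied number
    # of bifurcation events is p*log2(R).
    n = p * math.log2(R)
    return _mk_prediction(species_id, scenario, n, log10_pred, n_tip_obs, flags)


def predict_record(record: BranchRecord, scenario: FurcationScenario) -> Prediction:
    """Dispatch one branch record to the scenario's predictor."""
    common = dict(species_id=record.species_id, n_tip_obs=record.n_tip)
    if scenario.kind == "fixed":
        return predict_fixed(
            record.n_base,
            record.segment_length_cm,
            scenario.L_b,
            b=scenario.b,
            **common,
        )
    if scenario.kind == "geometric":
        return predict_geometric(
            record.n_base, record.segment_length_cm, scenario, **common
        )
    return predict_conservation(
        record.n_base, record.d_base_um, record.d_tip_um, scenario.p, **common
    )


def sweep_fixed(
    dataset: Dataset, L_b_values=DEFAULT_LB_GRID, b: int = 2
) -> list[Prediction]:
    """One fixed-spacing prediction per (record, L_b) over the grid."""
    out = []
    for L_b in L_b_values:
        scenario = FurcationScenario(kind="fixed", b=b, L_b=float(L_b))
        out.extend(predict_record(rec, scenario) for rec in dataset)
    return out


def predictions_frame(predictions: list[Prediction]) -> pd.DataFrame:
    """Tabulate predictions (one row each) for CSV export."""
    rows = []
    for p in predictions:
        rows.append(
            {
                "species_id": p.species_id,
                "scenario": p.scenario.label(),
                "kind": p.scenario.kind,
                "L_b": p.scenario.L_b,
                "lambda_len": (
                    p.scenario.lambda_len
                    if p.scenario.kind == "geometric"
                    else np.nan
                ),
                "n_events": p.n_events,
                "n_tip_obs": p.n_tip_obs,
                "log10_n_tip_pred": p.log10_n_tip_pred,
                "n_tip_pred": p.n_tip_pred,
                "log10_ratio": p.log10_ratio,
                "flags": ";".join(p.flags),
            }
        )
    return pd.DataFrame(rows)


def compare_scenarios(
    dataset: Dataset, scenarios: list[FurcationScenario]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-record predictions and a per-scenario summary.

    Returns ``(detail, summary)``: *detail* has one row per (record,
    scenario) with the log10 prediction/observation ratio; *summary* has,
    per scenario, the fraction of records whose prediction strictly exceeds
    the observed tip count and the median log10 ratio.
    """
    preds: list[Prediction] = []
    for sc in scenarios:
        preds.extend(predict_record(rec, sc) for rec in dataset)
    detail = predictions_frame(preds)
    if detail.empty:
        summary = pd.DataFrame(
            columns=["scenario", "n", "frac_overpredicted", "median_log10_ratio"]
        )
        return detail, summary
    grp = detail.groupby("scenario", sort=False)
    summary = grp.agg(
        n=("species_id", "size"),
        frac_overpredicted=("log10_ratio", lambda s: float((s > 0).mean())),
        median_log10_ratio=("log10_ratio", "median"),
    ).reset_index()
    return detail, summary
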