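"""End-to-end orchestration: load or simulate, fit, predict, compare, report.

:func:`run_all` binds the stages together: it reads (or simulates) a branch
dataset, runs the three stem regressions, optionally the phylogenetic RMA
when a chronogram is supplied, evaluates the furcation baselines, and
writes deterministic CSV/JSON outputs.  Running twice on identical inputs
yields byte-identical tables; every output embeds the configuration hash
and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .allometry import (
    length_effect,
    number_allometry,
    table1,
    widening_regression,
)
from .data import Dataset, read_branch_table, read_newick, validate, write_table
from .furcation import (
    DEFAULT_LB_GRID,
    FurcationScenario,
    compare_scenarios,
)
from .phylo import phylo_number_allometry
from .simulate import SimConfig, simulate_dataset

__all__ = ["RunConfig", "RunReport", "run_all", "default_scenarios"]

log = logging.getLogger("widenedpipe")


class ConfigurationError(ValueError):
    """Raised before any computation when the run configuration is invalid."""


def default_scenarios(
    lb_grid=DEFAULT_LB_GRID, lambda_len: float = 0.7
) -> list[FurcationScenario]:
    """The reference scenario set: fixed sweep 3–30 cm, geometric
    contraction at lambda 0.7, da Vinci, Murray."""
    out = [FurcationScenario(kind="fixed", L_b=float(l)) for l in lb_grid]
    out.append(FurcationScenario(kind="geometric", lambda_len=lambda_len))
    out.append(FurcationScenario(kind="davinci"))
    out.append(FurcationScenario(kind="murray"))
    return out


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_table`` (a CSV path) or ``simulate`` (a
    :class:`~widenedpipe.simulate.SimConfig`) must be given.
    """

    input_table: str | None = None
    simulate: SimConfig | None = None
    tree: str | None = None
    outdir: str | None = None
    scenarios: list[FurcationScenario] = field(default_factory=default_scenarios)
    column_map: dict = field(default_factory=dict)
    units: dict = field(default_factory=dict)
    alpha: float = 0.05
    plots: bool = False

    def digest(self) -> str:
        """Stable hash of the scientific configuration for provenance.

        Output-location fields are excluded so that identical analyses
        written to different directories produce identical files.
        """

        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return {type(o).__name__: dataclasses.asdict(o)}
            return str(o)

        d = dataclasses.asdict(self)
        d.pop("outdir", None)
        d.pop("plots", None)
        blob = json.dumps(d, default=enc, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class RunReport:
    """All results of one run, serializable to JSON."""

    provenance: str
    config_hash: str
    seed: int | None
    n_records: int
    n_species: int
    validation: list[dict]
    number_allometry: dict
    length_effect: dict
    widening_regression: dict
    phylo_rma: dict | None
    scenario_summary: list[dict]
    version: str = __version__

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _load(config: RunConfig) -> Dataset:
    if (config.input_table is None) == (config.simulate is None):
        raise ConfigurationError(
            "exactly one of input_table or simulate must be configured"
        )
    if config.input_table is not None:
        path = Path(config.input_table)
        if not path.exists():
            raise ConfigurationError(f"input table not found: {path}")
        log.info("reading branch table %s", path)
        return read_branch_table(
            path, column_map=config.column_map, units=config.units
        )
    log.info("simulating dataset (seed=%d)", config.simulate.seed)
    return simulate_dataset(config.simulate)


def run_all(config: RunConfig) -> RunReport:
    """Execute every stage and (optionally) write the output files.

    Stage failures propagate with the stage name prefixed, so a pipeline
    user can tell a loading problem from a fitting one.
    """
    dataset = _stage("load", _load, config)
    report_val = _stage("validate", validate, dataset)

    sma = _stage("number_allometry", number_allometry, dataset, alpha=config.alpha)
    multi = _stage("length_effect", length_effect, dataset, alpha=config.alpha)
    wid = _stage(
        "widening_regression", widening_regression, dataset, alpha=config.alpha
    )

    phylo_fit = None
    if config.tree is not None:
        tree = _stage("read_tree", read_newick, config.tree)
        phylo_fit = _stage(
            "phylo_rma", phylo_number_allometry, dataset, tree
        )

    detail, summary = _stage(
        "compare_scenarios", compare_scenarios, dataset, config.scenarios
    )

    seed = config.simulate.seed if config.simulate is not None else None
    report = RunReport(
        provenance=dataset.provenance,
        config_hash=config.digest(),
        seed=seed,
        n_records=len(dataset),
        n_species=dataset.n_species,
        validation=json.loads(report_val.to_json()),
        number_allometry=sma.to_dict(),
        length_effect=multi.to_dict(),
        widening_regression=wid.to_dict(),
        phylo_rma=None if phylo_fit is None else phylo_fit.to_dict(),
        scenario_summary=summary.to_dict(orient="records"),
    )

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        stamp = f"# widenedpipe {__version__} config={report.config_hash} seed={seed}\n"
        _write_csv(table1(dataset, alpha=config.alpha), outdir / "regressions.csv", stamp)
        _write_csv(detail, outdir / "predictions.csv", stamp)
        _write_csv(summary, outdir / "scenario_summary.csv", stamp)
        (outdir / "report.json").write_text(report.to_json() + "\n")
        write_table(dataset, outdir / "dataset.csv")
        if config.plots:
            from .plotting import plot_number_allometry, plot_predictions

            plot_number_allometry(dataset, sma, outdir / "number_allometry.png")
            plot_predictions(dataset, detail, outdir / "predictions.png")
        log.info("outputs written to %s", outdir)
    return report


def _stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except ConfigurationError:
        raise
    except Exception as exc:
        raise RuntimeError(f"stage '{name}' failed: {exc}") from exc


def _write_csv(df: pd.DataFrame, path: Path, stamp: str) -> None:
    with open(path, "w") as fh:
        fh.write(stamp)
        df.to_csv(fh, index=False, float_format="%.12g")
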