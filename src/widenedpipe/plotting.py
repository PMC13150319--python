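"""Diagnostic plots: log-log allometry scatter and observed-vs-predicted."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .allometry import LinearFit
from .data import Dataset

__all__ = ["plot_number_allometry", "plot_predictions"]


def plot_number_allometry(dataset: Dataset, fit: LinearFit, path) -> None:
    """Scatter of log10 tip vs base conduit counts with the SMA line."""
    df = dataset.to_frame()
    x = np.log10(df.n_base.to_numpy(float))
    y = np.log10(df.n_tip.to_numpy(float))
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(x, y, s=18, c="k", alpha=0.7)
    xs = np.linspace(x.min(), x.max(), 50)
    ax.plot(xs, fit.intercept + fit.slope * xs, "b-", label=f"SMA slope {fit.slope:.2f}")
    ax.plot(xs, xs, "k--", lw=0.8, label="1:1")
    ax.set_xlabel(r"$\log_{10} N_\mathrm{base}$")
    ax.set_ylabel(r"$\log_{10} N_\mathrm{tip}$")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_predictions(dataset: Dataset, detail, path) -> None:
    """Observed tip counts against each scenario's predictions (log10 y)."""
    df = dataset.to_frame()
    fig, ax = plt.subplots(figsize=(6, 5))
    x_obs = np.log10(df.n_base.to_numpy(float))
    ax.scatter(
        x_obs, np.log10(df.n_tip.to_numpy(float)), s=18, c="k", label="observed"
    )
    obs_x = dict(zip(df.species_id, x_obs))
    for kind, sub in detail.groupby("kind", sort=False):
        xs = sub.species_id.map(obs_x)
        ax.scatter(xs, sub.log10_n_tip_pred, s=8, alpha=0.4, label=kind)
    ax.set_xlabel(r"$\log_{10} N_\mathrm{base}$")
    ax.set_ylabel(r"$\log_{10} N_\mathrm{tip}$ (observed / predicted)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
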