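"""Minimal Kaplan-Meier and mean-cumulative-function line plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_km", "plot_mcf"]


def plot_km(curves: pd.DataFrame, ax=None, endpoint: str | None = None):
    """Step-plot KM curves from the tidy ``km_curves`` table.

    Expects columns endpoint, group, time, estimate, ci_low, ci_high (as
    written by the pipeline). One line per group; shaded 95% band.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    df = curves if endpoint is None else curves[curves["endpoint"] == endpoint]
    for group, sub in df.groupby("group"):
        ax.step(sub["time"], sub["estimate"], where="post", label=str(group))
        ax.fill_between(sub["time"], sub["ci_low"], sub["ci_high"],
                        step="post", alpha=0.2)
    ax.set_xlabel("months from consent")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(title="group")
    return ax


def plot_mcf(mcf: pd.DataFrame, ax=None):
    """Step-plot mean cumulative progression events per group."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for group, sub in mcf.groupby("group"):
        ax.step(sub["time"], sub["mcf"], where="post", label=str(group))
    ax.set_xlabel("months from consent")
    ax.set_ylabel("mean cumulative progression events")
    ax.legend(title="baseline CTC group")
    return ax
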