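"""Diagnostic figures: ranged plots, size biplots, and Dyar fit plots.

All functions draw onto a supplied or fresh matplotlib Axes and are safe
headless (callers save with ``fig.savefig``); nothing here is required by
the statistical pipeline.
"""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .dyar import DyarFit, StageSummary
from .partition import GapPartition


def _get_ax(ax):
    if ax is None:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        _, ax = plt.subplots(figsize=(5, 4))
    return ax


def ranged_plot(partition: GapPartition, ax=None):
    """Values in ascending order vs rank, colored by cohort, breaks marked."""
    ax = _get_ax(ax)
    values = partition.series.values
    labels = partition.labels_sorted
    ranks = np.arange(1, len(values) + 1)
    for k in range(1, partition.n_cohorts + 1):
        sel = labels == k
        ax.plot(ranks[sel], values[sel], "o-", label=f"cohort {k}")
    for b in partition.breaks:
        ax.axvline(b + 1.5, color="grey", ls=":", lw=0.8)
    ax.set_xlabel("rank")
    ax.set_ylabel(f"{partition.series.variable or 'value'} (µm)")
    ax.legend(fontsize=8)
    return ax


def biplot(x: Sequence[float], y: Sequence[float], labels: Optional[Sequence[int]] = None,
           xlabel: str = "head length (µm)", ylabel: str = "head width (µm)", ax=None):
    """Scatter of two measurements, optionally colored by stage."""
    ax = _get_ax(ax)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if labels is None:
        ax.plot(x, y, "o")
    else:
        labels = np.asarray(labels)
        for k in sorted(set(labels.tolist())):
            sel = labels == k
            ax.plot(x[sel], y[sel], "o", label=f"stage {k}")
        ax.legend(fontsize=8)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    return ax


def dyar_plot(summaries: Sequence[StageSummary], fit: DyarFit, ax=None):
    """ln(stage mean) vs stage index with the fitted line and ±1 sd bars."""
    ax = _get_ax(ax)
    stages = np.array([s.stage for s in summaries], float)
    lnmeans = np.log([s.mean for s in summaries])
    # sd of ln size approximated by cv = sd/mean on the raw scale
    errs = [
        (s.sd / s.mean) if (s.sd is not None and s.mean > 0) else 0.0 for s in summaries
    ]
    ax.errorbar(stages, lnmeans, yerr=errs, fmt="o", capsize=3)
    grid = np.linspace(stages.min() - 0.2, stages.max() + 0.2, 50)
    ax.plot(grid, fit.intercept + fit.slope * grid, "-", lw=1)
    ax.set_xlabel("instar")
    ax.set_ylabel("ln mean size (ln µm)")
    ax.set_xticks(stages)
    ax.set_title(f"{fit.method}: slope={fit.slope:.3f}, $R^2$={fit.r_squared:.3f}", fontsize=9)
    return ax
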