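"""Convenience figures: growth curves and volcano plots."""

from __future__ import annotations

import numpy as np
import pandas as pd


def plot_growth_curves(screen: pd.DataFrame, conditions=None, log_scale=True, ax=None):
    """Replicate-mean growth curves (+/- SEM) per condition.

    ``conditions`` is an optional list of (cell_line, drug) pairs; by
    default every condition in the table is drawn.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    grouped = screen.groupby(["cell_line", "drug", "time_h"])["confluency_pct"]
    stats = grouped.agg(["mean", "sem"]).reset_index()
    pairs = conditions or sorted(
        set(zip(stats["cell_line"], stats["drug"]))
    )
    for line, drug in pairs:
        sub = stats[(stats["cell_line"] == line) & (stats["drug"] == drug)]
        label = f"{line} + {drug}"
        ax.errorbar(
            sub["time_h"], sub["mean"], yerr=sub["sem"], label=label,
            lw=1.2, capsize=0, errorevery=max(1, len(sub) // 24),
        )
    if log_scale:
        ax.set_yscale("log")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("confluency (%)")
    ax.legend(fontsize=8)
    return ax


def plot_volcano(volcano_table: pd.DataFrame, effect_min=1.0, alpha=0.05, ax=None):
    """Scatter of log2 effect vs -log10 corrected p with hits in blue."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    colors = np.where(volcano_table["hit"], "tab:blue", "0.6")
    ax.scatter(volcano_table["effect"], volcano_table["neg_log10_p"], c=colors, s=18)
    ax.axhline(-np.log10(alpha), ls="--", c="0.8", lw=1)
    for sgn in (-1, 1):
        ax.axvline(sgn * effect_min, ls="--", c="0.8", lw=1)
    ax.set_xlabel("log2 effect")
    ax.set_ylabel("-log10 Bonferroni p")
    return ax
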