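"""Simple diagnostic plots over summary tables (optional convenience).

Requires matplotlib (the ``plot`` extra); everything plotted here is also
available as CSV, which is the canonical output.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["plot_metric_by_levels"]


def plot_metric_by_levels(
    summary: pd.DataFrame,
    metric: str = "coverage",
    parameter: str = "beta1",
    ax=None,
):
    """Plot one summary metric against the number of group levels.

    One line per (model, n_obs) combination, the layout used for the
    study's headline comparisons.  Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    sub = summary[summary["parameter"] == parameter]
    for (model, n_obs), grp in sub.groupby(["model", "n_obs"]):
        grp = grp.sort_values("n_levels")
        ax.plot(
            grp["n_levels"],
            grp[metric],
            marker="o" if model == "LMM" else "^",
            linestyle="-" if model == "LMM" else ":",
            label=f"{model}, N={n_obs}",
        )
    if metric == "coverage":
        ax.axhline(0.95, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("levels of the grouping factor")
    ax.set_ylabel(metric.replace("_", " "))
    ax.set_title(parameter)
    ax.legend(fontsize="small")
    return ax
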