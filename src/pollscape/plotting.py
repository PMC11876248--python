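"""Minimal panel plot of aggregated gradient results (requires matplotlib)."""

from __future__ import annotations

import pandas as pd

__all__ = ["plot_gradient_panels"]


def plot_gradient_panels(aggregated: pd.DataFrame, value: str = "mean_service", out=None):
    """One panel per habitat percentage: value vs mean log-LSI, one line per
    hazard level.  ``aggregated`` is the output of ``aggregate_results``.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fractions = sorted(aggregated.habitat_pct.unique())
    fig, axes = plt.subplots(1, len(fractions), figsize=(3 * len(fractions), 3),
                             sharey=True, squeeze=False)
    for ax, pct in zip(axes[0], fractions):
        sub = aggregated[aggregated.habitat_pct == pct]
        for hazard, grp in sub.groupby("hazard"):
            grp = grp.sort_values("mean_log_lsi")
            ax.plot(grp.mean_log_lsi, grp[value], marker="o", label=f"{hazard:g}%")
        ax.set_title(f"{pct:g}% habitat")
        ax.set_xlabel("log(LSI)")
    axes[0][0].set_ylabel(value.replace("_", " ") + " (%)")
    axes[0][-1].legend(title="hazard", fontsize="small")
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=150)
    return fig
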