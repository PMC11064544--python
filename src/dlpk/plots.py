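"""Plotting helpers: pcVPC panels and covariate-effect forest plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .nca import BIOEQUIVALENCE_BAND

__all__ = ["plot_vpc", "plot_forest", "plot_npde"]


def plot_npde(result, path=None):
    """Histogram of the NPDE against the standard-normal density plus a
    normal Q-Q panel."""
    from scipy import stats

    values = np.asarray(result.values)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    ax1.hist(values, bins=30, density=True, color="steelblue", alpha=0.7)
    x = np.linspace(-4, 4, 200)
    ax1.plot(x, stats.norm.pdf(x), "r-", lw=1.5)
    ax1.set_xlabel("NPDE")
    ax1.set_ylabel("density")
    stats.probplot(values, dist="norm", plot=ax2)
    ax2.set_title("normal Q-Q")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_vpc(result, path=None, title="Prediction-corrected VPC"):
    """Median solid, outer percentiles dashed, simulation CIs shaded."""
    tab = result.table
    fig, ax = plt.subplots(figsize=(7, 5))
    for p, (style, color) in {
        50.0: ("-", "red"),
        5.0: ("--", "red"),
        95.0: ("--", "red"),
    }.items():
        sub = tab[tab["pctl"] == p].sort_values("t_mid")
        if sub.empty:
            continue
        ax.plot(sub["t_mid"], sub["observed"], style, color=color, lw=1.5)
        ax.fill_between(
            sub["t_mid"], sub["ci_lo"], sub["ci_hi"],
            color="red" if p == 50.0 else "steelblue", alpha=0.2,
        )
    ax.set_xlabel("Time after dose (h)")
    ax.set_ylabel("Prediction-corrected concentration (ug/mL)")
    ax.set_title(title)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_forest(summary: pd.DataFrame, path=None, metric_order=("auc_tau", "cmax", "ctau")):
    """Covariate-effect ratios (median, 2.5th-97.5th) vs the 0.8-1.25 band."""
    metrics = [m for m in metric_order if m in set(summary["metric"])]
    fig, axes = plt.subplots(1, len(metrics), figsize=(4 * len(metrics), 6), sharey=True)
    axes = np.atleast_1d(axes)
    cats = summary[summary["metric"] == metrics[0]][["covariate", "category"]].drop_duplicates()
    labels = [f"{r.category} (n={int(summary[(summary.category==r.category)&(summary.metric==metrics[0])].n_subjects.iloc[0])})"
              for r in cats.itertuples()]
    ypos = np.arange(len(cats))[::-1]
    for ax, m in zip(axes, metrics):
        sub = summary[summary["metric"] == m].set_index("category")
        med = [sub.loc[c, "median"] for c in cats["category"]]
        lo = [sub.loc[c, "p2.5"] for c in cats["category"]]
        hi = [sub.loc[c, "p97.5"] for c in cats["category"]]
        ax.axvspan(*BIOEQUIVALENCE_BAND, color="0.85")
        ax.axvline(1.0, color="0.4", lw=1)
        ax.errorbar(
            med, ypos,
            xerr=[np.array(med) - np.array(lo), np.array(hi) - np.array(med)],
            fmt="o", color="k", capsize=3,
        )
        ax.set_title(m)
        ax.set_xlabel("Ratio vs overall population")
    axes[0].set_yticks(ypos)
    axes[0].set_yticklabels(labels)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
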