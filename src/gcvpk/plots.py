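"""Publication-style diagnostic plots (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy import stats

from gcvpk.diagnostics import NpdeResult, VpcResult
from gcvpk.nlme import FitResult

__all__ = ["plot_gof", "plot_vpc", "plot_npde"]


def plot_gof(result: FitResult):
    """2x2 goodness-of-fit panel: DV vs PRED, DV vs IPRED, CWRES vs PRED,
    CWRES vs time."""
    t = result.residual_table
    fig, axes = plt.subplots(2, 2, figsize=(8, 7))
    for ax, x, y, xl, yl in (
        (axes[0, 0], t["PRED"], t["DV"], "PRED (ug/mL)", "DV (ug/mL)"),
        (axes[0, 1], t["IPRED"], t["DV"], "IPRED (ug/mL)", "DV (ug/mL)"),
        (axes[1, 0], t["PRED"], t["CWRES"], "PRED (ug/mL)", "CWRES"),
        (axes[1, 1], t["TIME"], t["CWRES"], "time (h)", "CWRES"),
    ):
        ax.scatter(x, y, s=12, alpha=0.6, edgecolors="none")
        ax.set_xlabel(xl)
        ax.set_ylabel(yl)
        if yl == "CWRES":
            for h in (-3, 0, 3):
                ax.axhline(h, color="grey", lw=0.7, ls="--" if h else "-")
        else:
            lim = max(float(x.max()), float(y.max()))
            ax.plot([0, lim], [0, lim], color="grey", lw=0.7)
    fig.tight_layout()
    return fig


def plot_vpc(result: VpcResult):
    """Percentile bands of the simulated replicates with observed percentiles."""
    fig, ax = plt.subplots(figsize=(7, 5))
    s = result.summary
    mids = (s["t_lo"] + s["t_hi"]) / 2
    colors = {2.5: "tab:blue", 50.0: "tab:red", 97.5: "tab:blue"}
    for p in (2.5, 50.0, 97.5):
        sub = s[s["percentile"] == p]
        m = mids[sub.index]
        ax.fill_between(m, sub["sim_lo"], sub["sim_hi"], alpha=0.25,
                        color=colors[p], lw=0)
        ax.plot(m, sub["observed"], "o-", color=colors[p], ms=4,
                label=f"observed {p:g}th")
    ax.set_xlabel("time after last dose (h)")
    ax.set_ylabel("concentration (ug/mL)")
    ax.legend(frameon=False)
    fig.tight_layout()
    return fig


def plot_npde(result: NpdeResult):
    """QQ plot, histogram, and NPDE vs time / vs PRED scatters."""
    v = np.sort(result.values)
    fig, axes = plt.subplots(2, 2, figsize=(8, 7))
    q = stats.norm.ppf((np.arange(1, v.size + 1) - 0.5) / v.size)
    axes[0, 0].scatter(q, v, s=10)
    axes[0, 0].plot(q, q, color="grey", lw=0.8)
    axes[0, 0].set_xlabel("theoretical quantile")
    axes[0, 0].set_ylabel("NPDE")
    axes[0, 1].hist(v, bins=15, density=True, alpha=0.6)
    x = np.linspace(-3.5, 3.5, 200)
    axes[0, 1].plot(x, stats.norm.pdf(x), color="tab:red")
    axes[0, 1].set_xlabel("NPDE")
    t = result.table
    axes[1, 0].scatter(t["TAD"], t["NPDE"], s=10)
    axes[1, 0].set_xlabel("time after last dose (h)")
    axes[1, 0].set_ylabel("NPDE")
    axes[1, 1].scatter(t["PRED"], t["NPDE"], s=10)
    axes[1, 1].set_xlabel("PRED (ug/mL)")
    axes[1, 1].set_ylabel("NPDE")
    for ax in (axes[1, 0], axes[1, 1]):
        ax.axhline(0, color="grey", lw=0.7)
    fig.tight_layout()
    return fig
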