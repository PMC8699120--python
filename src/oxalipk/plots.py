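"""Optional diagnostic plots (goodness of fit, pcVPC, exposure)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["gof_plots", "vpc_plot", "exposure_boxplot"]


def gof_plots(fit, path) -> None:
    """OBS vs PRED/IPRED and CWRES vs PRED/TAD, 2x2 panel."""
    g = fit.gof
    fig, axes = plt.subplots(2, 2, figsize=(8, 8))
    for ax, xcol in zip(axes[0], ("PRED", "IPRED")):
        ax.loglog(g[xcol], g["OBS"], "o", ms=3, alpha=0.6)
        lim = [min(g[xcol].min(), g["OBS"].min()), max(g[xcol].max(), g["OBS"].max())]
        ax.plot(lim, lim, "k-", lw=0.8)
        ax.set_xlabel(f"{xcol} (ug/mL)")
        ax.set_ylabel("OBS (ug/mL)")
    for ax, xcol in zip(axes[1], ("PRED", "TAD")):
        ax.plot(g[xcol], g["CWRES"], "o", ms=3, alpha=0.6)
        ax.axhline(0.0, color="k", lw=0.8)
        for y in (-2, 2):
            ax.axhline(y, color="k", lw=0.5, ls="--")
        ax.set_xlabel(xcol)
        ax.set_ylabel("CWRES")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def vpc_plot(vpc, path) -> None:
    """Prediction-corrected VPC: observed percentiles over simulated bands."""
    t = vpc.bins
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for name, color in (("p5", "tab:blue"), ("p50", "tab:red"), ("p95", "tab:blue")):
        lo, hi = vpc.sim_ci[name]
        ax.fill_between(t, lo, hi, color=color, alpha=0.25, lw=0)
    ax.plot(t, vpc.obs_p50, "r-", label="observed median")
    ax.plot(t, vpc.obs_p5, "b--", label="observed 5th/95th")
    ax.plot(t, vpc.obs_p95, "b--")
    ax.set_yscale("log")
    ax.set_xlabel("time after dose (h)")
    ax.set_ylabel("prediction-corrected concentration (ug/mL)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def exposure_boxplot(summary, path) -> None:
    """Median and 5th-95th exposure per creatinine level."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    x = np.arange(len(summary.cr_levels))
    ax.errorbar(
        x,
        summary.auc_median,
        yerr=[
            summary.auc_median - summary.auc_p5,
            summary.auc_p95 - summary.auc_median,
        ],
        fmt="s",
        capsize=4,
    )
    ax.set_xticks(x, [f"{c:g}" for c in summary.cr_levels])
    ax.set_xlabel("plasma creatinine (mg/dL)")
    ax.set_ylabel("AUC(0-inf) (ug*h/mL)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
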