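"""Figure helpers: pooled lag panels and model diagnostics."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .correlation import CrossCorrResult
from .models import ModelFit

__all__ = ["lag_panel", "fitted_observed_plot"]


def lag_panel(results: list[CrossCorrResult], path: str | Path, title: str = "") -> Path:
    """Pooled cross-correlation panels: dots with CI bars, dashed lag-0 line."""
    n = len(results)
    fig, axes = plt.subplots(1, n, figsize=(3.2 * n, 3.0), squeeze=False, sharey=True)
    for ax, res in zip(axes[0], results):
        t = res.table
        yerr = [t["mean"] - t["ci_low"], t["ci_high"] - t["mean"]]
        ax.errorbar(t.index, t["mean"], yerr=yerr, fmt="o", color="k", capsize=3)
        ax.axvline(0, ls="--", color="grey", lw=0.8)
        ax.axhline(0, color="grey", lw=0.6)
        ax.axvline(res.peak_lag, ls=":", color="firebrick", lw=0.8)
        ax.set_xlabel("lag (0.5 days)")
        ax.set_title(f"{res.pair[0]} → {res.pair[1]} (peak {res.peak_lag})", fontsize=9)
    axes[0][0].set_ylabel("pooled cross-correlation")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def fitted_observed_plot(fit: ModelFit, path: str | Path) -> Path:
    """Fitted-versus-observed scatter for a clearance model fit."""
    fig, ax = plt.subplots(figsize=(3.6, 3.4))
    ax.scatter(fit.fitted(), fit.model.y, s=12, alpha=0.6)
    lims = [min(fit.model.y.min(), fit.fitted().min()), max(fit.model.y.max(), fit.fitted().max())]
    ax.plot(lims, lims, "k--", lw=0.8)
    ax.set_xlabel("fitted")
    ax.set_ylabel("observed")
    ax.set_title(f"{fit.kind}: {fit.response}", fontsize=9)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
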