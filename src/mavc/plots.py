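"""Optional figure helpers (scatter with marginals, posterior predictive)."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .memory_models import MODELS, CceiDataset, PosteriorSamples

__all__ = ["scatter_with_marginals", "posterior_predictive_overlay"]


def scatter_with_marginals(data: CceiDataset, path) -> None:
    """RI vs CCEI scatter with marginal histograms."""
    fig = plt.figure(figsize=(6, 6))
    grid = fig.add_gridspec(
        2, 2, width_ratios=(4, 1), height_ratios=(1, 4), hspace=0.05, wspace=0.05
    )
    ax = fig.add_subplot(grid[1, 0])
    ax_top = fig.add_subplot(grid[0, 0], sharex=ax)
    ax_right = fig.add_subplot(grid[1, 1], sharey=ax)
    ax.scatter(data.t, data.ccei, s=12, alpha=0.6)
    ax.set_xlabel("retention interval (s)")
    ax.set_ylabel("CCEI")
    ax.set_ylim(-0.02, 1.02)
    ax_top.hist(data.t, bins=20)
    ax_right.hist(data.ccei, bins=20, orientation="horizontal")
    for a in (ax_top, ax_right):
        a.tick_params(labelbottom=False, labelleft=False)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def posterior_predictive_overlay(
    data: CceiDataset, samples: PosteriorSamples, model: str, path, n_curves: int = 200
) -> None:
    """Scatter overlaid with the median and 95% band of posterior mean curves."""
    mod = MODELS[model]
    draws = samples.flat()
    idx = np.linspace(0, draws.shape[0] - 1, min(n_curves, draws.shape[0])).astype(int)
    tt = np.linspace(0.0, 30.0, 120)
    curves = mod.mu(draws[idx], tt)
    lo, med, hi = np.percentile(curves, [2.5, 50.0, 97.5], axis=0)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(data.t, data.ccei, s=12, alpha=0.5)
    ax.plot(tt, med, color="black", lw=2)
    ax.plot(tt, lo, color="grey", lw=1)
    ax.plot(tt, hi, color="grey", lw=1)
    ax.set_xlabel("retention interval (s)")
    ax.set_ylabel("CCEI")
    ax.set_ylim(-0.02, 1.02)
    ax.set_title(f"{model} model posterior predictions")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
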