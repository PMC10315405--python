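"""Figure analogues of the standard reporting plots: modal-pattern grids,
the global-allocation heatmap, and local pattern distributions."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .postprocess import PatternSummary

_LEVEL_CMAP = matplotlib.colors.ListedColormap(
    ["#1f3f77", "#7fb2e5", "#57a05a", "#e8d44d"])


def plot_modal_patterns(summary: PatternSummary, path=None):
    """Grid of modal consumption levels per global pattern (items on y)."""
    mg = summary.modal_global
    K, p = mg.shape
    fig, ax = plt.subplots(figsize=(2 + K, max(4, p * 0.22)))
    im = ax.imshow(mg.T, aspect="auto", cmap=_LEVEL_CMAP, vmin=1,
                   vmax=summary.theta0_mean.shape[-1])
    ax.set_xticks(range(K), [f"G{k + 1}" for k in range(K)])
    ax.set_yticks(range(p), summary.item_names, fontsize=7)
    ax.set_title("Modal consumption level, global patterns")
    fig.colorbar(im, ax=ax, label="level (1 = none)")
    if path:
        fig.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(fig)
    return fig


def plot_allocation_heatmap(summary: PatternSummary, path=None,
                            source: str = "G"):
    """Probability of each item following the global process, by subgroup."""
    mat = summary.heatmap_G if source == "G" else summary.heatmap_nu
    p, S = mat.shape
    fig, ax = plt.subplots(figsize=(2 + S, max(4, p * 0.22)))
    im = ax.imshow(mat, aspect="auto", cmap="Blues", vmin=0, vmax=1)
    ax.set_xticks(range(S), summary.subgroup_names, rotation=45, ha="right")
    ax.set_yticks(range(p), summary.item_names, fontsize=7)
    ax.set_title("P(item follows the global pattern)")
    fig.colorbar(im, ax=ax)
    if path:
        fig.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(fig)
    return fig


def plot_local_patterns(summary: PatternSummary, path=None):
    """Stacked level-probability bars of the top local pattern per subgroup."""
    S = len(summary.subgroup_names)
    d = summary.theta0_mean.shape[-1]
    p = len(summary.item_names)
    fig, axes = plt.subplots(S, 1, figsize=(max(6, p * 0.35), 2.2 * S),
                             sharex=True, squeeze=False)
    colors = ["#9e9e9e", "#e8d44d", "#ef8a3c", "#d12f2f"][:d]
    x = np.arange(p)
    for s in range(S):
        ax = axes[s, 0]
        theta = summary.theta1_mean[s][0]  # dominant local pattern
        bottom = np.zeros(p)
        for r in range(d):
            ax.bar(x, theta[:, r], bottom=bottom, color=colors[r],
                   width=0.8, label=f"level {r + 1}" if s == 0 else None)
            bottom += theta[:, r]
        ax.set_ylabel(summary.subgroup_names[s], fontsize=8)
        ax.set_ylim(0, 1)
    axes[-1, 0].set_xticks(x, summary.item_names, rotation=90, fontsize=7)
    fig.legend(loc="upper right", fontsize=7)
    fig.suptitle("Dominant local pattern per subgroup")
    if path:
        fig.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(fig)
    return fig
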