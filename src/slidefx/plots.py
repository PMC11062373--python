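"""Figure helpers for the CLI: slide-effect PCA scatter and QQ plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .set_structure import SlideEffectPCA
from .simulation_study import SimulationStudyResult

__all__ = ["pca_scatter", "qq_plot"]

_CLASS_COLORS = {"high": "#d62728", "low": "#1f77b4"}


def pca_scatter(pca: SlideEffectPCA, path: str | Path) -> None:
    """PC1 loadings vs PC2 loadings per CpG, coloured by median-beta class."""
    fig, ax = plt.subplots(figsize=(5, 4.5))
    load = pca.loadings
    if pca.median_class is not None:
        for cls, sub in load.groupby(pca.median_class):
            ax.scatter(sub["PC1"], sub["PC2"], s=8, alpha=0.6,
                       color=_CLASS_COLORS.get(cls, "gray"), label=cls)
        ax.legend(title="median beta", frameon=False)
    else:
        ax.scatter(load["PC1"], load["PC2"], s=8, alpha=0.6, color="gray")
    ve = pca.var_explained
    ax.set_xlabel(f"PC1 loading ({ve[0] * 100:.1f}% var)")
    if len(ve) > 1:
        ax.set_ylabel(f"PC2 loading ({ve[1] * 100:.1f}% var)")
    ax.set_title("Slide-effect PCA")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def qq_plot(result: SimulationStudyResult, path: str | Path) -> None:
    """QQ plots of -log10 p per set, one panel per set, lines per approach."""
    sets = sorted({label for _, label in result.pvalues})
    approaches = list(dict.fromkeys(a for a, _ in result.pvalues))
    ncol = min(3, len(sets))
    nrow = -(-len(sets) // ncol)
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3.5 * nrow), squeeze=False)
    for ax, label in zip(axes.ravel(), sets):
        for approach in approaches:
            exp, obs = result.qq_data[(approach, label)]
            ax.plot(exp, obs, lw=1, label=approach)
        lim = max(ax.get_xlim()[1], 1)
        ax.plot([0, lim], [0, lim], "k--", lw=0.8)
        ax.set_title(label)
        ax.set_xlabel("expected -log10 p")
        ax.set_ylabel("observed -log10 p")
    for ax in axes.ravel()[len(sets):]:
        ax.axis("off")
    axes.ravel()[0].legend(fontsize=8, frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
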