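"""Plot helpers: Vst Manhattan-style scan and PCA scatter."""

from __future__ import annotations

import numpy as np


def plot_vst_manhattan(records, cutoff: float | None = None, path: str | None = None):
    """Per-gene Vst scatter in gene order with an optional top-percentile line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    defined = [r for r in records if r.defined]
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.scatter(range(len(defined)), [r.vst for r in defined], s=6, c="steelblue")
    if cutoff is not None:
        ax.axhline(cutoff, ls="--", c="firebrick", lw=1)
    ax.set_xlabel("gene index")
    ax.set_ylabel(r"$V_{st}$")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_pca(result, labels: dict[str, str] | None = None, path: str | None = None):
    """PC1 vs PC2 scatter colored by population label."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    scores = result.scores
    if labels:
        groups = sorted({labels[s] for s in result.samples})
        for g, color in zip(groups, ("steelblue", "darkorange", "seagreen")):
            idx = np.array([i for i, s in enumerate(result.samples) if labels[s] == g])
            ax.scatter(scores[idx, 0], scores[idx, 1], s=12, label=g, c=color)
        ax.legend()
    else:
        ax.scatter(scores[:, 0], scores[:, 1], s=12)
    ev = result.explained_variance_pct
    ax.set_xlabel(f"PC1 ({ev[0]:.2f}%)")
    if len(ev) > 1:
        ax.set_ylabel(f"PC2 ({ev[1]:.2f}%)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
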