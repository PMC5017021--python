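"""Score plots and fold-change heat maps (matplotlib, non-interactive)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .io import SampleMetadata
from .multivariate import ClusterTree, PCAResults


def score_plot(results: PCAResults, meta: SampleMetadata, sample_ids, path, title: str = "") -> None:
    """PC1/PC2 score plot, coloured by condition and labelled C/T.time."""
    scores = results.scores_frame(index=sample_ids)
    fig, ax = plt.subplots(figsize=(6, 5))
    meta_idx = meta.table.set_index("injection_id")
    colors = {"control": "tab:blue", "treated": "tab:red"}
    for inj, row in scores.iterrows():
        cond = meta_idx.loc[inj, "condition"]
        ax.scatter(row["PC1"], row["PC2"], color=colors.get(cond, "gray"), s=25)
        ax.annotate(inj, (row["PC1"], row["PC2"]), fontsize=5, alpha=0.7)
    r2 = results.r2cum[-1] if len(results.r2cum) else 0.0
    sub = f"R2cum {r2:.3f}"
    if results.q2cum is not None and len(results.q2cum):
        sub += f", Q2cum {results.q2cum[-1]:.3f}"
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.set_title(f"{title} ({sub})".strip())
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def log2fc_heatmap(log2fc: pd.DataFrame, tree: ClusterTree, path, title: str = "") -> None:
    """Heat map of log2 fold changes with rows in dendrogram leaf order."""
    ordered = log2fc.iloc[tree.leaf_order]
    vmax = max(1.0, float(np.nanmax(np.abs(ordered.to_numpy()))))
    fig, ax = plt.subplots(figsize=(6, max(3, 0.18 * len(ordered))))
    im = ax.imshow(ordered.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(len(ordered.columns)), [str(c) for c in ordered.columns], fontsize=7)
    ax.set_yticks(range(len(ordered)), [str(i) for i in ordered.index], fontsize=5)
    fig.colorbar(im, ax=ax, label="log2 fold change")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
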