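"""Small plotting helpers for screen results.

Matplotlib is imported lazily so the analysis stack stays importable in
minimal environments.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["plot_signature", "plot_precision_recall", "plot_consensus_heatmap"]


def plot_signature(results, strain, ax=None):
    """Bar plot of a strain's standardized amino acid signature (Z-scores),
    with the univariate significance threshold band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    z = results.z.loc[strain]
    called = results.univariate_calls().loc[strain]
    colors = ["#c0392b" if c else "#7f8c8d" for c in called]
    ax.bar(range(len(z)), z.to_numpy(), color=colors)
    ax.axhline(0, color="black", lw=0.8)
    ax.set_xticks(range(len(z)))
    ax.set_xticklabels(z.index, rotation=90)
    ax.set_ylabel("Z (robust SD units)")
    ax.set_title(f"{strain}: metabolic signature")
    return ax


def plot_precision_recall(curve: pd.DataFrame, ax=None, label=None,
                          random_precision: float | None = 0.10):
    """Precision over TP recall, with the random-classifier baseline."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.plot(curve["tp"], curve["precision"], drawstyle="steps-post", label=label)
    if random_precision is not None:
        ax.axhline(random_precision, ls="--", color="grey",
                   label=f"random ({random_precision:.0%})")
    ax.set_xlabel("true positives recalled")
    ax.set_ylabel("precision")
    ax.set_ylim(0, 1.05)
    ax.legend(loc="best")
    return ax


def plot_consensus_heatmap(consensus_results, ax=None):
    """Consensus-index matrix ordered by the final cluster labels."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    labels = consensus_results.labels
    if labels is None:
        labels = consensus_results.final_clusters()
    order = labels.sort_values(kind="mergesort").index
    c = consensus_results.consensus.loc[order, order].to_numpy()
    im = ax.imshow(np.nan_to_num(c, nan=0.0), cmap="viridis", vmin=0, vmax=1)
    ax.figure.colorbar(im, ax=ax, label="consensus index")
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title("consensus matrix (cluster-ordered)")
    return ax
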