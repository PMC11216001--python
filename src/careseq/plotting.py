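"""Sequence visualisations: state-distribution and index plots per typology."""
from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .sequences import SequenceSet  # noqa: E402


def state_distribution_plot(seqs: SequenceSet, labels=None, path=None):
    """Weighted per-sweep state composition, optionally one panel per cluster."""
    alpha = seqs.alphabet
    groups = [("All children", np.ones(len(seqs), dtype=bool))]
    if labels is not None:
        labels = np.asarray(labels)
        groups = [(str(g), labels == g) for g in sorted(set(map(str, labels)))]
    fig, axes = plt.subplots(1, len(groups), figsize=(4 * len(groups), 3.2),
                             squeeze=False, sharey=True)
    sweeps = np.arange(1, seqs.n_sweeps + 1)
    for ax, (name, mask) in zip(axes[0], groups):
        w = seqs.weights[mask]
        shares = np.zeros((alpha.size, seqs.n_sweeps))
        for t in range(seqs.n_sweeps):
            shares[:, t] = np.bincount(seqs.states[mask, t], weights=w,
                                       minlength=alpha.size) / w.sum()
        bottom = np.zeros(seqs.n_sweeps)
        for s, code in enumerate(alpha.codes):
            ax.bar(sweeps, shares[s], bottom=bottom, color=alpha.color(code),
                   label=alpha.label(code), width=0.8)
            bottom += shares[s]
        ax.set_title(name, fontsize=9)
        ax.set_xticks(sweeps)
        ax.set_xlabel("sweep")
    axes[0][0].set_ylabel("weighted share")
    handles, lab = axes[0][-1].get_legend_handles_labels()
    fig.legend(handles, lab, loc="lower center", ncol=2, fontsize=7,
               bbox_to_anchor=(0.5, -0.25))
    fig.tight_layout()
    if path:
        fig.savefig(path, bbox_inches="tight", dpi=120)
        plt.close(fig)
        return None
    return fig


def index_plot(seqs: SequenceSet, labels=None, path=None, max_rows: int = 500):
    """Each row one child's sequence, coloured by state, grouped by cluster."""
    alpha = seqs.alphabet
    order = np.argsort(np.asarray(labels).astype(str), kind="stable") if labels is not None \
        else np.arange(len(seqs))
    order = order[:max_rows]
    img = seqs.states[order]
    from matplotlib.colors import ListedColormap

    cmap = ListedColormap([alpha.color(c) for c in alpha.codes])
    fig, ax = plt.subplots(figsize=(4, 6))
    ax.imshow(img, aspect="auto", cmap=cmap, vmin=0, vmax=alpha.size - 1,
              interpolation="nearest")
    ax.set_xticks(range(seqs.n_sweeps))
    ax.set_xticklabels([f"sw{t + 1}" for t in range(seqs.n_sweeps)])
    ax.set_ylabel("children (sorted by typology)" if labels is not None else "children")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
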