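"""Optional figure outputs: ROC curves, decision curves, selection bars."""

from __future__ import annotations

import numpy as np

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_roc(scores_by_model: dict, labels, path) -> None:
    from sklearn.metrics import roc_curve
    fig, ax = plt.subplots(figsize=(5, 5))
    for name, s in scores_by_model.items():
        fpr, tpr, _ = roc_curve(labels, s)
        ax.plot(fpr, tpr, label=name)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_decision_curve(dca, path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    for col in dca.columns:
        if col == "threshold":
            continue
        style = {"treat_none": "k-", "treat_all": "k:"}.get(col)
        if style:
            ax.plot(dca["threshold"], dca[col], style, lw=0.8, label=col)
        else:
            ax.plot(dca["threshold"], dca[col], label=col)
    ax.set_ylim(bottom=-0.05)
    ax.set_xlabel("threshold probability")
    ax.set_ylabel("net benefit")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_selection_frequencies(frequencies, threshold: float, path) -> None:
    freq = frequencies.sort_values(ascending=True)
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.barh(np.arange(len(freq)), freq.to_numpy())
    ax.set_yticks(np.arange(len(freq)), freq.index, fontsize=7)
    ax.axvline(threshold, color="r", ls="--", lw=0.8)
    ax.set_xlabel("bootstrap selection frequency")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
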