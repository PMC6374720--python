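"""Minimal static figures for the pipeline outputs."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402


def plot_pcoa(coords: pd.DataFrame, taxa: dict[str, str], path) -> None:
    """Scatter of specimens on the first two principal coordinates,
    coloured by taxon label."""
    fig, ax = plt.subplots(figsize=(6, 5))
    labels = sorted({taxa.get(s, "?") for s in coords.index})
    cmap = plt.get_cmap("tab10")
    for i, label in enumerate(labels):
        members = [s for s in coords.index if taxa.get(s, "?") == label]
        sub = coords.loc[members]
        ax.scatter(sub.iloc[:, 0], sub.iloc[:, 1], s=25,
                   color=cmap(i % 10), label=label)
    ax.set_xlabel("PCo 1")
    ax.set_ylabel("PCo 2")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_hybrid_metrics(report: pd.DataFrame, path) -> None:
    """Per-specimen hybrid index and panel heterozygosity bar chart."""
    fig, axes = plt.subplots(2, 1, figsize=(8, 6), sharex=True)
    x = range(len(report))
    axes[0].bar(x, 100 * report["index_a"], color="0.3")
    axes[0].axhline(50, color="red", lw=0.8, ls="--")
    axes[0].set_ylabel("% alleles from parent A")
    axes[1].bar(x, 100 * report["het_frac"], color="0.5")
    axes[1].set_ylabel("% loci heterozygous")
    axes[1].set_xticks(list(x))
    axes[1].set_xticklabels(report["specimen_id"], rotation=90, fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
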