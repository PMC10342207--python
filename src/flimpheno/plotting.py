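"""Figures for classifier reports: ROC curves, gini importances, UMAP scatter."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_roc", "plot_importances", "plot_embedding"]


def plot_roc(pair_reports: dict, title: str, path) -> None:
    """Pooled test-fold ROC curves, one per feature set, for one class pair."""
    fig, ax = plt.subplots(figsize=(4.5, 4))
    for name, rep in pair_reports.items():
        ax.plot(rep.roc_points["fpr"], rep.roc_points["tpr"],
                label=f"{name} (AUC {rep.mean_auc:.2f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_importances(report, path) -> None:
    """Mean-decrease-gini importances of one classifier, sorted."""
    series = pd.Series(report.importances).sort_values()
    fig, ax = plt.subplots(figsize=(5, 0.3 * len(series) + 1.2))
    series.plot.barh(ax=ax)
    ax.set_xlabel("mean decrease gini")
    ax.set_title(f"{report.class_a} vs {report.class_b} ({report.feature_set})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_embedding(coords: pd.DataFrame, title: str, path) -> None:
    """2-D embedding scatter colored by group label."""
    fig, ax = plt.subplots(figsize=(4.5, 4))
    for group, sub in coords.groupby("group"):
        ax.scatter(sub["umap1"], sub["umap2"], s=8, label=str(group), alpha=0.7)
    ax.set_xlabel("UMAP 1")
    ax.set_ylabel("UMAP 2")
    ax.set_title(title)
    ax.legend(fontsize=8, markerscale=1.5)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
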