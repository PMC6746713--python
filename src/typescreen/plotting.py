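"""Plots for the screening results: ROC with CI band, feature box plots,
daily trajectories.  Matplotlib is imported lazily with the Agg backend so
the package works headless."""

from __future__ import annotations

import numpy as np
import pandas as pd


def _plt():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_roc(roc_summary, path=None, label: str | None = None):
    """Mean bootstrap ROC curve with the pointwise 2.5-97.5 percentile band."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(5, 5))
    lbl = label or (
        f"AUC = {roc_summary.mean_auc:.3f} "
        f"[{roc_summary.ci_low:.2f}-{roc_summary.ci_high:.2f}]"
    )
    ax.plot(roc_summary.fpr_grid, roc_summary.mean_tpr, lw=2, label=lbl)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8, alpha=0.6)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right")
    ax.set_title("Subject-level bootstrap ROC")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_feature_boxes(
    feature_table: pd.DataFrame, labels, features: list[str], path=None
):
    """Group-wise box plots of selected session features (DT vs HC)."""
    from .evaluate import _labels_to_series

    plt = _plt()
    lab = _labels_to_series(labels)
    y = feature_table["subject_id"].map(lab)
    fig, axes = plt.subplots(1, len(features), figsize=(2.4 * len(features), 4))
    axes = np.atleast_1d(axes)
    for ax, f in zip(axes, features):
        data = [feature_table.loc[y == 1, f], feature_table.loc[y == 0, f]]
        ax.boxplot(data, tick_labels=["DT", "HC"], showfliers=False)
        ax.set_title(f)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_daily_trajectories(daily: pd.DataFrame, threshold: float | None = None,
                            path=None):
    """Daily mean prediction probability per subject over the study days."""
    plt = _plt()
    subjects = sorted(daily["subject_id"].unique())
    ncols = min(4, len(subjects))
    nrows = int(np.ceil(len(subjects) / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(3 * ncols, 2.2 * nrows),
                             squeeze=False, sharey=True)
    for ax, s in zip(axes.flat, subjects):
        g = daily[daily["subject_id"] == s]
        ax.plot(g["day_index"], g["mean_prob"], "o-", ms=4)
        if threshold is not None:
            ax.axhline(threshold, ls="--", lw=0.8, color="gray")
        ax.set_title(s, fontsize=9)
        ax.set_ylim(0, 1)
    for ax in axes.flat[len(subjects):]:
        ax.set_visible(False)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
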