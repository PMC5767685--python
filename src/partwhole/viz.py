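"""Plot helpers mirroring the standard figures of this analysis style:
RSM heatmaps, weight-curve bands (mean ± SEM), and accuracy bars."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def rsm_heatmap(group_rsm: pd.DataFrame, roi: str, path: str | Path) -> Path:
    """One heatmap per emotion for a given ROI from the long group-RSM table."""
    emotions = list(dict.fromkeys(group_rsm["emotion"]))
    cats = sorted(set(group_rsm["cat_a"]) | set(group_rsm["cat_b"]))
    fig, axes = plt.subplots(1, len(emotions), figsize=(4 * len(emotions), 3.6))
    axes = np.atleast_1d(axes)
    sub_roi = group_rsm[group_rsm["roi"] == roi]
    for ax, emo in zip(axes, emotions):
        sub = sub_roi[sub_roi["emotion"] == emo]
        mat = np.full((len(cats), len(cats)), np.nan)
        for _, row in sub.iterrows():
            i, j = cats.index(row["cat_a"]), cats.index(row["cat_b"])
            mat[i, j] = mat[j, i] = row["z"]
        im = ax.imshow(mat, cmap="viridis")
        ax.set_xticks(range(len(cats)), cats, rotation=45, ha="right")
        ax.set_yticks(range(len(cats)), cats)
        ax.set_title(f"{roi} – {emo}")
        fig.colorbar(im, ax=ax, label="Fisher z")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def weight_band_plot(curves: pd.DataFrame, roi: str, path: str | Path) -> Path:
    """Group mean ± SEM of the α → z curve per emotion for one ROI."""
    sub = curves[curves["roi"] == roi]
    fig, ax = plt.subplots(figsize=(5.5, 4))
    for emo, grp in sub.groupby("emotion"):
        agg = grp.groupby("alpha")["z"].agg(["mean", "sem"])
        ax.plot(agg.index, agg["mean"], label=emo)
        ax.fill_between(
            agg.index, agg["mean"] - agg["sem"], agg["mean"] + agg["sem"], alpha=0.3
        )
    ax.set_xlabel("face weight α")
    ax.set_ylabel("Fisher z(r)")
    ax.set_title(f"weight curves – {roi}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def accuracy_bar_plot(group_class: pd.DataFrame, path: str | Path) -> Path:
    """Mean decoding accuracy per ROI × training type with the chance line."""
    pivot = group_class.pivot(index="roi", columns="training_type", values="mean_accuracy")
    fig, ax = plt.subplots(figsize=(1.6 * len(pivot) + 2, 4))
    pivot.plot.bar(ax=ax)
    ax.axhline(1 / 3, color="k", linestyle="--", linewidth=1, label="chance (33.33%)")
    ax.set_ylabel("accuracy")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
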