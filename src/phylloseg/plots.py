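"""Matplotlib renderings of the three result views: metric bars, score bars
with significance asterisks, and the two-score scatter with the LDA
boundary."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .classification import FisherLDA
from .scoring import GroupStats

_LESION_ORDER = ["FA", "PT"]


def score_bar_plot(stats: GroupStats, path: str | Path, alpha: float = 0.05) -> None:
    """Mean +/- SD bars per lesion for both scores; an asterisk marks a
    KS p-value below ``alpha``."""
    fig, axes = plt.subplots(1, 2, figsize=(7, 3.2))
    panels = [
        ("Epithelial / stromal area ratio", stats.area_ratio_mean, stats.area_ratio_sd,
         stats.ks_area_ratio[1]),
        ("Mean stromal SHG (8-bit)", stats.shg_mean, stats.shg_sd, stats.ks_shg[1]),
    ]
    for ax, (title, means, sds, p) in zip(axes, panels):
        xs = np.arange(len(_LESION_ORDER))
        vals = [means.get(l, np.nan) for l in _LESION_ORDER]
        errs = [sds.get(l, 0.0) for l in _LESION_ORDER]
        ax.bar(xs, vals, yerr=errs, capsize=4, color=["#4878CF", "#D65F5F"])
        ax.set_xticks(xs, _LESION_ORDER)
        ax.set_title(title, fontsize=9)
        if np.isfinite(p) and p < alpha:
            top = max(v + e for v, e in zip(vals, errs))
            ax.plot(xs, [top * 1.08] * 2, "k-", lw=1)
            ax.text(0.5, top * 1.1, "*", ha="center", fontsize=14)
        ax.margins(y=0.2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def scatter_plot(
    points: pd.DataFrame, path: str | Path, model: FisherLDA | None = None
) -> None:
    """Two-score scatter: filled circles FA, open circles PT, colored by
    patient; optionally overlays the LDA decision boundary."""
    fig, ax = plt.subplots(figsize=(4.6, 4.2))
    patients = sorted(points["patient_id"].unique())
    cmap = plt.get_cmap("tab10")
    colors = {p: cmap(i % 10) for i, p in enumerate(patients)}
    for (lesion, patient), grp in points.groupby(["lesion", "patient_id"]):
        filled = lesion == "FA"
        ax.scatter(
            grp["area_ratio"],
            grp["shg_stroma_mean"],
            s=18,
            facecolors=colors[patient] if filled else "none",
            edgecolors=colors[patient],
            linewidths=0.8,
            label=None,
        )
    if model is not None and np.linalg.norm(model.w_) > 0:
        xs = np.linspace(points["area_ratio"].min(), points["area_ratio"].max(), 200)
        w, b = model.w_, model.b_
        if model.standardize:
            xs_s = (xs - model.scale_mean_[0]) / model.scale_std_[0]
            if abs(w[1]) > 1e-12:
                ys_s = -(w[0] * xs_s + b) / w[1]
                ys = ys_s * model.scale_std_[1] + model.scale_mean_[1]
                ax.plot(xs, ys, "k--", lw=1)
        elif abs(w[1]) > 1e-12:
            ax.plot(xs, -(w[0] * xs + b) / w[1], "k--", lw=1)
        lo, hi = points["shg_stroma_mean"].min(), points["shg_stroma_mean"].max()
        pad = 0.1 * (hi - lo + 1e-9)
        ax.set_ylim(lo - pad, hi + pad)
    ax.set_xlabel("Epithelial / stromal area ratio")
    ax.set_ylabel("Mean stromal SHG (8-bit)")
    ax.set_title("FA (filled) vs PT (open), colored by patient", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def metric_bar_plot(summaries: list[dict], path: str | Path) -> None:
    """Mean +/- SD bars of total accuracy and weighted IoU per split."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    metrics = ["accuracy", "weighted_iou"]
    width = 0.35
    xs = np.arange(len(summaries))
    for i, metric in enumerate(metrics):
        vals = [s[f"{metric}_mean"] for s in summaries]
        errs = [s[f"{metric}_sd"] for s in summaries]
        ax.bar(xs + (i - 0.5) * width, vals, width, yerr=errs, capsize=4,
               label=metric.replace("_", " "))
    ax.set_xticks(xs, [s["split"] for s in summaries])
    ax.set_ylim(0, 1.05)
    ax.legend(fontsize=8)
    ax.set_title("Segmentation performance per split", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
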