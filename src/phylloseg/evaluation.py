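"""Segmentation quality metrics: confusion matrix, total accuracy, per-class
and area-weighted IoU, FN/FP difference images, and per-split reports.

Metrics are computed per image and then aggregated (mean and sample SD over
images); pooled-pixel variants are also reported for completeness. Weighted
IoU uses ground-truth class-area fractions as weights; classes absent from
both rasters have undefined IoU and are excluded (their weight is zero
anyway).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyInputError, ShapeMismatchError
from .io import DatasetManifest, LABELS, LABEL_NAMES, STROMA
from .segmentation import SegNetSegmenter, predict as predict_image


def confusion(pred: np.ndarray, truth: np.ndarray, n_classes: int = 3) -> np.ndarray:
    """3x3 count matrix; rows are ground truth, columns are prediction."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ShapeMismatchError(f"pred {pred.shape} vs truth {truth.shape}")
    flat = truth.astype(np.intp).ravel() * n_classes + pred.astype(np.intp).ravel()
    return np.bincount(flat, minlength=n_classes * n_classes).reshape(n_classes, n_classes)


def total_accuracy(cm: np.ndarray) -> float:
    """Fraction of pixels on the diagonal."""
    total = cm.sum()
    if total == 0:
        raise EmptyInputError("empty confusion matrix")
    return float(np.trace(cm) / total)


def class_iou(cm: np.ndarray, k: int) -> float:
    """Intersection-over-union for class ``k``; NaN when the class is absent
    from both rasters (undefined, excluded from aggregates)."""
    inter = cm[k, k]
    union = cm[k, :].sum() + cm[:, k].sum() - inter
    if union == 0:
        return float("nan")
    return float(inter / union)


def weighted_iou(cm: np.ndarray) -> float:
    """Ground-truth-area-weighted sum of per-class IoU values."""
    total = cm.sum()
    if total == 0:
        raise EmptyInputError("empty confusion matrix")
    out = 0.0
    for k in range(cm.shape[0]):
        w = cm[k, :].sum() / total
        if w > 0:
            out += w * class_iou(cm, k)
    return float(out)


def difference_image(
    pred: np.ndarray, truth: np.ndarray, reference_class: int = STROMA
) -> np.ndarray:
    """RGB visualization of disagreement relative to one reference class:
    false negatives (truth is the class, prediction is not) in magenta,
    false positives in green, agreement as grayscale ground truth."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ShapeMismatchError(f"pred {pred.shape} vs truth {truth.shape}")
    gray = (truth.astype(np.uint16) * 255 // max(len(LABELS) - 1, 1)).astype(np.uint8)
    rgb = np.stack([gray, gray, gray], axis=-1)
    fn = (truth == reference_class) & (pred != reference_class)
    fp = (pred == reference_class) & (truth != reference_class)
    rgb[fn] = (255, 0, 255)
    rgb[fp] = (0, 255, 0)
    return rgb


@dataclass
class EvalReport:
    """Per-image metric table plus aggregate statistics for one split."""

    split: str
    per_image: pd.DataFrame  # image_id, accuracy, weighted_iou, iou_<class>...
    summary: dict

    def save(self, csv_path: str | Path, json_path: str | Path) -> None:
        self.per_image.to_csv(csv_path, index=False)
        Path(json_path).write_text(json.dumps(self.summary, indent=2))


def _aggregate(values: np.ndarray) -> tuple[float, float]:
    mean = float(np.nanmean(values))
    finite = values[~np.isnan(values)]
    sd = float(np.std(finite, ddof=1)) if finite.size > 1 else 0.0
    return mean, sd


def evaluate_split(
    model: SegNetSegmenter, manifest: DatasetManifest, split: str
) -> EvalReport:
    """Segment every image of a split and report per-image total accuracy,
    weighted IoU, and per-class IoU, with mean and sample SD over images."""
    rows = manifest.subset(split)
    if rows.empty:
        raise EmptyInputError(f"split '{split}' is empty")
    records = []
    pooled = np.zeros((3, 3), dtype=np.int64)
    for _, row in rows.iterrows():
        image = manifest.load_image(row["image_id"])
        truth = manifest.load_mask(row["image_id"])
        pred = predict_image(model, image)
        cm = confusion(pred, truth)
        pooled += cm
        rec = {
            "image_id": row["image_id"],
            "lesion": row["lesion"],
            "accuracy": total_accuracy(cm),
            "weighted_iou": weighted_iou(cm),
        }
        for k in LABELS:
            rec[f"iou_{LABEL_NAMES[k].lower()}"] = class_iou(cm, k)
        records.append(rec)
    table = pd.DataFrame(records)
    summary = {"split": split, "n_images": len(table)}
    for metric in ["accuracy", "weighted_iou"] + [
        f"iou_{LABEL_NAMES[k].lower()}" for k in LABELS
    ]:
        mean, sd = _aggregate(table[metric].to_numpy(dtype=float))
        summary[f"{metric}_mean"] = mean
        summary[f"{metric}_sd"] = sd
    summary["pooled_accuracy"] = total_accuracy(pooled)
    summary["pooled_weighted_iou"] = weighted_iou(pooled)
    return EvalReport(split=split, per_image=table, summary=summary)
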