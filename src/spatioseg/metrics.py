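"""Segmentation evaluation: overlap metrics (IoU, Dice, F1) and HD95.

Overlap metrics are computed per class from the pixel confusion counts; the
95th-percentile Hausdorff distance (HD95) measures boundary agreement as the
95th percentile of the pooled bidirectional boundary-to-boundary Euclidean
distances, in pixels.  ``evaluate_dataset`` aggregates per image, then over
classes, then over images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "overlap_metrics",
    "boundary_pixels",
    "hd95",
    "MetricReport",
    "evaluate_dataset",
]

# 8-connectivity structuring element for boundary extraction
_STRUCT8 = np.ones((3, 3), dtype=bool)


def _check_mask(mask: np.ndarray, num_classes: int, name: str) -> np.ndarray:
    mask = np.asarray(mask)
    if not np.issubdtype(mask.dtype, np.integer):
        raise TypeError(f"{name} mask must be integer-typed, got {mask.dtype}")
    if mask.size and (mask.min() < 0 or mask.max() >= num_classes):
        raise ValueError(f"{name} labels outside [0, {num_classes})")
    return mask


def overlap_metrics(pred: np.ndarray, truth: np.ndarray, num_classes: int):
    """Per-class IoU, Dice and pixel-level F1 from confusion counts.

    ``IoU = TP/(TP+FP+FN)``, ``DSC = 2TP/(2TP+FP+FN)``; F1 is computed from
    pixel precision and recall, which at pixel level is algebraically the same
    quantity as DSC.  A class empty in both masks scores 1 by convention.
    Returns three arrays of length ``num_classes``.
    """
    pred = _check_mask(pred, num_classes, "pred")
    truth = _check_mask(truth, num_classes, "truth")
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    cm = np.bincount(
        truth.ravel() * num_classes + pred.ravel(), minlength=num_classes**2
    ).reshape(num_classes, num_classes)
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        iou = tp / (tp + fp + fn)
        dsc = 2 * tp / (2 * tp + fp + fn)
        prec = tp / (tp + fp)
        rec = tp / (tp + fn)
        f1 = 2 * prec * rec / (prec + rec)
    empty_both = (tp + fp + fn) == 0
    iou[empty_both] = 1.0
    dsc[empty_both] = 1.0
    # F1 is NaN when precision+recall is 0 (no overlap) -> score 0; empty-both -> 1
    f1 = np.where(np.isnan(f1), 0.0, f1)
    f1[empty_both] = 1.0
    return iou, dsc, f1


def boundary_pixels(region: np.ndarray) -> np.ndarray:
    """Boundary of a boolean region: pixels removed by 8-connected erosion.

    Pixels on the image border count as boundary (the outside is background).
    Returns an (M, 2) array of (row, col) coordinates.
    """
    region = np.asarray(region, dtype=bool)
    eroded = ndimage.binary_erosion(region, structure=_STRUCT8, border_value=0)
    return np.argwhere(region & ~eroded)


def hd95(pred_region: np.ndarray, truth_region: np.ndarray) -> float:
    """95th-percentile symmetric boundary distance between two regions, in pixels.

    Boundary pixels of each region are extracted by erosion difference; the
    Euclidean distance from every boundary pixel of one region to the nearest
    boundary pixel of the other is collected in both directions, pooled, and
    the 95th percentile taken with linear interpolation between order
    statistics.  Returns ``nan`` when either region is empty (undefined).
    """
    a = boundary_pixels(pred_region)
    b = boundary_pixels(truth_region)
    if len(a) == 0 or len(b) == 0:
        return float("nan")
    shape = np.asarray(pred_region).shape
    d_ab = _directed_distances(a, b, shape)
    d_ba = _directed_distances(b, a, shape)
    pooled = np.concatenate([d_ab, d_ba])
    return float(np.percentile(pooled, 95, method="linear"))


def _directed_distances(src: np.ndarray, dst: np.ndarray, shape) -> np.ndarray:
    """Distance from each src pixel to the nearest dst pixel (exact Euclidean EDT)."""
    target = np.ones(shape, dtype=bool)
    target[tuple(dst.T)] = False
    edt = ndimage.distance_transform_edt(target)
    return edt[tuple(src.T)]


@dataclass
class MetricReport:
    """Per-class and mean overlap/boundary metrics for an evaluated set."""

    per_class_iou: np.ndarray
    per_class_dsc: np.ndarray
    per_class_f1: np.ndarray
    per_class_hd95: np.ndarray
    mean_iou: float
    mean_dsc: float
    mean_f1: float
    mean_hd95: float
    n_images: int
    n_undefined_hd95: int = 0
    mean_prediction_time: float | None = None
    per_image: pd.DataFrame | None = field(default=None, repr=False)

    def to_json(self, path=None) -> str:
        payload = {
            "per_class_iou": self.per_class_iou.tolist(),
            "per_class_dsc": self.per_class_dsc.tolist(),
            "per_class_f1": self.per_class_f1.tolist(),
            "per_class_hd95": self.per_class_hd95.tolist(),
            "mean_iou": self.mean_iou,
            "mean_dsc": self.mean_dsc,
            "mean_f1": self.mean_f1,
            "mean_hd95": self.mean_hd95,
            "n_images": self.n_images,
            "n_undefined_hd95": self.n_undefined_hd95,
            "mean_prediction_time": self.mean_prediction_time,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_csv(self, path) -> None:
        """One row per image per class, plus per-class and overall summary rows."""
        frames = []
        if self.per_image is not None:
            frames.append(self.per_image)
        C = len(self.per_class_iou)
        summary = pd.DataFrame(
            {
                "image": ["summary"] * C,
                "class": list(range(C)),
                "iou": self.per_class_iou,
                "dsc": self.per_class_dsc,
                "f1": self.per_class_f1,
                "hd95": self.per_class_hd95,
            }
        )
        overall = pd.DataFrame(
            {
                "image": ["overall"],
                "class": ["mean"],
                "iou": [self.mean_iou],
                "dsc": [self.mean_dsc],
                "f1": [self.mean_f1],
                "hd95": [self.mean_hd95],
            }
        )
        frames += [summary, overall]
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def evaluate_dataset(
    preds: list[np.ndarray],
    truths: list[np.ndarray],
    num_classes: int = 4,
    timings: list[float] | None = None,
) -> MetricReport:
    """Aggregate metrics: per image per class, mean over classes, mean over images.

    Undefined HD95 values (a class empty in either mask) are excluded from
    the means; their count is reported.
    """
    if len(preds) != len(truths):
        raise ValueError(f"got {len(preds)} predictions for {len(truths)} truths")
    if not preds:
        raise ValueError("empty evaluation set")
    rows = []
    per_image_class_iou = np.zeros((len(preds), num_classes))
    per_image_class_dsc = np.zeros_like(per_image_class_iou)
    per_image_class_f1 = np.zeros_like(per_image_class_iou)
    per_image_class_hd = np.full((len(preds), num_classes), np.nan)
    for i, (p, t) in enumerate(zip(preds, truths)):
        iou, dsc, f1 = overlap_metrics(p, t, num_classes)
        per_image_class_iou[i] = iou
        per_image_class_dsc[i] = dsc
        per_image_class_f1[i] = f1
        for c in range(num_classes):
            per_image_class_hd[i, c] = hd95(p == c, t == c)
            rows.append(
                {"image": i, "class": c, "iou": iou[c], "dsc": dsc[c],
                 "f1": f1[c], "hd95": per_image_class_hd[i, c]}
            )
    import warnings

    per_class_iou = per_image_class_iou.mean(axis=0)
    per_class_dsc = per_image_class_dsc.mean(axis=0)
    per_class_f1 = per_image_class_f1.mean(axis=0)
    with warnings.catch_warnings():
        # a class undefined in every image legitimately averages to NaN
        warnings.simplefilter("ignore", category=RuntimeWarning)
        per_class_hd = np.nanmean(per_image_class_hd, axis=0)
        # per-image mean over classes, then mean over images
        image_mean_hd = np.nanmean(per_image_class_hd, axis=1)
    n_undef = int(np.isnan(per_image_class_hd).sum())
    return MetricReport(
        per_class_iou=per_class_iou,
        per_class_dsc=per_class_dsc,
        per_class_f1=per_class_f1,
        per_class_hd95=per_class_hd,
        mean_iou=float(per_image_class_iou.mean(axis=1).mean()),
        mean_dsc=float(per_image_class_dsc.mean(axis=1).mean()),
        mean_f1=float(per_image_class_f1.mean(axis=1).mean()),
        mean_hd95=float(np.nanmean(image_mean_hd)),
        n_images=len(preds),
        n_undefined_hd95=n_undef,
        mean_prediction_time=(float(np.mean(timings)) if timings else None),
        per_image=pd.DataFrame(rows),
    )
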