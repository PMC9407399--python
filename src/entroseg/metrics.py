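"""Segmentation evaluation: Dice, IoU, recall, precision, F2, mAP, HD95.

Overlap metrics follow the usual conventions with an explicit both-empty
rule: a prediction that correctly finds nothing scores 1 (logged by callers
so aggregates are not silently inflated).  The 95th-percentile Hausdorff
distance is computed between mask boundaries in physical units (voxel
spacing in mm), symmetrised by the max of the two directed distances; it is
undefined (raises) when either mask is empty.  mAP is the mean of the exact
average precision of the foreground class and of the background class
(probabilities and labels inverted), using every unique probability value as
a threshold.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from sklearn.metrics import average_precision_score


def _counts(pred: np.ndarray, gt: np.ndarray) -> tuple[int, int, int]:
    pred = np.asarray(pred).astype(bool)
    gt = np.asarray(gt).astype(bool)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    tp = int((pred & gt).sum())
    fp = int((pred & ~gt).sum())
    fn = int((~pred & gt).sum())
    return tp, fp, fn


def dice(pred: np.ndarray, gt: np.ndarray) -> float:
    """2|A∩B| / (|A|+|B|); 1 when both masks are empty."""
    tp, fp, fn = _counts(pred, gt)
    denom = 2 * tp + fp + fn
    return 1.0 if denom == 0 else 2.0 * tp / denom


def iou(pred: np.ndarray, gt: np.ndarray) -> float:
    """|A∩B| / |A∪B|; 1 when both masks are empty."""
    tp, fp, fn = _counts(pred, gt)
    union = tp + fp + fn
    return 1.0 if union == 0 else tp / union


def recall(pred: np.ndarray, gt: np.ndarray) -> float:
    """TP / (TP+FN); 1 when the ground truth is empty."""
    tp, _, fn = _counts(pred, gt)
    return 1.0 if tp + fn == 0 else tp / (tp + fn)


def precision(pred: np.ndarray, gt: np.ndarray) -> float:
    """TP / (TP+FP); 1 when the prediction is empty."""
    tp, fp, _ = _counts(pred, gt)
    return 1.0 if tp + fp == 0 else tp / (tp + fp)


def f2(pred: np.ndarray, gt: np.ndarray) -> float:
    """F2 = 5PR / (4P + R), weighting recall over precision."""
    p = precision(pred, gt)
    r = recall(pred, gt)
    return 0.0 if p == 0 and r == 0 else 5.0 * p * r / (4.0 * p + r)


def map_score(prob: np.ndarray, gt: np.ndarray) -> float:
    """Mean of foreground and background average precision (exact PR curves)."""
    prob = np.asarray(prob, dtype=np.float64).ravel()
    gt = np.asarray(gt).astype(bool).ravel()
    if prob.shape != gt.shape:
        raise ValueError("probability map and ground truth differ in size")
    aps = []
    for scores, labels in ((prob, gt), (1.0 - prob, ~gt)):
        if labels.any():
            aps.append(float(average_precision_score(labels, scores)))
        else:
            aps.append(1.0)  # no positives of this class to retrieve
    return float(np.mean(aps))


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Coordinates of boundary voxels (mask minus its erosion)."""
    mask = np.asarray(mask).astype(bool)
    inner = ndimage.binary_erosion(mask, border_value=0)
    return np.argwhere(mask & ~inner)


def hausdorff95(pred: np.ndarray, gt: np.ndarray, spacing_mm: float = 0.5) -> float:
    """Symmetrised 95th-percentile boundary distance in millimetres.

    Directed distances are the nearest-neighbour distances from each boundary
    voxel of one mask to the other mask's boundary; the 95th percentile
    (linear interpolation) of each direction is taken and the two are
    symmetrised by max.  Raises ValueError when either mask is empty.
    """
    pred_b = _boundary(pred)
    gt_b = _boundary(gt)
    if len(pred_b) == 0 or len(gt_b) == 0:
        raise ValueError("hausdorff95 undefined for empty masks")
    d_pg = cKDTree(gt_b).query(pred_b)[0]
    d_gp = cKDTree(pred_b).query(gt_b)[0]
    h = max(np.percentile(d_pg, 95), np.percentile(d_gp, 95))
    return float(h * spacing_mm)


@dataclasses.dataclass
class EvalReport:
    """Aggregate metrics plus a per-sample table (one row per volume)."""

    dice: float
    iou: float
    recall: float
    precision: float
    f2: float
    map_score: float
    hausdorff95_mm: float | None  # None if undefined for every sample
    n_hd_undefined: int
    per_sample: pd.DataFrame

    def to_csv(self, path) -> None:
        agg = pd.DataFrame(
            [
                {
                    "sample": "aggregate",
                    "dice": self.dice,
                    "iou": self.iou,
                    "recall": self.recall,
                    "precision": self.precision,
                    "f2": self.f2,
                    "map": self.map_score,
                    "hd95_mm": self.hausdorff95_mm,
                }
            ]
        )
        pd.concat([self.per_sample, agg], ignore_index=True).to_csv(path, index=False)


def evaluate(
    preds: list[np.ndarray],
    gts: list[np.ndarray],
    probs: list[np.ndarray] | None = None,
    spacing_mm: float = 0.5,
    sample_ids: list[str] | None = None,
) -> EvalReport:
    """Per-volume metrics and their mean.

    `preds`/`gts` are binary volumes; `probs` (optional, same shapes) feed
    mAP — when absent, the binary prediction is used as the score map.
    Samples where HD95 is undefined (an empty mask) are excluded from the
    HD95 aggregate and counted in ``n_hd_undefined``.
    """
    if len(preds) != len(gts):
        raise ValueError("preds and gts must have the same length")
    probs = probs if probs is not None else [np.asarray(p, dtype=float) for p in preds]
    sample_ids = sample_ids or [f"vol{i}" for i in range(len(preds))]
    rows = []
    n_hd_undef = 0
    for sid, pred, gt, prob in zip(sample_ids, preds, gts, probs):
        try:
            hd = hausdorff95(pred, gt, spacing_mm)
        except ValueError:
            hd = np.nan
            n_hd_undef += 1
        rows.append(
            {
                "sample": sid,
                "dice": dice(pred, gt),
                "iou": iou(pred, gt),
                "recall": recall(pred, gt),
                "precision": precision(pred, gt),
                "f2": f2(pred, gt),
                "map": map_score(prob, gt),
                "hd95_mm": hd,
            }
        )
    table = pd.DataFrame(rows)
    hd_vals = table["hd95_mm"].dropna()
    return EvalReport(
        dice=float(table["dice"].mean()),
        iou=float(table["iou"].mean()),
        recall=float(table["recall"].mean()),
        precision=float(table["precision"].mean()),
        f2=float(table["f2"].mean()),
        map_score=float(table["map"].mean()),
        hausdorff95_mm=float(hd_vals.mean()) if len(hd_vals) else None,
        n_hd_undefined=n_hd_undef,
        per_sample=table,
    )
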