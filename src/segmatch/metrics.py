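"""Evaluation metrics: Dice, Normalized Surface Dice, and the IoU family.

Boundary convention for NSD: a foreground pixel is a boundary pixel when at
least one of its 4-neighbours is background, with the image border counting
as background; distances are Euclidean between pixel centres. Empty-mask
conventions: a metric is 1 when both masks are empty and 0 when exactly one
is.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.ndimage import distance_transform_edt

from segmatch.errors import DataError

#: NSD tolerance, in pixels, at the native resolution the default was
#: calibrated for (inter-rater variability at width 512).
NATIVE_NSD_TOLERANCE = 13.0
NATIVE_WIDTH = 512


def scaled_tolerance(width: int) -> float:
    """Scale the native NSD tolerance proportionally to image width."""
    return max(1.0, round(NATIVE_NSD_TOLERANCE * width / NATIVE_WIDTH))


@dataclass
class MetricReport:
    dice: float
    nsd: float
    tolerance: float
    ch_iou: float
    isi_iou: float
    mc_iou: float
    per_class_iou: Dict[int, float] = field(default_factory=dict)

    def to_dict(self) -> Dict:
        return {"dice": self.dice, "nsd": self.nsd, "tolerance": self.tolerance,
                "ch_iou": self.ch_iou, "isi_iou": self.isi_iou,
                "mc_iou": self.mc_iou,
                "per_class_iou": {str(k): v for k, v in self.per_class_iou.items()}}


def dice_score(pred: np.ndarray, gt: np.ndarray, cls: int = 1) -> float:
    """Dice overlap of class ``cls``: 2|P∩G| / (|P| + |G|); 1 if both empty."""
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise DataError(f"shape mismatch {pred.shape} vs {gt.shape}")
    p = pred == cls
    g = gt == cls
    denom = int(p.sum()) + int(g.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((p & g).sum()) / denom


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Foreground pixels with at least one non-foreground 4-neighbour
    (image border counts as non-foreground)."""
    m = np.asarray(mask).astype(bool, copy=False)
    padded = np.zeros((m.shape[0] + 2, m.shape[1] + 2), dtype=bool)
    padded[1:-1, 1:-1] = m
    interior = (padded[:-2, 1:-1] & padded[2:, 1:-1]
                & padded[1:-1, :-2] & padded[1:-1, 2:])
    return m & ~interior


def nsd_score(pred: np.ndarray, gt: np.ndarray, tau: float) -> float:
    """Normalized Surface Dice at pixel tolerance ``tau``.

    Fraction of boundary pixels of each mask lying within Euclidean
    distance ``tau`` of the other mask's boundary.
    """
    if tau < 0:
        raise DataError("tolerance must be >= 0")
    p = np.asarray(pred) != 0
    g = np.asarray(gt) != 0
    if p.shape != g.shape:
        raise DataError(f"shape mismatch {p.shape} vs {g.shape}")
    p_any, g_any = bool(p.any()), bool(g.any())
    if not p_any and not g_any:
        return 1.0
    if p_any != g_any:
        return 0.0
    bp = boundary_pixels(p)
    bg = boundary_pixels(g)
    dist_to_bg = distance_transform_edt(~bg)
    dist_to_bp = distance_transform_edt(~bp)
    hits = int((dist_to_bg[bp] <= tau).sum()) + int((dist_to_bp[bg] <= tau).sum())
    return hits / (int(bp.sum()) + int(bg.sum()))


def _class_iou(pred: np.ndarray, gt: np.ndarray, cls: int) -> float:
    p = pred == cls
    g = gt == cls
    union = int((p | g).sum())
    if union == 0:
        return 1.0
    return int((p & g).sum()) / union


def multiclass_iou_report(preds: Sequence[np.ndarray],
                          gts: Sequence[np.ndarray],
                          n_classes: int,
                          ) -> Tuple[float, float, float, Dict[int, float]]:
    """Image-averaged IoU statistics over non-background classes.

    Per image, the first value averages IoU over classes present in that
    image's ground truth; the second over classes present in the ground
    truth or the prediction (spurious predicted classes count with their
    actual, typically zero, IoU). The third swaps the averaging order:
    per-class IoU averaged over the images where the class appears, then
    averaged over classes.
    """
    if len(preds) != len(gts):
        raise DataError("pred/gt list lengths differ")
    ch_vals: List[float] = []
    isi_vals: List[float] = []
    class_vals: Dict[int, List[float]] = {c: [] for c in range(1, n_classes)}
    for pred, gt in zip(preds, gts):
        pred = np.asarray(pred)
        gt = np.asarray(gt)
        if pred.shape != gt.shape:
            raise DataError("pred/gt shape mismatch")
        gt_classes = [c for c in range(1, n_classes) if np.any(gt == c)]
        all_classes = [c for c in range(1, n_classes)
                       if np.any(gt == c) or np.any(pred == c)]
        ious = {c: _class_iou(pred, gt, c) for c in all_classes}
        if gt_classes:
            ch_vals.append(float(np.mean([ious[c] for c in gt_classes])))
        if all_classes:
            isi_vals.append(float(np.mean([ious[c] for c in all_classes])))
        for c in all_classes:
            class_vals[c].append(ious[c])
    per_class = {c: float(np.mean(v)) for c, v in class_vals.items() if v}
    ch_iou = float(np.mean(ch_vals)) if ch_vals else 1.0
    isi_iou = float(np.mean(isi_vals)) if isi_vals else 1.0
    mc_iou = float(np.mean(list(per_class.values()))) if per_class else 1.0
    return ch_iou, isi_iou, mc_iou, per_class


def predict_masks(model, images: Sequence[np.ndarray],
                  batch_size: int = 8) -> List[np.ndarray]:
    """Hard per-pixel argmax predictions in evaluation mode."""
    out: List[np.ndarray] = []
    for start in range(0, len(images), batch_size):
        batch = np.stack(images[start:start + batch_size])
        logits = model.forward(batch, train=False)
        out.extend(np.argmax(logits, axis=-1).astype(np.int64))
    return out


def evaluate(model, test_set: Sequence[Tuple[np.ndarray, np.ndarray]],
             tolerance: float | None = None) -> MetricReport:
    """Full metric report on (image, mask) pairs.

    Dice and NSD are computed on the foreground-vs-background binarization
    (background excluded); the IoU family covers individual classes.
    """
    images = [img for img, _ in test_set]
    gts = [mask for _, mask in test_set]
    if tolerance is None:
        tolerance = scaled_tolerance(images[0].shape[1])
    preds = predict_masks(model, images)
    dice = float(np.mean([dice_score(p != 0, g != 0, cls=True)
                          for p, g in zip(preds, gts)]))
    nsd = float(np.mean([nsd_score(p, g, tolerance)
                         for p, g in zip(preds, gts)]))
    n_classes = model.cfg.n_classes
    ch_iou, isi_iou, mc_iou, per_class = multiclass_iou_report(preds, gts, n_classes)
    return MetricReport(dice=dice, nsd=nsd, tolerance=float(tolerance),
                        ch_iou=ch_iou, isi_iou=isi_iou, mc_iou=mc_iou,
                        per_class_iou=per_class)
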