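"""Segmentation metrics (Dice / Sen / BACC) and Grad-CAM visualization.

Metrics are computed from hard confusion counts at a probability threshold,
restricted to the valid field-of-view region when one is given:

    Dice = 2·TP / (2·TP + FP + FN)
    Sen  = TPR = TP / (TP + FN)
    TNR  = TN / (FP + TN)
    BACC = (TPR + TNR) / 2

Degenerate conventions (empty mask and/or empty prediction count as perfect
and are flagged): Sen = 1 when TP+FN = 0; Dice = 1 when 2TP+FP+FN = 0;
TNR = 1 when FP+TN = 0.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .imaging import resize_array
from .segnet import SegModel, segment_patch


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(probability: np.ndarray, mask: np.ndarray, threshold: float = 0.5,
              valid_mask: np.ndarray | None = None) -> ConfusionCounts:
    """Hard counts of prediction = (probability >= threshold) against mask."""
    probability = np.asarray(probability)
    mask = np.asarray(mask)
    if probability.shape != mask.shape:
        raise ValueError(f"shape mismatch: {probability.shape} vs {mask.shape}")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary")
    pred = probability >= threshold
    gt = mask.astype(bool)
    if valid_mask is not None:
        valid = np.asarray(valid_mask).astype(bool)
        if valid.shape != mask.shape:
            raise ValueError("valid_mask shape mismatch")
        if not valid.any():
            raise ValueError("empty valid region: nothing to evaluate")
        pred, gt = pred[valid], gt[valid]
    return ConfusionCounts(
        tp=int(np.count_nonzero(pred & gt)),
        fp=int(np.count_nonzero(pred & ~gt)),
        tn=int(np.count_nonzero(~pred & ~gt)),
        fn=int(np.count_nonzero(~pred & gt)),
    )


def metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Dice / Sen / TPR / TNR / BACC from confusion counts."""
    degenerate = []
    if 2 * counts.tp + counts.fp + counts.fn == 0:
        dice = 1.0
        degenerate.append("dice")
    else:
        dice = 2.0 * counts.tp / (2.0 * counts.tp + counts.fp + counts.fn)
    if counts.tp + counts.fn == 0:
        sen = 1.0
        degenerate.append("sen")
    else:
        sen = counts.tp / (counts.tp + counts.fn)
    if counts.fp + counts.tn == 0:
        tnr = 1.0
        degenerate.append("tnr")
    else:
        tnr = counts.tn / (counts.fp + counts.tn)
    return {"dice": dice, "sen": sen, "tpr": sen, "tnr": tnr,
            "bacc": (sen + tnr) / 2.0, "degenerate": degenerate}


@dataclass
class MetricsReport:
    per_image: list[dict] = field(default_factory=list)

    METRIC_KEYS = ("dice", "sen", "tpr", "tnr", "bacc")

    def aggregate(self) -> dict[str, tuple[float, float]]:
        """mean ± std (population std, matching the per-image list moments)."""
        agg = {}
        for k in self.METRIC_KEYS:
            vals = np.array([row[k] for row in self.per_image])
            agg[k] = (float(vals.mean()), float(vals.std()))
        return agg

    def to_json(self) -> str:
        return json.dumps({"per_image": self.per_image,
                           "aggregate": {k: list(v) for k, v in self.aggregate().items()}})

    def to_csv(self, path: str | Path) -> None:
        keys = ["id", *self.METRIC_KEYS]
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=keys)
            writer.writeheader()
            for row in self.per_image:
                writer.writerow({k: row.get(k, "") for k in keys})


def evaluate_images(predictions: list[np.ndarray], masks: list[np.ndarray],
                    valid_masks: list[np.ndarray | None] | None = None,
                    threshold: float = 0.5, ids: list[str] | None = None) -> MetricsReport:
    """Per-image metrics + mean ± std aggregate over a stitched test set."""
    valid_masks = valid_masks or [None] * len(predictions)
    ids = ids or [f"{i:04d}" for i in range(len(predictions))]
    report = MetricsReport()
    for pid, prob, mask, valid in zip(ids, predictions, masks, valid_masks):
        counts = confusion(prob, mask, threshold=threshold, valid_mask=valid)
        row = metrics(counts)
        row.update(id=pid, tp=counts.tp, fp=counts.fp, tn=counts.tn, fn=counts.fn)
        report.per_image.append(row)
    return report


# ---------------------------------------------------------------------------
# Grad-CAM
# ---------------------------------------------------------------------------

def gradcam_from(activation_grad: np.ndarray, activation: np.ndarray) -> np.ndarray:
    """Core Grad-CAM arithmetic on one sample's (C,H,W) activation/gradient.

    Channel weights are the spatial means of the gradients; the heatmap is
    the rectified weighted activation sum, min-max normalized to [0, 1]
    (all-zero map when the target produced no gradient)."""
    weights = activation_grad.mean(axis=(1, 2))
    cam = np.maximum((weights[:, None, None] * activation).sum(axis=0), 0.0)
    peak = cam.max()
    if peak > 0:
        lo = cam.min()
        cam = (cam - lo) / (peak - lo) if peak > lo else cam / peak
    return cam


def gradcam_map(model: SegModel, triplet, z2=None,
                target_layer: str = "decoder_final") -> np.ndarray:
    """Grad-CAM of the summed segmentation logits at a named decoder layer,
    resized to the input patch size."""
    out = segment_patch(triplet, z2, model, capture=(target_layer,))
    if target_layer not in out.captures:
        raise KeyError(f"layer {target_layer!r} not found in decoder captures")
    act = out.captures[target_layer]
    out.final_logits.sum().backward()
    if act.grad is None:
        grad = np.zeros_like(act.data)
    else:
        grad = act.grad
    cam = gradcam_from(grad[0], act.data[0])
    side = np.asarray(triplet.small if hasattr(triplet, "small") else triplet[0]).shape[-1]
    return resize_array(cam.astype(np.float32), side)
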