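"""Segmentation evaluation: confusion counts, overlap rates, Hausdorff distance.

Rates follow the usual pixel-confusion definitions:

    dice = 2TP/(2TP+FP+FN)   iou = TP/(TP+FP+FN)
    sen = recall = TP/(TP+FN)   spc = TN/(TN+FP)   precision = TP/(TP+FP)

Degenerate denominators are resolved by the both-empty convention: an overlap
rate whose denominator vanishes is 1 when both masks agree on emptiness
(nothing to find, nothing found) and 0 otherwise.

The Hausdorff distance is the full symmetric boundary-to-boundary maximum of
nearest-neighbour Euclidean distances, reported as a percentage of the image
diagonal so that values are comparable across image sizes.  If exactly one
mask is empty the distance is reported as 100 (the whole diagonal); if both
are empty it is 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree


@dataclass(frozen=True)
class Confusion:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _check_binary(a, name):
    a = np.asarray(a)
    if a.dtype != bool and not np.isin(a, (0, 1)).all():
        raise ValueError(f"{name} must be binary")
    return a.astype(bool)


def confusion(pred_mask, true_mask) -> Confusion:
    """Exact pixel confusion counts between two binary masks."""
    pred = _check_binary(pred_mask, "pred_mask")
    true = _check_binary(true_mask, "true_mask")
    if pred.shape != true.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {true.shape}")
    tp = int(np.count_nonzero(pred & true))
    fp = int(np.count_nonzero(pred & ~true))
    fn = int(np.count_nonzero(~pred & true))
    tn = int(np.count_nonzero(~pred & ~true))
    return Confusion(tp, fp, fn, tn)


def _rate(num: int, den: int, empty_agree: bool) -> float:
    if den == 0:
        return 1.0 if empty_agree else 0.0
    return num / den


def rates(c: Confusion) -> dict[str, float]:
    """Overlap and classification rates from a confusion table."""
    both_empty = (c.tp + c.fp + c.fn) == 0
    sen = _rate(c.tp, c.tp + c.fn, both_empty)
    return {
        "dice": _rate(2 * c.tp, 2 * c.tp + c.fp + c.fn, both_empty),
        "iou": _rate(c.tp, c.tp + c.fp + c.fn, both_empty),
        "sen": sen,
        "recall": sen,
        "spc": _rate(c.tn, c.tn + c.fp, c.tn + c.fp == 0),
        "precision": _rate(c.tp, c.tp + c.fp, both_empty),
    }


def _boundary_points(mask: np.ndarray) -> np.ndarray:
    """(row, col) coordinates of foreground pixels on the mask boundary."""
    eroded = ndimage.binary_erosion(mask, structure=np.ones((3, 3)), border_value=0)
    return np.argwhere(mask & ~eroded)


def hausdorff_pct(mask_a, mask_b, image_shape=None) -> float:
    """Symmetric Hausdorff distance between mask boundaries, % of diagonal."""
    a = _check_binary(mask_a, "mask_a")
    b = _check_binary(mask_b, "mask_b")
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    empty_a, empty_b = not a.any(), not b.any()
    if empty_a and empty_b:
        return 0.0
    if empty_a or empty_b:
        return 100.0
    pa, pb = _boundary_points(a), _boundary_points(b)
    d_ab = cKDTree(pb).query(pa)[0].max()
    d_ba = cKDTree(pa).query(pb)[0].max()
    shape = image_shape or a.shape
    diagonal = float(np.hypot(shape[0], shape[1]))
    return 100.0 * float(max(d_ab, d_ba)) / diagonal


@dataclass
class MetricsReport:
    """Per-image rows plus aggregate means over a dataset."""

    ids: list[str] = field(default_factory=list)
    rows: list[dict[str, float]] = field(default_factory=list)
    confusion_total: Confusion = Confusion(0, 0, 0, 0)

    METRIC_KEYS = ("dice", "iou", "sen", "spc", "precision", "recall", "hd_pct")

    def add(self, sample_id: str, pred_mask, true_mask):
        c = confusion(pred_mask, true_mask)
        row = rates(c)
        row["hd_pct"] = hausdorff_pct(pred_mask, true_mask)
        self.ids.append(sample_id)
        self.rows.append(row)
        t = self.confusion_total
        self.confusion_total = Confusion(t.tp + c.tp, t.fp + c.fp,
                                         t.fn + c.fn, t.tn + c.tn)

    def mean(self) -> dict[str, float]:
        if not self.rows:
            return {k: float("nan") for k in self.METRIC_KEYS}
        return {k: float(np.mean([r[k] for r in self.rows])) for k in self.METRIC_KEYS}

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.rows, index=self.ids)
        df.index.name = "id"
        mean_row = pd.DataFrame([self.mean()], index=["mean"])
        mean_row.index.name = "id"
        return pd.concat([df, mean_row])


def predict_mask(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a foreground-probability map into a binary mask."""
    return np.asarray(prob) >= threshold
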