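"""Pixel-level evaluation against hand-labeled ground truth.

Segmentation quality is summarized by the confusion counts and

    sensitivity = TP / (TP + FN)      (vessel pixels found)
    specificity = TN / (TN + FP)      (background pixels kept)
    accuracy    = (TP + TN) / (TP + TN + FP + FN)

computed over the pixels inside the field of view by default —
outside-FOV pixels are trivially true negatives and inflate accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["ConfusionCounts", "confusion", "aggregate"]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN and the derived rates."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def sensitivity(self) -> float | None:
        """TP / (TP + FN); None when the truth has no vessel pixels."""
        denom = self.tp + self.fn
        return self.tp / denom if denom else None

    @property
    def specificity(self) -> float | None:
        denom = self.tn + self.fp
        return self.tn / denom if denom else None

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
        }


def confusion(
    pred: np.ndarray,
    truth: np.ndarray,
    fov: np.ndarray | None = None,
) -> ConfusionCounts:
    """Confusion counts of a predicted vessel map against ground truth.

    Only pixels inside ``fov`` are counted when a mask is given.  If
    the truth contains no vessel pixel in the evaluated region the
    sensitivity is undefined (reported as None, with a warning here).
    """
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must share a shape")
    if fov is not None:
        fov = np.asarray(fov, dtype=bool)
        if fov.shape != pred.shape:
            raise ValueError("fov must share the prediction's shape")
        pred, truth = pred[fov], truth[fov]
    tp = int(np.count_nonzero(pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    if tp + fn == 0:
        warnings.warn(
            "ground truth has no vessel pixels in the evaluated region; "
            "sensitivity is undefined", stacklevel=2,
        )
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def aggregate(results: list[ConfusionCounts]) -> dict:
    """Unweighted per-image means of the three rates.

    Images whose sensitivity (or specificity) is undefined are left out
    of that rate's mean only.
    """
    if not results:
        raise ValueError("aggregate requires a nonempty list")
    out = {"n_images": len(results)}
    for rate in ("sensitivity", "specificity", "accuracy"):
        values = [getattr(c, rate) for c in results]
        values = [v for v in values if v is not None]
        out[rate] = float(np.mean(values)) if values else None
    return out
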