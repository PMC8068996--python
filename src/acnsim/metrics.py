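"""Threshold binarization schemes and confusion-matrix metrics.

Foreground/background separation uses the mode-plus-deviations threshold

    p_thresd = p_mode + c * p_std        (default c = 2)

where ``p_mode`` is the most frequent 8-bit pixel value (capillaries occupy
a small fraction of a frame, so the mode is the background level) and
``p_std`` the population standard deviation of all pixels; pixels strictly
above the threshold are foreground.

Two schemes turn a stack of per-frame predictions into one en-face mask:

1. *Simple average*: average the frames, then threshold the mean image.
2. *Repeat counting*: threshold each frame separately, call a pixel a true
   signal when it is foreground in at least N frames, and give it the
   maximum intensity it attained across frames.  Larger N suppresses more
   randomly emerging noise at the cost of some true signal.

Segmentations are scored against ground truth with the standard confusion
counts and accuracy / precision / recall / F1; rates are reported
normalised within the positive class (TP, FN over TP+FN) and the negative
class (TN, FP over TN+FP).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ThresholdParams",
    "ConfusionCounts",
    "Metrics",
    "threshold_value",
    "binarize_foreground",
    "average_frames",
    "binarize_simple_average",
    "binarize_repeat_count",
    "confusion",
    "metrics",
    "f1_from_precision_recall",
]


@dataclass(frozen=True)
class ThresholdParams:
    c: float
    pmode: float
    pstd: float

    @property
    def pthresd(self) -> float:
        return self.pmode + self.c * self.pstd


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    # rates normalised within the GT-positive and GT-negative classes
    @property
    def tp_rate(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0

    @property
    def fn_rate(self) -> float:
        d = self.tp + self.fn
        return self.fn / d if d else 0.0

    @property
    def tn_rate(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else 0.0

    @property
    def fp_rate(self) -> float:
        d = self.tn + self.fp
        return self.fp / d if d else 0.0


@dataclass(frozen=True)
class Metrics:
    accuracy: float
    precision: float
    recall: float
    f1: float


def _as_8bit_values(image: np.ndarray) -> np.ndarray:
    """View an image on the 8-bit scale.

    uint8 passes through; other integer arrays must already lie in
    [0, 255]; floating images in [0, 1] are quantized to the 8-bit scale,
    floating images on the 8-bit scale (e.g. frame averages) are rounded.
    """
    a = np.asarray(image)
    if a.size == 0:
        raise ValueError("image is empty")
    if a.dtype == np.uint8:
        return a.astype(np.int64)
    if np.issubdtype(a.dtype, np.integer):
        if a.min() < 0 or a.max() > 255:
            raise ValueError("integer image values outside [0, 255]")
        return a.astype(np.int64)
    if a.min() < 0 or a.max() > 255:
        raise ValueError("image values outside the 8-bit range")
    if a.max() <= 1.0:
        a = a * 255.0
    return np.floor(a + 0.5).astype(np.int64)


def threshold_value(image: np.ndarray, c: float = 2.0) -> ThresholdParams:
    """Mode + c standard deviations of an image on the 8-bit scale.

    Ties between equally frequent values break toward the lowest value
    (the background is dark); the standard deviation is the population
    standard deviation of all pixels.
    """
    v = _as_8bit_values(image)
    counts = np.bincount(v.ravel(), minlength=256)
    pmode = int(np.argmax(counts))  # argmax takes the first (lowest) max
    pstd = float(v.std())
    return ThresholdParams(c=c, pmode=float(pmode), pstd=pstd)


def binarize_foreground(image: np.ndarray, c: float = 2.0) -> np.ndarray:
    """Foreground mask: pixels strictly above ``pmode + c * pstd``."""
    v = _as_8bit_values(image)
    return v > threshold_value(image, c).pthresd


def average_frames(stack: np.ndarray, group_size: int) -> np.ndarray:
    """Non-overlapping groupwise mean along the first (z) axis."""
    stack = np.asarray(stack)
    n = stack.shape[0]
    if group_size < 1 or n % group_size:
        raise ValueError(
            f"stack depth {n} is not divisible by group size {group_size}"
        )
    shape = (n // group_size, group_size) + stack.shape[1:]
    return stack.reshape(shape).mean(axis=1)


def binarize_simple_average(frames: np.ndarray, c: float = 2.0) -> np.ndarray:
    """Scheme 1: mean over all frames, then threshold the mean image."""
    frames = np.asarray(frames)
    if frames.ndim < 3 or frames.shape[0] < 1:
        raise ValueError("expected a non-empty (n, h, w) frame stack")
    mean = frames.astype(float).mean(axis=0)
    return binarize_foreground(mean, c)


def binarize_repeat_count(
    frames: np.ndarray, c: float = 2.0, n_repeat: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Scheme 2: per-frame thresholding, then repeat counting.

    A pixel enters the merged mask when it is foreground in at least
    ``n_repeat`` frames; its merged intensity is the maximum it attained
    over all frames (0 elsewhere), so the merged image is itself binarized
    by "value > 0".  Returns ``(mask, merged_intensity)``.
    """
    frames = np.asarray(frames)
    if frames.ndim < 3 or frames.shape[0] < 1:
        raise ValueError("expected a non-empty (n, h, w) frame stack")
    if n_repeat < 1:
        raise ValueError("n_repeat must be >= 1")
    per_frame = np.stack([binarize_foreground(f, c) for f in frames])
    count = per_frame.sum(axis=0)
    mask = count >= n_repeat
    merged = np.where(mask, frames.astype(float).max(axis=0), 0.0)
    return mask, merged


def confusion(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """2x2 confusion counts of a binary prediction against ground truth."""
    pred = np.asarray(pred).astype(bool)
    gt = np.asarray(gt).astype(bool)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    tp = int(np.count_nonzero(pred & gt))
    tn = int(np.count_nonzero(~pred & ~gt))
    fp = int(np.count_nonzero(pred & ~gt))
    fn = int(np.count_nonzero(~pred & gt))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both vanish)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def metrics(cc: ConfusionCounts) -> Metrics:
    """Accuracy, precision, recall and F1 with 0/0 -> 0 conventions."""
    total = cc.total
    accuracy = (cc.tp + cc.tn) / total if total else 0.0
    precision = cc.tp / (cc.tp + cc.fp) if (cc.tp + cc.fp) else 0.0
    recall = cc.tp / (cc.tp + cc.fn) if (cc.tp + cc.fn) else 0.0
    return Metrics(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1_from_precision_recall(precision, recall),
    )
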