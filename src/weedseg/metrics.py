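"""Per-class one-vs-rest confusion aggregation and segmentation metrics.

For each class c the pixels are scored one-vs-rest: TP (predicted c, truly
c), FP (predicted c, truly other), FN (truly c, predicted other), TN (rest).
Counts are summed over the whole image set *before* any ratio is formed, so
dataset metrics are ratios of dataset totals.  Metrics:

    precision = TP / (TP + FP)            recall = TP / (TP + FN)
    IOU       = TP / (TP + FP + FN)       F1 = 2 P R / (P + R)
    MIOU      = mean of per-class IOUs    IOU = F1 / (2 - F1)  (identity)

Zero-denominator convention: a class absent from both prediction and truth
(TP+FP+FN = 0) scores 1 in all four metrics; otherwise a metric whose own
denominator is zero scores 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_counts",
    "precision",
    "recall",
    "f1score",
    "iou",
    "miou",
    "f1_to_iou",
    "report_from_counts",
    "evaluate_dataset",
    "evaluate_predictions",
]


@dataclass
class ConfusionCounts:
    """Per-class one-vs-rest pixel counts; integer arrays of length K."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray

    @classmethod
    def zeros(cls, num_classes: int) -> "ConfusionCounts":
        z = lambda: np.zeros(num_classes, dtype=np.int64)
        return cls(z(), z(), z(), z())

    @classmethod
    def from_class_counts(cls, counts: dict[int, tuple[int, int, int, int]],
                          num_classes: int) -> "ConfusionCounts":
        """Build from a {class: (tp, fn, fp, tn)} mapping."""
        out = cls.zeros(num_classes)
        for c, (tp, fn, fp, tn) in counts.items():
            out.tp[c], out.fn[c], out.fp[c], out.tn[c] = tp, fn, fp, tn
        return out

    @property
    def num_classes(self) -> int:
        return len(self.tp)

    @property
    def total_pixels(self) -> int:
        return int(self.tp[0] + self.fp[0] + self.fn[0] + self.tn[0])

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)

    def validate(self) -> None:
        totals = self.tp + self.fp + self.fn + self.tn
        if len(set(totals.tolist())) > 1:
            raise ValueError("per-class totals disagree; counts are inconsistent")


def confusion_counts(pred: np.ndarray, truth: np.ndarray,
                     num_classes: int) -> ConfusionCounts:
    """One-vs-rest confusion counts for one prediction/truth mask pair."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    for name, arr in (("pred", pred), ("truth", truth)):
        if arr.min() < 0 or arr.max() >= num_classes:
            raise ValueError(
                f"{name} labels out of range [0, {num_classes}): "
                f"[{arr.min()}, {arr.max()}]")
    joint = np.bincount(truth.ravel() * num_classes + pred.ravel(),
                        minlength=num_classes * num_classes
                        ).reshape(num_classes, num_classes)
    tp = np.diag(joint).astype(np.int64)
    fp = joint.sum(axis=0) - tp          # predicted c but truly other
    fn = joint.sum(axis=1) - tp          # truly c but predicted other
    tn = joint.sum() - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)


def _ratio(num: int, den: int, counts: ConfusionCounts, cls: int) -> float:
    if counts.tp[cls] + counts.fp[cls] + counts.fn[cls] == 0:
        return 1.0  # class absent and never predicted
    return num / den if den else 0.0


def precision(c: ConfusionCounts, cls: int) -> float:
    return _ratio(int(c.tp[cls]), int(c.tp[cls] + c.fp[cls]), c, cls)


def recall(c: ConfusionCounts, cls: int) -> float:
    return _ratio(int(c.tp[cls]), int(c.tp[cls] + c.fn[cls]), c, cls)


def iou(c: ConfusionCounts, cls: int) -> float:
    return _ratio(int(c.tp[cls]), int(c.tp[cls] + c.fp[cls] + c.fn[cls]), c, cls)


def f1score(c: ConfusionCounts, cls: int) -> float:
    p, r = precision(c, cls), recall(c, cls)
    if c.tp[cls] + c.fp[cls] + c.fn[cls] == 0:
        return 1.0
    return 2 * p * r / (p + r) if p + r else 0.0


def f1_to_iou(f1: float) -> float:
    """The F1/IOU identity: IOU = F1 / (2 - F1), exact for one-vs-rest counts."""
    if not 0.0 <= f1 <= 1.0:
        raise ValueError(f"F1 must lie in [0, 1], got {f1}")
    return f1 / (2.0 - f1)


@dataclass
class MetricsReport:
    """Per-class metric suite plus the class-mean IOU."""

    class_names: tuple[str, ...]
    iou: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    counts: ConfusionCounts

    @property
    def miou(self) -> float:
        return float(np.mean(self.iou))

    def to_dict(self) -> dict:
        per_class = {
            name: {
                "iou": float(self.iou[i]),
                "precision": float(self.precision[i]),
                "recall": float(self.recall[i]),
                "f1": float(self.f1[i]),
                "tp": int(self.counts.tp[i]),
                "fp": int(self.counts.fp[i]),
                "fn": int(self.counts.fn[i]),
                "tn": int(self.counts.tn[i]),
            }
            for i, name in enumerate(self.class_names)
        }
        return {"per_class": per_class, "miou": self.miou,
                "total_pixels": self.counts.total_pixels}

    def summary(self) -> str:
        lines = [f"{'class':<12s}{'IOU':>8s}{'Prec':>8s}{'Rec':>8s}{'F1':>8s}"]
        for i, name in enumerate(self.class_names):
            lines.append(f"{name:<12s}{self.iou[i]:>8.4f}{self.precision[i]:>8.4f}"
                         f"{self.recall[i]:>8.4f}{self.f1[i]:>8.4f}")
        lines.append(f"MIOU {self.miou:.4f}")
        return "\n".join(lines)


DEFAULT_CLASS_NAMES = ("background", "crop", "weed")


def report_from_counts(counts: ConfusionCounts,
                       class_names: tuple[str, ...] = DEFAULT_CLASS_NAMES
                       ) -> MetricsReport:
    k = counts.num_classes
    if len(class_names) != k:
        class_names = tuple(f"class{i}" for i in range(k))
    return MetricsReport(
        class_names=class_names,
        iou=np.array([iou(counts, c) for c in range(k)]),
        precision=np.array([precision(counts, c) for c in range(k)]),
        recall=np.array([recall(counts, c) for c in range(k)]),
        f1=np.array([f1score(counts, c) for c in range(k)]),
        counts=counts,
    )


def miou(report: MetricsReport) -> float:
    return report.miou


def _upsample_labels_nearest(labels: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour resize of an integer label grid."""
    h, w = labels.shape
    th, tw = size
    rows = np.clip((np.arange(th) + 0.5) * h / th, 0, h - 1).astype(int)
    cols = np.clip((np.arange(tw) + 0.5) * w / tw, 0, w - 1).astype(int)
    return labels[np.ix_(rows, cols)]


def evaluate_predictions(pairs, num_classes: int = 3,
                         class_names: tuple[str, ...] = DEFAULT_CLASS_NAMES
                         ) -> MetricsReport:
    """Aggregate (pred_mask, truth_mask) pairs into one report.

    Counts are summed across the whole set first; predictions whose size
    differs from the truth mask are upsampled nearest-neighbour to the
    truth's native resolution.
    """
    total = ConfusionCounts.zeros(num_classes)
    n = 0
    for pred, truth in pairs:
        pred = np.asarray(pred)
        truth = np.asarray(truth)
        if pred.shape != truth.shape:
            pred = _upsample_labels_nearest(pred, truth.shape)
        total = total + confusion_counts(pred, truth, num_classes)
        n += 1
    if n == 0:
        raise ValueError("cannot evaluate an empty image set")
    return report_from_counts(total, class_names)


def evaluate_dataset(net, scenes,
                     class_names: tuple[str, ...] = DEFAULT_CLASS_NAMES
                     ) -> MetricsReport:
    """Run ``net`` on aligned (image, mask) pairs and report dataset metrics.

    ``scenes`` yields (image, mask) where image is (C, H, W) float and mask
    is (H, W) integer labels; per-pixel classes are the argmax over logits.
    """
    scenes = list(scenes)
    if not scenes:
        raise ValueError("cannot evaluate an empty image set")
    k = net.config.num_classes

    def prediction_pairs():
        for image, mask in scenes:
            pred = net.predict(np.asarray(image)[None])[0]
            yield pred, np.asarray(mask)

    return evaluate_predictions(prediction_pairs(), num_classes=k,
                                class_names=class_names)
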