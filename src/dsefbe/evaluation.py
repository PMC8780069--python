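"""Classification metrics and qualitative inspection.

Per-class metrics are computed from one-vs-rest reductions of the confusion
matrix:

    precision   = TP / (TP + FP)
    recall      = TP / (TP + FN)
    specificity = TN / (TN + FP)
    F1          = 2 · precision · recall / (precision + recall)
    accuracy    = (TP + TN) / (TP + TN + FP + FN)

Degenerate 0/0 cases (e.g. a class never predicted) return 0 and set a flag
rather than propagating NaN.  Multi-class AUC is the macro average of
one-vs-rest ROC areas with trapezoidal integration.  Class activation maps
use gradient weighting on the backbone's final convolutional output, since
the network head is not a plain GAP + FC stack.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.metrics import roc_curve, auc as sk_auc
from sklearn.preprocessing import label_binarize

__all__ = ["ClassMetrics", "MetricsReport", "confusion", "class_metrics",
           "macro_average", "accuracy", "roc_auc", "metrics_report", "cam"]


@dataclass
class ClassMetrics:
    precision: float
    recall: float
    specificity: float
    f1: float
    degenerate: bool = False


@dataclass
class MetricsReport:
    per_class: list
    macro: ClassMetrics
    accuracy: float
    auc: float | None
    confusion: np.ndarray


def confusion(actual, predicted, n_classes: int) -> np.ndarray:
    """Counts[i, j] = number of samples with actual class i predicted as j."""
    actual = np.asarray(actual, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if actual.size == 0:
        raise ValueError("empty label vectors")
    if actual.shape != predicted.shape:
        raise ValueError("label vectors differ in length")
    for name, v in (("actual", actual), ("predicted", predicted)):
        if v.min() < 0 or v.max() >= n_classes:
            raise ValueError(f"{name} labels outside [0, {n_classes})")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (actual, predicted), 1)
    return cm


def _ovr_counts(cm: np.ndarray, class_id: int):
    tp = cm[class_id, class_id]
    fn = cm[class_id].sum() - tp
    fp = cm[:, class_id].sum() - tp
    tn = cm.sum() - tp - fn - fp
    return tp, fp, tn, fn


def _safe_div(num: float, den: float):
    return (num / den, False) if den > 0 else (0.0, True)


def class_metrics(cm: np.ndarray, class_id: int) -> ClassMetrics:
    if not 0 <= class_id < cm.shape[0]:
        raise ValueError(f"class id {class_id} out of range")
    tp, fp, tn, fn = _ovr_counts(cm, class_id)
    precision, d1 = _safe_div(tp, tp + fp)
    recall, d2 = _safe_div(tp, tp + fn)
    specificity, d3 = _safe_div(tn, tn + fp)
    f1, d4 = _safe_div(2 * recall * precision, recall + precision)
    return ClassMetrics(precision, recall, specificity, f1,
                        degenerate=d1 or d2 or d3 or d4)


def accuracy(cm: np.ndarray) -> float:
    """Overall accuracy: trace / total (equals (TP+TN)/(TP+TN+FP+FN) for the
    binary one-vs-rest reduction)."""
    return float(np.trace(cm) / cm.sum())


def macro_average(per_class) -> ClassMetrics:
    if not per_class:
        raise ValueError("no per-class metrics to average")
    return ClassMetrics(
        precision=float(np.mean([c.precision for c in per_class])),
        recall=float(np.mean([c.recall for c in per_class])),
        specificity=float(np.mean([c.specificity for c in per_class])),
        f1=float(np.mean([c.f1 for c in per_class])),
        degenerate=any(c.degenerate for c in per_class),
    )


def roc_auc(scores, actual) -> float:
    """Macro one-vs-rest AUC with trapezoidal integration."""
    scores = np.asarray(scores, dtype=float)
    actual = np.asarray(actual, dtype=int)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores contain non-finite entries")
    present = np.unique(actual)
    if present.size < 2:
        raise ValueError("AUC needs at least two classes present")
    n_classes = scores.shape[1]
    onehot = label_binarize(actual, classes=np.arange(n_classes))
    if n_classes == 2 and onehot.shape[1] == 1:
        onehot = np.hstack([1 - onehot, onehot])
    aucs = []
    for k in present:
        fpr, tpr, _ = roc_curve(onehot[:, k], scores[:, k])
        aucs.append(sk_auc(fpr, tpr))
    return float(np.mean(aucs))


def metrics_report(actual, predicted, n_classes: int,
                   scores=None) -> MetricsReport:
    cm = confusion(actual, predicted, n_classes)
    per_class = [class_metrics(cm, k) for k in range(n_classes)]
    return MetricsReport(
        per_class=per_class,
        macro=macro_average(per_class),
        accuracy=accuracy(cm),
        auc=None if scores is None else roc_auc(scores, actual),
        confusion=cm,
    )


# ------------------------------------------------------------------------- CAM
def cam(model, image, class_id: int) -> np.ndarray:
    """Gradient-weighted class activation map, in [0, 1] at input resolution.

    The class score is backpropagated to the backbone's final convolutional
    map; channel weights are the spatially averaged gradients, and the
    rectified weighted sum is min-max normalized and upsampled.  A constant
    map normalizes to all-zeros.
    """
    image = np.asarray(image)
    if image.ndim == 3:
        image = image[None]
    model.eval()
    logits = model.forward(image)
    if not 0 <= class_id < logits.shape[1]:
        raise ValueError(f"class id {class_id} out of range")
    logits[0, class_id].backward()
    feat = model.last_featmap
    A, G = feat.data[0], feat.grad[0]              # (c, h, w)
    weights = G.mean(axis=(1, 2))
    heat = np.maximum((weights[:, None, None] * A).sum(axis=0), 0.0)
    lo, hi = heat.min(), heat.max()
    heat = (heat - lo) / (hi - lo) if hi > lo else np.zeros_like(heat)
    size = image.shape[-1]
    zoom = size / heat.shape[-1]
    up = ndimage.zoom(heat, zoom, order=1)
    return np.clip(up, 0.0, 1.0)
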