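"""Multi-label evaluation metrics: AUC, macro/micro F1, P@k, accuracy.

AUC is the rank (Mann-Whitney) statistic with ties counting one half; macro
averages are per-class means, micro metrics pool counts over all classes.
P@k ranks each sample's label scores and reports the mean fraction of true
labels among the top k, with ties broken by ascending label index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import f1_score, roc_auc_score

from .graph import ValidationError

__all__ = [
    "MetricsReport",
    "auc",
    "macro_micro_auc",
    "f1_scores",
    "precision_at_k",
    "accuracy",
    "evaluate_predictions",
]


def auc(scores: np.ndarray, truth: np.ndarray) -> float:
    """Area under the ROC curve for one binary task."""
    truth = np.asarray(truth).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    if truth.min() == truth.max():
        raise ValidationError("AUC undefined: truth contains a single class")
    return float(roc_auc_score(truth, scores))


def macro_micro_auc(scores: np.ndarray, truth: np.ndarray) -> tuple[float, float, int]:
    """Per-class-mean and pooled AUC over a (n, C) score/truth pair.

    Classes whose truth column is single-class are skipped from the macro
    mean; the number skipped is returned alongside.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    truth = np.atleast_2d(np.asarray(truth))
    per_class, skipped = [], 0
    for c in range(truth.shape[1]):
        col = truth[:, c]
        if col.min() == col.max():
            skipped += 1
            continue
        per_class.append(auc(scores[:, c], col))
    if not per_class:
        raise ValidationError("AUC undefined for every class")
    micro = auc(scores.ravel(), truth.ravel())
    return float(np.mean(per_class)), micro, skipped


def f1_scores(pred: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    """(macro, micro) F1 for binary indicator matrices of equal shape.

    Classes with zero support and zero predictions contribute F1 = 0 to the
    macro mean.
    """
    pred = np.atleast_2d(np.asarray(pred).astype(int))
    truth = np.atleast_2d(np.asarray(truth).astype(int))
    if pred.shape != truth.shape:
        raise ValidationError(f"shape mismatch {pred.shape} vs {truth.shape}")
    if pred.shape[1] == 1:
        # single label column: per-class mean and pooled counts coincide
        f1 = f1_score(truth.ravel(), pred.ravel(), zero_division=0)
        return float(f1), float(f1)
    macro = f1_score(truth, pred, average="macro", zero_division=0)
    micro = f1_score(truth, pred, average="micro", zero_division=0)
    return float(macro), float(micro)


def precision_at_k(scores: np.ndarray, truth: np.ndarray, k: int) -> float:
    """Mean over samples of (true labels in top-k)/k.

    Ties in scores are broken by ascending label index.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    truth = np.atleast_2d(np.asarray(truth))
    C = scores.shape[1]
    if k < 1 or k > C:
        raise ValidationError(f"k must lie in [1, {C}], got {k}")
    # stable argsort on -scores: among ties, smaller label index ranks first
    order = np.argsort(-scores, axis=1, kind="stable")[:, :k]
    hits = np.take_along_axis(truth, order, axis=1).sum(axis=1)
    return float(np.mean(hits / k))


def accuracy(pred, truth) -> float:
    """Fraction of exactly matching predictions."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.size == 0:
        raise ValidationError("accuracy of an empty prediction set is undefined")
    if pred.shape != truth.shape:
        raise ValidationError(f"shape mismatch {pred.shape} vs {truth.shape}")
    return float(np.mean(pred == truth))


@dataclass
class MetricsReport:
    auc_macro: float
    auc_micro: float
    f1_macro: float
    f1_micro: float
    accuracy: float
    p_at_k: dict[int, float] = field(default_factory=dict)
    auc_classes_skipped: int = 0

    def as_dict(self) -> dict[str, float]:
        out = {
            "auc_macro": self.auc_macro,
            "auc_micro": self.auc_micro,
            "f1_macro": self.f1_macro,
            "f1_micro": self.f1_micro,
            "accuracy": self.accuracy,
        }
        for k, v in self.p_at_k.items():
            out[f"p_at_{k}"] = v
        return out


def evaluate_predictions(
    scores: np.ndarray,
    truth: np.ndarray,
    ks: tuple[int, ...] = (5,),
    threshold: float = 0.5,
    single_label: bool = False,
) -> MetricsReport:
    """Full metric report from a (n, C) score matrix and indicator truth.

    In single-label mode the predicted class is the argmax and accuracy is
    over class assignments; otherwise scores are binarized at ``threshold``
    and accuracy is element-wise over indicators.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    truth = np.atleast_2d(np.asarray(truth))
    if single_label:
        pred_cls = scores.argmax(axis=1)
        true_cls = truth.argmax(axis=1)
        pred = np.zeros_like(truth)
        pred[np.arange(len(pred_cls)), pred_cls] = 1
        acc = accuracy(pred_cls, true_cls)
    else:
        pred = (scores >= threshold).astype(int)
        acc = accuracy(pred, truth.astype(int))
    macro_auc, micro_auc, skipped = macro_micro_auc(scores, truth)
    f1m, f1mi = f1_scores(pred, truth)
    p_at = {k: precision_at_k(scores, truth, k) for k in ks if k <= scores.shape[1]}
    return MetricsReport(
        auc_macro=macro_auc,
        auc_micro=micro_auc,
        f1_macro=f1m,
        f1_micro=f1mi,
        accuracy=acc,
        p_at_k=p_at,
        auc_classes_skipped=skipped,
    )
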