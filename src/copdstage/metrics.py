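"""Four-class staging metrics: accuracy, macro precision/recall/F1, OvR AUC.

Macro averages are unweighted means over the four stages.  The AUC is the
unweighted mean of per-stage one-vs-rest ROC AUCs computed from predicted
probabilities; a stage absent from the ground truth has no defined AUC and is
excluded from the macro mean with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cohort import N_STAGES

__all__ = ["MetricsReport", "compute_metrics", "roc_points"]


@dataclass
class MetricsReport:
    accuracy: float
    precision_macro: float
    recall_macro: float
    f1_macro: float
    auc_macro_ovr: float
    per_class: dict
    confusion: np.ndarray
    missing_auc_classes: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision_macro,
            "recall": self.recall_macro,
            "f1": self.f1_macro,
            "auc": self.auc_macro_ovr,
        }

    def __str__(self) -> str:
        head = (
            f"accuracy={self.accuracy:.3f} precision={self.precision_macro:.3f} "
            f"recall={self.recall_macro:.3f} f1={self.f1_macro:.3f} auc={self.auc_macro_ovr:.3f}"
        )
        return head


def compute_metrics(y_true, y_pred, probs) -> MetricsReport:
    """Metric bundle for 4-class predictions.

    probs must be (n, 4) with rows summing to 1 (the softmax / predict_proba
    output used for the ROC computation).
    """
    from sklearn.metrics import (
        confusion_matrix,
        precision_recall_fscore_support,
        roc_auc_score,
    )

    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    probs = np.asarray(probs, dtype=np.float64)
    if probs.shape != (y_true.size, N_STAGES):
        raise ValueError(f"probs must be (n, {N_STAGES})")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")

    labels = np.arange(N_STAGES)
    conf = confusion_matrix(y_true, y_pred, labels=labels)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, zero_division=0
    )

    per_class: dict = {}
    aucs = []
    missing = []
    for c in labels:
        pos = y_true == c
        entry = {"precision": float(prec[c]), "recall": float(rec[c]), "f1": float(f1[c])}
        if pos.any() and (~pos).any():
            auc = float(roc_auc_score(pos.astype(int), probs[:, c]))
            entry["auc"] = auc
            aucs.append(auc)
        else:
            entry["auc"] = None
            missing.append(int(c))
        per_class[int(c)] = entry
    if missing:
        warnings.warn(
            f"stages {missing} absent from y_true (or cover it entirely); "
            "their AUC is undefined and excluded from the macro mean",
            stacklevel=2,
        )

    return MetricsReport(
        accuracy=float(np.trace(conf) / conf.sum()),
        precision_macro=float(prec.mean()),
        recall_macro=float(rec.mean()),
        f1_macro=float(f1.mean()),
        auc_macro_ovr=float(np.mean(aucs)) if aucs else float("nan"),
        per_class=per_class,
        confusion=conf,
        missing_auc_classes=missing,
    )


def roc_points(y_true, probs):
    """One-vs-rest ROC curve points per stage, long-format for plotting.

    Returns a DataFrame with columns (stage, fpr, tpr, threshold); stages
    absent from y_true are skipped.
    """
    import pandas as pd
    from sklearn.metrics import roc_curve

    y_true = np.asarray(y_true, dtype=np.int64)
    probs = np.asarray(probs, dtype=np.float64)
    frames = []
    for c in range(N_STAGES):
        pos = (y_true == c).astype(int)
        if pos.min() == pos.max():
            continue
        fpr, tpr, thr = roc_curve(pos, probs[:, c])
        frames.append(pd.DataFrame({"stage": c, "fpr": fpr, "tpr": tpr, "threshold": thr}))
    return pd.concat(frames, ignore_index=True)
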