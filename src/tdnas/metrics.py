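"""Classification metrics and the judgment criterion.

The search scores each trained model on the validation set with a
scalar judgment criterion

    jc = omega1 * Acc + omega2 * F_beta,    omega2 = 1 - omega1,

where Acc is plain accuracy and F_beta the weighted harmonic mean of
macro-averaged precision and recall, (1 + beta^2) P R / (beta^2 P + R).
beta > 1 weights recall, beta < 1 precision; omega1 = 1 reduces jc to
accuracy alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = ["EvalResult", "confusion_matrix", "f_beta",
           "judgment_criterion", "evaluate"]


@dataclass(frozen=True)
class EvalResult:
    """Validation metrics for one trained model."""

    confusion: np.ndarray
    accuracy: float
    precision_macro: float
    recall_macro: float
    f_beta: float
    jc: float
    omega1_used: float
    beta_used: float

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "precision_macro": self.precision_macro,
            "recall_macro": self.recall_macro,
            "f_beta": self.f_beta,
            "jc": self.jc,
            "omega1_used": self.omega1_used,
            "beta_used": self.beta_used,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EvalResult":
        d = dict(d)
        d["confusion"] = np.asarray(d["confusion"], dtype=np.int64)
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    def confusion_csv(self, class_names=None) -> str:
        """Confusion matrix as CSV with a header row/column of class names."""
        k = self.confusion.shape[0]
        names = list(class_names) if class_names else [f"C{i}" for i in range(k)]
        lines = ["true\\pred," + ",".join(names)]
        for i in range(k):
            lines.append(names[i] + "," + ",".join(str(v) for v in self.confusion[i]))
        return "\n".join(lines) + "\n"


def confusion_matrix(true_labels, pred_labels, k: int) -> np.ndarray:
    """K x K count matrix; rows are true class, columns predicted class."""
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(pred_labels, dtype=np.int64)
    if t.shape != p.shape:
        raise ValueError("label sequences must have equal length")
    if t.size and (t.min() < 0 or t.max() >= k or p.min() < 0 or p.max() >= k):
        raise ValueError(f"labels must lie in [0, {k})")
    cm = np.zeros((k, k), dtype=np.int64)
    np.add.at(cm, (t, p), 1)
    return cm


def f_beta(precision: float, recall: float, beta: float) -> float:
    """Weighted harmonic mean of precision and recall; 0 when both are 0."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    if not (0.0 <= precision <= 1.0 and 0.0 <= recall <= 1.0):
        raise ValueError("precision and recall must lie in [0, 1]")
    denom = beta**2 * precision + recall
    if denom == 0.0:
        return 0.0
    return (1.0 + beta**2) * precision * recall / denom


def judgment_criterion(acc: float, fb: float, omega1: float) -> float:
    """jc = omega1 * Acc + (1 - omega1) * F_beta."""
    if not 0.0 <= omega1 <= 1.0:
        raise ValueError("omega1 must lie in [0, 1]")
    if not (0.0 <= acc <= 1.0 and 0.0 <= fb <= 1.0):
        raise ValueError("accuracy and F_beta must lie in [0, 1]")
    return omega1 * acc + (1.0 - omega1) * fb


def evaluate(true_labels, pred_labels, k: int, omega1: float = 1.0,
             beta: float = 1.0) -> EvalResult:
    """Full validation-set evaluation.

    Macro precision/recall are unweighted means over the K classes;
    a class with zero predicted (resp. true) samples contributes 0 to
    the macro precision (resp. recall). F_beta is computed from the
    macro-averaged values.
    """
    cm = confusion_matrix(true_labels, pred_labels, k)
    total = cm.sum()
    acc = float(np.trace(cm) / total) if total else 0.0
    pred_tot = cm.sum(axis=0).astype(float)
    true_tot = cm.sum(axis=1).astype(float)
    diag = np.diag(cm).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        prec = np.where(pred_tot > 0, diag / np.where(pred_tot > 0, pred_tot, 1), 0.0)
        rec = np.where(true_tot > 0, diag / np.where(true_tot > 0, true_tot, 1), 0.0)
    p_macro = float(prec.mean())
    r_macro = float(rec.mean())
    fb = f_beta(p_macro, r_macro, beta)
    jc = judgment_criterion(acc, fb, omega1)
    return EvalResult(confusion=cm, accuracy=acc, precision_macro=p_macro,
                      recall_macro=r_macro, f_beta=fb, jc=jc,
                      omega1_used=omega1, beta_used=beta)
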