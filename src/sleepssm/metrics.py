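"""Evaluation metrics for 5-class sleep staging, computed from a
confusion matrix.

Overall metrics: accuracy, macro-F1, Cohen's kappa, and macro-averaged
sensitivity / specificity / precision; per-class precision is reported
alongside, since class imbalance (N1 is rare) makes overall numbers
alone misleading.  All values are on a 0–100 percentage scale, kappa on
−100…100.

Conventions for degenerate counts: a ratio with zero denominator (e.g.
precision of a never-predicted class) is reported as 0 with a warning,
and a class with precision + recall = 0 contributes F1 = 0 to the macro
average.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_CLASSES = 5
STAGE_NAMES = ("W", "N1", "N2", "N3", "REM")


def confusion_matrix(y_true, y_pred, n_classes: int = N_CLASSES) -> np.ndarray:
    """Count table: rows are true stages, columns predicted stages."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: {y_true.shape} true vs {y_pred.shape} predicted")
    for name, y in (("true", y_true), ("predicted", y_pred)):
        if y.size and (y.min() < 0 or y.max() >= n_classes):
            raise ValueError(f"{name} labels outside 0..{n_classes - 1}")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def binary_decomposition(cm: np.ndarray, c: int) -> tuple[int, int, int, int]:
    """One-vs-rest (TP, FN, FP, TN) counts for class ``c``."""
    cm = np.asarray(cm)
    tp = int(cm[c, c])
    fn = int(cm[c].sum() - tp)
    fp = int(cm[:, c].sum() - tp)
    tn = int(cm.sum() - tp - fn - fp)
    return tp, fn, fp, tn


def _safe_ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what}: zero denominator, reporting 0", stacklevel=3)
        return 0.0
    return num / den


def accuracy(cm: np.ndarray) -> float:
    cm = np.asarray(cm)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * np.trace(cm) / total


def macro_f1(cm: np.ndarray) -> float:
    """Unweighted mean of per-class F1 scores (percentage)."""
    cm = np.asarray(cm)
    f1s = []
    for c in range(cm.shape[0]):
        tp, fn, fp, _ = binary_decomposition(cm, c)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1s.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
    return 100.0 * float(np.mean(f1s))


def cohens_kappa(cm: np.ndarray) -> float:
    """Chance-corrected agreement (p_o − p_e)/(1 − p_e), scaled to ±100."""
    cm = np.asarray(cm, dtype=np.float64)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(cm) / total
    p_e = float((cm.sum(axis=1) * cm.sum(axis=0)).sum()) / total**2
    if p_e >= 1.0:
        warnings.warn("expected agreement is 1; kappa undefined, reporting 0")
        return 0.0
    return 100.0 * (p_o - p_e) / (1.0 - p_e)


def sensitivity_specificity_precision(
    cm: np.ndarray,
    average: str = "macro",
) -> tuple[float, float, float, np.ndarray, np.ndarray, np.ndarray]:
    """Overall and per-class one-vs-rest Sen/Spec/Pre (percentages).

    ``average='macro'`` (default) averages the per-class ratios with equal
    class weight; ``'micro'`` pools the binary counts first.
    """
    cm = np.asarray(cm)
    k = cm.shape[0]
    sen = np.empty(k)
    spec = np.empty(k)
    pre = np.empty(k)
    pooled = np.zeros(4, dtype=np.int64)
    for c in range(k):
        tp, fn, fp, tn = binary_decomposition(cm, c)
        pooled += (tp, fn, fp, tn)
        sen[c] = 100.0 * _safe_ratio(tp, tp + fn, f"sensitivity[{STAGE_NAMES[c]}]")
        spec[c] = 100.0 * _safe_ratio(tn, tn + fp, f"specificity[{STAGE_NAMES[c]}]")
        pre[c] = 100.0 * _safe_ratio(tp, tp + fp, f"precision[{STAGE_NAMES[c]}]")
    if average == "macro":
        overall = (float(sen.mean()), float(spec.mean()), float(pre.mean()))
    elif average == "micro":
        tp, fn, fp, tn = (int(v) for v in pooled)
        overall = (
            100.0 * _safe_ratio(tp, tp + fn, "micro sensitivity"),
            100.0 * _safe_ratio(tn, tn + fp, "micro specificity"),
            100.0 * _safe_ratio(tp, tp + fp, "micro precision"),
        )
    else:
        raise ValueError(f"unknown average {average!r}")
    return (*overall, sen, spec, pre)


@dataclass
class MetricsReport:
    """Overall and per-class staging metrics for one evaluation set."""

    acc: float
    mf1: float
    kappa: float
    sen: float
    spec: float
    pre: float
    per_class_precision: np.ndarray
    per_class_sensitivity: np.ndarray
    per_class_specificity: np.ndarray
    n_epochs: int
    confusion: np.ndarray = field(repr=False, default=None)

    @classmethod
    def from_confusion(cls, cm: np.ndarray,
                       average: str = "macro") -> "MetricsReport":
        sen, spec, pre, sen_c, spec_c, pre_c = (
            sensitivity_specificity_precision(cm, average=average))
        return cls(
            acc=accuracy(cm),
            mf1=macro_f1(cm),
            kappa=cohens_kappa(cm),
            sen=sen, spec=spec, pre=pre,
            per_class_precision=pre_c,
            per_class_sensitivity=sen_c,
            per_class_specificity=spec_c,
            n_epochs=int(np.asarray(cm).sum()),
            confusion=np.asarray(cm),
        )

    @classmethod
    def from_labels(cls, y_true, y_pred,
                    average: str = "macro") -> "MetricsReport":
        return cls.from_confusion(confusion_matrix(y_true, y_pred),
                                  average=average)

    def to_row(self) -> dict:
        row = {
            "ACC": self.acc, "MF1": self.mf1, "Kappa": self.kappa,
            "Sen": self.sen, "Spec": self.spec, "Pre": self.pre,
            "n": self.n_epochs,
        }
        for name, v in zip(STAGE_NAMES, self.per_class_precision):
            row[f"Pre({name})"] = v
        return row


def report_table(reports: dict[str, MetricsReport]) -> pd.DataFrame:
    """Rows of overall + per-class-precision columns, one per report."""
    return pd.DataFrame({name: r.to_row() for name, r in reports.items()}).T


def format_report(reports: dict[str, MetricsReport]) -> str:
    """Human-readable table mirroring the standard column layout."""
    df = report_table(reports)
    return df.to_string(float_format=lambda v: f"{v:6.2f}")
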