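"""Multiclass classification metrics from the confusion matrix.

Per-class rates use one-vs-rest reductions of a C×C confusion matrix whose
rows are true classes and columns predicted classes; single-number summaries
are prevalence-weighted means over the classes, the convention that lets a
16-class problem be reported as one TPR/FPR pair.

Two FPR conventions are available. The default is the standard
FP/(FP+TN). The study this package re-implements prints FPR = FP/(FP+FN),
a quantity insensitive to true negatives; it is reproduced behind
``paper_literal_fpr=True`` for reproduction experiments only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.metrics import confusion_matrix as _sk_confusion

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion_matrix",
    "classification_metrics",
    "kappa",
    "rmse",
    "curve_areas",
    "evaluate_predictions",
]


@dataclass
class ConfusionMatrix:
    """C×C integer matrix (rows = true class, columns = predicted)."""

    matrix: np.ndarray
    vocabulary: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=int)
        self.vocabulary = list(self.vocabulary)
        c = len(self.vocabulary)
        if self.matrix.shape != (c, c):
            raise ValueError("matrix shape does not match vocabulary")
        if (self.matrix < 0).any():
            raise ValueError("confusion matrix entries must be non-negative")

    @property
    def n(self) -> int:
        return int(self.matrix.sum())

    def one_vs_rest(self, c: int) -> tuple[int, int, int, int]:
        """(TP, FP, TN, FN) for class index c."""
        m = self.matrix
        tp = int(m[c, c])
        fp = int(m[:, c].sum() - tp)
        fn = int(m[c, :].sum() - tp)
        tn = self.n - tp - fp - fn
        return tp, fp, tn, fn


def confusion_matrix(y_true, y_pred, vocabulary) -> ConfusionMatrix:
    """Tally a confusion matrix; zero-count classes keep their row/column."""
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    vocab = list(vocabulary)
    allowed = set(vocab)
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        bad = sorted({v for v in arr if v not in allowed})
        if bad:
            raise ValueError(f"{name} contains labels outside vocabulary: {bad}")
    m = _sk_confusion(y_true, y_pred, labels=vocab)
    return ConfusionMatrix(m, vocab)


@dataclass
class MetricsReport:
    """Per-class and prevalence-weighted metrics for one prediction set."""

    vocabulary: list[str]
    per_class: dict[str, dict[str, float]]
    weighted_tpr: float
    weighted_fpr: float
    weighted_precision: float
    accuracy: float
    kappa: float
    n: int
    rmse: float | None = None
    roc_area: float | None = None
    prc_area: float | None = None
    per_class_roc: dict[str, float] = field(default_factory=dict)
    per_class_prc: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "accuracy": self.accuracy,
            "weighted_tpr": self.weighted_tpr,
            "weighted_fpr": self.weighted_fpr,
            "weighted_precision": self.weighted_precision,
            "kappa": self.kappa,
            "rmse": self.rmse,
            "roc_area": self.roc_area,
            "prc_area": self.prc_area,
            "per_class": self.per_class,
            "per_class_roc": self.per_class_roc,
            "per_class_prc": self.per_class_prc,
        }


def classification_metrics(
    cm: ConfusionMatrix, paper_literal_fpr: bool = False
) -> MetricsReport:
    """TPR/recall, FPR, precision per class plus weighted summaries and CA.

    TPR_c = TP/(TP+FN) (0 for a class with no true rows); FPR_c defaults to
    FP/(FP+TN); CA = trace/N; weighted rates are Σ_c prevalence_c · rate_c.
    """
    n = cm.n
    if n == 0:
        raise ValueError("empty confusion matrix")
    per_class: dict[str, dict[str, float]] = {}
    prevalence = cm.matrix.sum(axis=1) / n
    w_tpr = w_fpr = w_prec = 0.0
    for c, cls in enumerate(cm.vocabulary):
        tp, fp, tn, fn = cm.one_vs_rest(c)
        tpr = tp / (tp + fn) if tp + fn else 0.0
        if paper_literal_fpr:
            fpr = fp / (fp + fn) if fp + fn else 0.0
        else:
            fpr = fp / (fp + tn) if fp + tn else 0.0
        prec = tp / (tp + fp) if tp + fp else 0.0
        per_class[cls] = {
            "tpr": tpr, "fpr": fpr, "precision": prec, "recall": tpr,
            "support": int(tp + fn),
        }
        w_tpr += prevalence[c] * tpr
        w_fpr += prevalence[c] * fpr
        w_prec += prevalence[c] * prec
    accuracy = float(np.trace(cm.matrix) / n)
    return MetricsReport(
        vocabulary=cm.vocabulary,
        per_class=per_class,
        weighted_tpr=float(w_tpr),
        weighted_fpr=float(w_fpr),
        weighted_precision=float(w_prec),
        accuracy=accuracy,
        kappa=kappa(cm),
        n=n,
    )


def kappa(cm: ConfusionMatrix) -> float:
    """Cohen's kappa: (Po − Pe)/(1 − Pe) with Pe from the marginals."""
    n = cm.n
    if n == 0:
        raise ValueError("empty confusion matrix")
    po = float(np.trace(cm.matrix)) / n
    row = cm.matrix.sum(axis=1)
    col = cm.matrix.sum(axis=0)
    pe = float((row * col).sum()) / (n * n)
    if pe == 1.0:
        raise ValueError("chance agreement Pe = 1; kappa undefined")
    return (po - pe) / (1.0 - pe)


def rmse(prob_matrix, y_true, vocabulary) -> float:
    """Root mean squared error of class probabilities against one-hot truth.

    RMSE = sqrt( (1/(N·C)) Σ_i Σ_c (p_ic − y_ic)² ); in [0, 1] for valid
    probability rows.
    """
    p = np.asarray(prob_matrix, dtype=float)
    y_true = np.asarray(y_true, dtype=object)
    vocab = list(vocabulary)
    if p.ndim != 2 or p.shape != (len(y_true), len(vocab)):
        raise ValueError("prob_matrix shape must be (n_rows, n_classes)")
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    index = {c: i for i, c in enumerate(vocab)}
    onehot = np.zeros_like(p)
    onehot[np.arange(len(y_true)), [index[v] for v in y_true]] = 1.0
    return float(np.sqrt(np.mean((p - onehot) ** 2)))


def curve_areas(scores, y_true, vocabulary):
    """One-vs-rest ROC and precision-recall areas, per class and weighted.

    ROC area uses the trapezoidal rule with tied scores grouped; PRC area is
    the average-precision step sum. Classes without both a positive and a
    negative row are reported as NaN and excluded from the weighted
    averages, whose weights are renormalized prevalences over the included
    classes.
    """
    s = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true, dtype=object)
    vocab = list(vocabulary)
    if s.shape != (len(y_true), len(vocab)):
        raise ValueError("scores shape must be (n_rows, n_classes)")
    roc: dict[str, float] = {}
    prc: dict[str, float] = {}
    weights = []
    for c, cls in enumerate(vocab):
        pos = y_true == cls
        npos = int(pos.sum())
        if npos == 0 or npos == len(y_true):
            roc[cls] = float("nan")
            prc[cls] = float("nan")
            weights.append(0.0)
            continue
        roc[cls] = float(roc_auc_score(pos, s[:, c]))
        prc[cls] = float(average_precision_score(pos, s[:, c]))
        weights.append(npos / len(y_true))
    total = sum(weights)
    if total > 0:
        w_roc = sum(w * roc[c] for c, w in zip(vocab, weights) if w > 0) / total
        w_prc = sum(w * prc[c] for c, w in zip(vocab, weights) if w > 0) / total
    else:
        w_roc = w_prc = float("nan")
    return roc, prc, float(w_roc), float(w_prc)


def evaluate_predictions(
    y_true,
    y_pred,
    vocabulary,
    prob_matrix=None,
    paper_literal_fpr: bool = False,
) -> MetricsReport:
    """Full report: rates + kappa, and RMSE / curve areas when scores given."""
    cm = confusion_matrix(y_true, y_pred, vocabulary)
    report = classification_metrics(cm, paper_literal_fpr=paper_literal_fpr)
    if prob_matrix is not None:
        report.rmse = rmse(prob_matrix, y_true, vocabulary)
        roc, prc, w_roc, w_prc = curve_areas(prob_matrix, y_true, vocabulary)
        report.per_class_roc = roc
        report.per_class_prc = prc
        report.roc_area = w_roc
        report.prc_area = w_prc
    return report
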