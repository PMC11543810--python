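"""Annotation-quality metrics.

Accuracy, support-weighted and macro F1, Cohen's kappa, balanced
accuracy, precision/recall, NMI and ARI, all computed from the true and
predicted label sets via scikit-learn, plus the raw contingency
(confusion) table.  NMI uses the arithmetic normalisation
2·I(U,V)/(H(U)+H(V)) (the log base cancels); ARI is the standard
pair-counting form (RI − E[RI])/(max RI − E[RI]).  Classes present in
only one of the two labelings are kept as zero rows/columns, so a class
the predictor never emits still counts against balanced accuracy and
per-class recall.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    adjusted_rand_score,
    balanced_accuracy_score,
    cohen_kappa_score,
    confusion_matrix,
    normalized_mutual_info_score,
    precision_recall_fscore_support,
)

from .io_preprocess import LabelSet

__all__ = [
    "ContingencyTable",
    "MetricsReport",
    "confusion",
    "classification_report",
    "clustering_agreement",
]


@dataclass(frozen=True)
class ContingencyTable:
    """counts[i, j] = number of cells with true class i predicted as j."""

    counts: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self):
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match label vocabularies")
        if (self.counts < 0).any():
            raise ValueError("negative count")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.row_labels),
                            columns=list(self.col_labels))


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    weighted_f1: float
    macro_f1: float
    kappa: float
    nmi: float
    ari: float
    balanced_accuracy: float
    macro_precision: float
    weighted_precision: float
    macro_recall: float
    weighted_recall: float
    per_class: dict = field(compare=False)

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "accuracy", "weighted_f1", "macro_f1", "kappa", "nmi", "ari",
            "balanced_accuracy", "macro_precision", "weighted_precision",
            "macro_recall", "weighted_recall")}
        d["per_class"] = self.per_class
        return d


def _merged_vocab(true: LabelSet, pred: LabelSet) -> tuple[str, ...]:
    vocab = list(true.vocabulary)
    vocab += [v for v in pred.vocabulary if v not in set(vocab)]
    return tuple(vocab)


def _check(true: LabelSet, pred: LabelSet) -> None:
    if len(true) != len(pred):
        raise ValueError(f"length mismatch: {len(true)} true vs {len(pred)} predicted")
    if len(true) == 0:
        raise ValueError("empty input")


def confusion(true: LabelSet, pred: LabelSet) -> ContingencyTable:
    """Square contingency table over the merged class vocabulary."""
    _check(true, pred)
    vocab = _merged_vocab(true, pred)
    counts = confusion_matrix(list(true.labels), list(pred.labels), labels=list(vocab))
    return ContingencyTable(counts, vocab, vocab)


def classification_report(true: LabelSet, pred: LabelSet) -> MetricsReport:
    """Full metric panel for a predicted annotation against the truth."""
    _check(true, pred)
    vocab = list(_merged_vocab(true, pred))
    y, yhat = list(true.labels), list(pred.labels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-division classes reported as 0
        prec, rec, f1, support = precision_recall_fscore_support(
            y, yhat, labels=vocab, zero_division=0
        )
        macro_p, macro_r, macro_f1, _ = precision_recall_fscore_support(
            y, yhat, labels=vocab, average="macro", zero_division=0
        )
        wt_p, wt_r, wt_f1, _ = precision_recall_fscore_support(
            y, yhat, labels=vocab, average="weighted", zero_division=0
        )
        bal = balanced_accuracy_score(y, yhat)
    nmi, ari = clustering_agreement(true, pred)
    per_class = {
        v: {"precision": float(p), "recall": float(r), "f1": float(f), "support": int(s)}
        for v, p, r, f, s in zip(vocab, prec, rec, f1, support)
    }
    return MetricsReport(
        accuracy=float(accuracy_score(y, yhat)),
        weighted_f1=float(wt_f1),
        macro_f1=float(macro_f1),
        kappa=float(cohen_kappa_score(y, yhat, labels=vocab)),
        nmi=nmi,
        ari=ari,
        balanced_accuracy=float(bal),
        macro_precision=float(macro_p),
        weighted_precision=float(wt_p),
        macro_recall=float(macro_r),
        weighted_recall=float(wt_r),
        per_class=per_class,
    )


def clustering_agreement(true: LabelSet, pred: LabelSet) -> tuple[float, float]:
    """(NMI, ARI) between the two labelings; both permutation-invariant.

    NMI = 2·I(U,V)/(H(U)+H(V)), 0 by convention when both entropies
    vanish; ARI = 0 when a marginal is degenerate (E[RI] equals RI).
    """
    _check(true, pred)
    codes_t = np.asarray(true.codes)
    codes_p = np.asarray(pred.codes)
    if len(np.unique(codes_t)) == 1 and len(np.unique(codes_p)) == 1:
        # H(U)+H(V)=0: the ratio is 0/0, resolved to 0 by convention
        nmi = 0.0
    else:
        nmi = float(
            normalized_mutual_info_score(codes_t, codes_p, average_method="arithmetic")
        )
    ari = float(adjusted_rand_score(codes_t, codes_p))
    return nmi, ari
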