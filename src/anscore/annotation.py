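"""Score-based cell annotation and its evaluation metrics.

Cells are labeled unsupervised by the argmax over signature scores. Whether
argmax labeling works depends not only on how much label information the
scores carry but on whether score *ranges* are comparable across signatures;
the two are disentangled by two quantities:

* **information quantity** — mean held-out balanced accuracy of a supervised
  (unpenalized multinomial logistic) classifier predicting the true label
  from the score matrix, under stratified k-fold cross-validation. An upper
  proxy for the label information in the scores, invariant to per-column
  affine distortions.
* **scale imbalance** — |information quantity − balanced accuracy of argmax
  labels|. Large values mean the scores are informative but on incomparable
  scales, so the argmax rule misassigns cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    average_precision_score,
    balanced_accuracy_score,
    confusion_matrix,
    f1_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold

from .core import ScoreMatrix, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationResult",
    "argmax_labels",
    "evaluate_labels",
    "binary_auc",
    "information_quantity",
    "scale_imbalance",
    "write_annotation_report",
]


@dataclass
class AnnotationResult:
    predicted: pd.Series
    truth: pd.Series | None
    balanced_accuracy: float
    weighted_f1: float
    confusion: pd.DataFrame  # rows: truth classes, columns: predicted


def argmax_labels(scores: ScoreMatrix) -> pd.Series:
    """Label each cell with its maximal-score signature.

    Ties go to the first signature in column order; the number of tied cells
    is logged.
    """
    vals = scores.values
    if not np.all(np.isfinite(vals)):
        raise ValidationError("score matrix contains non-finite values")
    idx = np.argmax(vals, axis=1)  # first maximum = first column in order
    n_ties = int((np.sum(vals == vals.max(axis=1, keepdims=True), axis=1) > 1).sum())
    if n_ties:
        logger.warning("argmax labeling: %d cell(s) had tied maximal scores", n_ties)
    labels = [scores.signature_names[i] for i in idx]
    return pd.Series(labels, index=scores.cell_ids, name="predicted")


def evaluate_labels(pred, truth) -> AnnotationResult:
    """Balanced accuracy, weighted F1 and the confusion table of a labeling.

    Balanced accuracy is the unweighted mean of per-class recall; weighted F1
    the support-weighted mean of per-class F1. Labels present only in the
    predictions count as errors against every truth class (warned).
    """
    pred = pd.Series(list(pred)).astype(str)
    truth = pd.Series(list(truth)).astype(str)
    if len(pred) != len(truth):
        raise ValidationError("pred and truth have different lengths")
    truth_classes = sorted(truth.unique())
    extra = sorted(set(pred.unique()) - set(truth_classes))
    if extra:
        logger.warning("predicted label(s) absent from truth: %s", extra)
    labels = truth_classes + extra
    cm = confusion_matrix(truth, pred, labels=labels)
    cm = pd.DataFrame(cm, index=labels, columns=labels).loc[truth_classes, labels]
    ba = balanced_accuracy_score(truth, pred)
    wf1 = f1_score(truth, pred, average="weighted", zero_division=0)
    return AnnotationResult(
        predicted=pred,
        truth=truth,
        balanced_accuracy=float(ba),
        weighted_f1=float(wf1),
        confusion=cm,
    )


def binary_auc(scores, truth, kind: str = "roc") -> float:
    """Area under the ROC (rank statistic, averaged ties) or PR curve."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    if len(np.unique(truth)) != 2:
        raise ValidationError("binary_auc requires exactly two classes in truth")
    if kind == "roc":
        return float(roc_auc_score(truth, scores))
    if kind == "pr":
        return float(average_precision_score(truth, scores))
    raise ValidationError(f"unknown AUC kind {kind!r}")


def information_quantity(
    scores: ScoreMatrix | np.ndarray,
    truth,
    k_folds: int = 10,
    seed: int = 42,
    metric: str = "balanced_accuracy",
) -> float:
    """Cross-validated supervised annotation performance of the scores.

    Fits an unpenalized multinomial logistic regression on the score columns
    under stratified ``k_folds``-fold cross-validation (shuffled with
    ``seed``) and returns the mean held-out balanced accuracy (or weighted F1
    with ``metric="weighted_f1"``). Deterministic given the seed.
    """
    X = scores.values if isinstance(scores, ScoreMatrix) else np.asarray(scores, float)
    y = np.asarray([str(t) for t in truth])
    classes, counts = np.unique(y, return_counts=True)
    small = classes[counts < k_folds]
    if small.size:
        raise ValidationError(
            f"class(es) too small for {k_folds}-fold stratification: {list(small)}"
        )
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    vals = []
    for tr, te in skf.split(X, y):
        # C=inf: unpenalized multinomial fit (reproducible: fixed tol/iteration cap)
        clf = LogisticRegression(C=np.inf, max_iter=2000, tol=1e-6)
        clf.fit(X[tr], y[tr])
        yhat = clf.predict(X[te])
        if metric == "balanced_accuracy":
            vals.append(balanced_accuracy_score(y[te], yhat))
        elif metric == "weighted_f1":
            vals.append(f1_score(y[te], yhat, average="weighted", zero_division=0))
        else:
            raise ValidationError(f"unknown metric {metric!r}")
    return float(np.mean(vals))


def scale_imbalance(
    scores: ScoreMatrix,
    truth,
    k_folds: int = 10,
    seed: int = 42,
) -> float:
    """|information quantity − balanced accuracy of argmax annotation|."""
    iq = information_quantity(scores, truth, k_folds=k_folds, seed=seed)
    ba = evaluate_labels(argmax_labels(scores), truth).balanced_accuracy
    return abs(iq - ba)


def write_annotation_report(
    scores: ScoreMatrix,
    path,
    truth=None,
) -> pd.DataFrame:
    """TSV report per cell: predicted label, truth (if given), max score and
    the margin to the runner-up signature."""
    pred = argmax_labels(scores)
    vals = scores.values
    order = np.sort(vals, axis=1)
    margin = order[:, -1] - order[:, -2] if vals.shape[1] > 1 else order[:, -1]
    df = pd.DataFrame(
        {
            "cell_id": scores.cell_ids,
            "predicted": pred.to_numpy(),
            "truth": list(truth) if truth is not None else [""] * len(pred),
            "max_score": vals.max(axis=1),
            "margin": margin,
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return df
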