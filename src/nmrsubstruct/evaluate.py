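"""Micro-averaged evaluation of one-hot substructure classifiers.

The prediction and truth lists-of-lists are flattened to class indices
(argmax of the probability rows, position of the 1 in the truth rows) and
tallied into an m×m confusion matrix C whose entries sum to the number of
test instances.  Per class i: TP_i = C[i,i]; FP_i = column sum − C[i,i];
FN_i = row sum − C[i,i]; TN_i = total − (TP+FP+FN).  Overall accuracy is
trace/total, and because every instance belongs to exactly one class the
micro-averaged precision, recall and F1 all equal that accuracy — an
identity asserted rather than assumed.

Top-k accuracy per class asks whether the true class ranks within the k
highest predicted probabilities; a class with decent support whose top-k
accuracy stays below a threshold is counted as poorly characterized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def flatten_labels(true_onehots: np.ndarray,
                   pred_probabilities: np.ndarray) -> tuple:
    """Flatten one-hot truths and probability rows to index lists.

    Argmax ties break toward the lowest class index.  Each truth row must
    contain exactly one 1.
    """
    true_onehots = np.asarray(true_onehots)
    pred = np.asarray(pred_probabilities)
    if true_onehots.shape != pred.shape:
        raise ValueError("true/pred shape mismatch")
    if not np.all(np.sum(true_onehots == 1, axis=1) == 1):
        raise ValueError("each true vector must have exactly one 1")
    return true_onehots.argmax(axis=1), pred.argmax(axis=1)


def confusion_matrix(true_indices: Sequence, pred_indices: Sequence,
                     m: int) -> np.ndarray:
    """C[i, j] = number of instances with true class i predicted as j."""
    t = np.asarray(true_indices, dtype=int)
    p = np.asarray(pred_indices, dtype=int)
    if t.shape != p.shape:
        raise ValueError("length mismatch")
    if t.size and (t.min() < 0 or p.min() < 0 or t.max() >= m or p.max() >= m):
        raise ValueError(f"class index outside 0..{m - 1}")
    c = np.zeros((m, m), dtype=int)
    np.add.at(c, (t, p), 1)
    return c


def per_class_counts(c: np.ndarray, class_index: int) -> tuple:
    """(TP, FP, FN, TN) for one class of a confusion matrix."""
    tp = int(c[class_index, class_index])
    fp = int(c[:, class_index].sum()) - tp
    fn = int(c[class_index, :].sum()) - tp
    tn = int(c.sum()) - tp - fp - fn
    return tp, fp, fn, tn


def micro_metrics(c: np.ndarray) -> tuple:
    """(accuracy, precision_micro, recall_micro, f1_micro).

    For single-label data all four coincide; the identity is checked here
    and any violation would indicate a bookkeeping bug.
    """
    total = int(c.sum())
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp = float(np.trace(c))
    fp = float(c.sum(axis=0).sum() - np.trace(c))
    fn = float(c.sum(axis=1).sum() - np.trace(c))
    accuracy = tp / total
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    assert abs(precision - accuracy) < 1e-12
    assert abs(recall - accuracy) < 1e-12
    return accuracy, precision, recall, f1


def _ranks(pred_probabilities: np.ndarray) -> np.ndarray:
    """Rank of each class per row, 0 = most probable; ties by lowest index."""
    # stable sort of -p keeps the lower class index first among ties
    order = np.argsort(-pred_probabilities, axis=1, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(order.shape[0])[:, None]
    ranks[rows, order] = np.arange(order.shape[1])[None, :]
    return ranks


def topk_table(true_indices: Sequence, pred_probabilities: np.ndarray,
               ks: Sequence = (1, 3, 5, 10)) -> pd.DataFrame:
    """Per-class support and top-k accuracies.

    A k larger than the class count is clamped (with a log message).
    Rows are indexed by class; columns: support, top1, top3, ...
    """
    t = np.asarray(true_indices, dtype=int)
    pred = np.asarray(pred_probabilities)
    m = pred.shape[1]
    ranks = _ranks(pred)
    true_rank = ranks[np.arange(len(t)), t]
    rows = []
    for cls in range(m):
        mask = t == cls
        support = int(mask.sum())
        row = {"class": cls, "support": support}
        for k in ks:
            kk = min(k, m)
            if kk != k:
                logger.info("top-%d clamped to %d classes", k, m)
            row[f"top{k}"] = (
                float((true_rank[mask] < kk).mean()) if support else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("class")


def count_poor_classes(per_class: pd.DataFrame, k: int,
                       min_support: int = 10,
                       threshold: float = 0.10) -> int:
    """Classes with support > min_support whose top-k accuracy < threshold."""
    col = f"top{k}"
    if col not in per_class.columns:
        raise ValueError(f"no {col} column in the per-class table")
    sel = per_class[per_class["support"] > min_support]
    return int((sel[col] < threshold).sum())


@dataclass
class EvalReport:
    confusion: np.ndarray
    n_test: int
    accuracy_overall: float
    precision_micro: float
    recall_micro: float
    f1_micro: float
    per_class: pd.DataFrame

    def summary(self) -> str:
        lines = [
            f"test instances:     {self.n_test}",
            f"overall accuracy:   {self.accuracy_overall:.3f}",
            f"micro precision:    {self.precision_micro:.3f}",
            f"micro recall:       {self.recall_micro:.3f}",
            f"micro F1:           {self.f1_micro:.3f}",
            "",
            "per-class top-k accuracies:",
            self.per_class.round(3).to_string(),
        ]
        return "\n".join(lines)

    def save(self, directory) -> None:
        import pathlib

        directory = pathlib.Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.confusion).to_csv(directory / "confusion.csv")
        self.per_class.to_csv(directory / "per_class.csv")
        (directory / "summary.txt").write_text(self.summary() + "\n")


def evaluate(true_onehots: np.ndarray, pred_probabilities: np.ndarray,
             ks: Sequence = (1, 3, 5, 10)) -> EvalReport:
    """Full evaluation from one-hot truths and predicted probabilities."""
    t, p = flatten_labels(true_onehots, pred_probabilities)
    m = np.asarray(pred_probabilities).shape[1]
    c = confusion_matrix(t, p, m)
    accuracy, precision, recall, f1 = micro_metrics(c)
    table = topk_table(t, pred_probabilities, ks)
    return EvalReport(c, int(c.sum()), accuracy, precision, recall, f1, table)
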