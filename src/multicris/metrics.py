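"""Single-label and multi-label performance metrics.

Multi-label conventions: relaxed accuracy is containment of the reference
primary class in the predicted label set; Hamming loss is the mean fraction
of the K labels on which the sets disagree (symmetric difference / K);
subset accuracy requires exact set equality; multi-label accuracy is the
mean Jaccard index (empty vs empty counts as 1); label-ranking average
precision ranks classes by descending score with ties broken by class order.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Mapping, Optional, Sequence, Set

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    matthews_corrcoef,
    precision_recall_fscore_support,
    roc_auc_score,
)

from .types import MultiLabelAssignment, NOT_CLASSIFIED

logger = logging.getLogger(__name__)


def label_sets(assignments: Sequence[MultiLabelAssignment]) -> List[frozenset]:
    return [a.labels for a in assignments]


def relaxed_accuracy(pred_sets: Sequence[Set[str]], ref_primary: Sequence[str]) -> float:
    """Fraction of samples whose predicted label set contains the reference
    primary class."""
    if len(pred_sets) != len(ref_primary):
        raise ValueError("length mismatch between predictions and references")
    if not pred_sets:
        return float("nan")
    hits = sum(1 for s, r in zip(pred_sets, ref_primary) if r in s)
    return hits / len(pred_sets)


def hamming_loss(
    pred_sets: Sequence[Set[str]], ref_sets: Sequence[Set[str]], n_classes: int
) -> float:
    """Mean fraction of misclassified labels: |pred symmetric-diff ref| / K."""
    if not pred_sets:
        return float("nan")
    total = sum(len(set(p) ^ set(r)) for p, r in zip(pred_sets, ref_sets))
    return total / (len(pred_sets) * n_classes)


def subset_accuracy(pred_sets: Sequence[Set[str]], ref_sets: Sequence[Set[str]]) -> float:
    """Fraction of samples with strictly identical label sets."""
    if not pred_sets:
        return float("nan")
    return sum(1 for p, r in zip(pred_sets, ref_sets) if set(p) == set(r)) / len(pred_sets)


def multilabel_accuracy(pred_sets: Sequence[Set[str]], ref_sets: Sequence[Set[str]]) -> float:
    """Mean Jaccard index |intersection|/|union|; empty vs empty counts 1."""
    if not pred_sets:
        return float("nan")
    total = 0.0
    for p, r in zip(pred_sets, ref_sets):
        p, r = set(p), set(r)
        union = p | r
        total += 1.0 if not union else len(p & r) / len(union)
    return total / len(pred_sets)


def average_precision_ml(
    scores: pd.DataFrame, ref_sets: Sequence[Set[str]]
) -> float:
    """Label-ranking average precision.

    Per sample, classes are ranked by descending score (ties resolved by
    class/column order); the average over true labels of
    (number of true labels at or above its rank) / rank is taken, then the
    mean over samples with a non-empty reference set.
    """
    classes = list(scores.columns)
    values = scores.to_numpy(dtype=float)
    per_sample = []
    for j, ref in enumerate(ref_sets):
        ref = set(ref)
        if not ref:
            continue
        order = np.argsort(-values[j], kind="stable")  # stable: ties keep class order
        rank_of = {classes[c]: pos + 1 for pos, c in enumerate(order)}
        precisions = []
        for t in ref:
            r = rank_of[t]
            above = sum(1 for u in ref if rank_of[u] <= r)
            precisions.append(above / r)
        per_sample.append(sum(precisions) / len(precisions))
    if not per_sample:
        return float("nan")
    return float(np.mean(per_sample))


def single_label_metrics(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    class_names: Sequence[str],
    scores: Optional[pd.DataFrame] = None,
) -> Dict[str, object]:
    """Accuracy, per-class precision/recall/F1, macro-F1, MCC, and (when
    per-class scores are supplied) one-vs-rest AUROC and AUPRC."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    classes = list(class_names)
    prec, rec, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, zero_division=0
    )
    out: Dict[str, object] = {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "mcc": float(matthews_corrcoef(y_true, y_pred)),
        "per_class": {
            k: {
                "precision": float(p),
                "recall": float(r),
                "f1": float(f),
                "support": int(s),
            }
            for k, p, r, f, s in zip(classes, prec, rec, f1, support)
        },
        "macro_f1": float(np.mean(f1)),
    }
    if scores is None:
        logger.warning("no scores supplied; AUROC/AUPRC omitted")
        return out
    auroc, auprc = {}, {}
    for k in classes:
        truth = np.array([1 if t == k else 0 for t in y_true])
        if truth.min() == truth.max():
            auroc[k] = float("nan")
            auprc[k] = float("nan")
            continue
        s = scores[k].to_numpy(dtype=float)
        auroc[k] = float(roc_auc_score(truth, s))
        auprc[k] = float(average_precision_score(truth, s))
    out["auroc"] = auroc
    out["auprc"] = auprc
    return out


def multilabel_metrics(
    predicted: Sequence[MultiLabelAssignment],
    reference: Sequence[MultiLabelAssignment],
    class_names: Sequence[str],
) -> Dict[str, float]:
    """Convenience bundle over aligned assignment collections."""
    by_id = {a.sample_id: a for a in reference}
    common = [p for p in predicted if p.sample_id in by_id]
    preds = [p.labels for p in common]
    refs = [by_id[p.sample_id].labels for p in common]
    ref_primary = [by_id[p.sample_id].primary for p in common]
    out = {
        "relaxed_accuracy": relaxed_accuracy(preds, ref_primary),
        "hamming_loss": hamming_loss(preds, refs, len(class_names)),
        "subset_accuracy": subset_accuracy(preds, refs),
        "multilabel_accuracy": multilabel_accuracy(preds, refs),
        "n_samples": len(common),
    }
    if all(p.scores is not None for p in common) and common:
        scores = pd.DataFrame(
            [[p.scores[k] for k in class_names] for p in common],
            index=[p.sample_id for p in common],
            columns=list(class_names),
        )
        out["average_precision"] = average_precision_ml(scores, refs)
    return out
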