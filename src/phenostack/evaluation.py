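"""Binary-classification evaluation: confusion-matrix accounting,
sensitivity/specificity/accuracy/MCC, stratified cross-validation and
ROC/AUC.

The metric definitions are the standard ones:

    SE  = TP / (TP + FN)                     sensitivity (active recall)
    SP  = TN / (TN + FP)                     specificity (inactive recall)
    PPV = TP / (TP + FP)                     positive predictive value
    ACC = (TP + TN) / total                  overall accuracy
    MCC = (TP*TN - FN*FP) / sqrt((TP+FN)(TP+FP)(TN+FN)(TN+FP))

Any metric whose denominator is zero is reported as 0, signalling
"undefined/uninformative" while keeping tabular reports total.

A terminology trap worth stating: virtual-screening reports in this
domain often label their overall-accuracy column "PPV".  ``MetricSet``
carries both quantities under unambiguous names (``ppv_eq3`` for the
true positive predictive value, ``accuracy`` for overall accuracy) and
the report writer's "PPV" column shows accuracy to match the field's
table convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import sklearn.metrics as skm
from sklearn.model_selection import StratifiedKFold

from phenostack.synthetic_data import CompoundRecord, LabeledDataset


@dataclass
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if self.total < 1:
            raise ValueError("confusion matrix must contain at least one case")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricSet:
    se: float
    sp: float
    ppv_eq3: float
    accuracy: float
    mcc: float
    auc: float | None = None

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)
                if getattr(self, f.name) is not None}


def confusion(labels: Sequence[int], predictions: Sequence[int]) -> ConfusionMatrix:
    """Count TP/TN/FP/FN for 0/1 labels and predictions."""
    labels = np.asarray(labels, dtype=int)
    predictions = np.asarray(predictions, dtype=int)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must have equal length")
    if len(labels) < 1:
        raise ValueError("empty input")
    if not (np.isin(labels, (0, 1)).all() and np.isin(predictions, (0, 1)).all()):
        raise ValueError("labels and predictions must be 0/1")
    tp = int(np.sum((labels == 1) & (predictions == 1)))
    tn = int(np.sum((labels == 0) & (predictions == 0)))
    fp = int(np.sum((labels == 0) & (predictions == 1)))
    fn = int(np.sum((labels == 1) & (predictions == 0)))
    return ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn)


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else 0.0


def metrics(cm: ConfusionMatrix, auc: float | None = None) -> MetricSet:
    """SE, SP, PPV, accuracy and MCC from a confusion matrix."""
    tp, tn, fp, fn = cm.tp, cm.tn, cm.fp, cm.fn
    denom = math.sqrt((tp + fn) * (tp + fp) * (tn + fn) * (tn + fp))
    mcc = _safe_div(tp * tn - fn * fp, denom)
    return MetricSet(
        se=_safe_div(tp, tp + fn),
        sp=_safe_div(tn, tn + fp),
        ppv_eq3=_safe_div(tp, tp + fp),
        accuracy=_safe_div(tp + tn, cm.total),
        mcc=mcc,
        auc=auc,
    )


def roc_auc(labels: Sequence[int], scores: Sequence[float]
            ) -> tuple[list[tuple[float, float]], float]:
    """ROC curve (FPR, TPR pairs over descending score thresholds) and the
    trapezoidal AUC; tied scores collapse onto one threshold, making the
    AUC equal to the Mann-Whitney concordance statistic."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present for ROC analysis")
    fpr, tpr, _ = skm.roc_curve(labels, scores)
    auc = float(skm.auc(fpr, tpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def evaluate_predictions(labels: Sequence[int], predictions: Sequence[int],
                         scores: Sequence[float] | None = None) -> MetricSet:
    auc = None
    if scores is not None and len(np.unique(np.asarray(labels))) == 2:
        _, auc = roc_auc(labels, scores)
    return metrics(confusion(labels, predictions), auc)


def cross_validate(
    fit_predict: Callable[[list[CompoundRecord], list[CompoundRecord]],
                          tuple[np.ndarray, np.ndarray | None]],
    dataset: LabeledDataset,
    k: int = 5,
    seed: int = 0,
    partition: str = "train",
) -> tuple[MetricSet, MetricSet]:
    """Stratified k-fold cross-validation of an entire pipeline.

    ``fit_predict(train_records, val_records)`` must refit everything
    (descriptor selection, base models, stacking, ...) on the training
    records and return ``(predicted_labels, scores_or_None)`` for the
    validation records.  Returns (mean, sd) over the per-fold metric sets.
    """
    records = dataset.subset(partition) if partition else list(dataset.records)
    y = np.array([r.label for r in records])
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(f"each class needs >= {k} members for {k}-fold CV")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    per_fold: list[MetricSet] = []
    for tr_idx, va_idx in skf.split(np.zeros(len(y)), y):
        tr = [records[i] for i in tr_idx]
        va = [records[i] for i in va_idx]
        preds, scores = fit_predict(tr, va)
        per_fold.append(evaluate_predictions(y[va_idx], preds, scores))
    names = ["se", "sp", "ppv_eq3", "accuracy", "mcc"]
    arr = np.array([[getattr(ms, n) for n in names] for ms in per_fold])
    aucs = [ms.auc for ms in per_fold if ms.auc is not None]
    mean = MetricSet(*arr.mean(axis=0),
                     auc=float(np.mean(aucs)) if aucs else None)
    sd = MetricSet(*arr.std(axis=0, ddof=1),
                   auc=float(np.std(aucs, ddof=1)) if len(aucs) > 1 else None)
    return mean, sd


def report_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble a model-comparison table (one row per model x phase).

    Each input dict carries ``model``, ``phase`` (cv/test) and a
    ``MetricSet`` under ``metrics`` (optionally ``sd``).  Following the
    field's table convention, the "PPV" column shows overall accuracy;
    the true positive predictive value is kept in ``ppv_eq3``.
    """
    out = []
    for row in rows:
        ms: MetricSet = row["metrics"]
        rec = {"model": row["model"], "phase": row["phase"],
               "SE": ms.se, "SP": ms.sp, "PPV": ms.accuracy,
               "ppv_eq3": ms.ppv_eq3, "MCC": ms.mcc}
        if ms.auc is not None:
            rec["AUC"] = ms.auc
        sd = row.get("sd")
        if sd is not None:
            rec["MCC_sd"] = sd.mcc
        out.append(rec)
    return pd.DataFrame(out)
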