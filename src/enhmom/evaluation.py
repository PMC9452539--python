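"""Evaluation: Sn/Sp/Acc/MCC, Chou-style counts, cross-validation, ROC/PR.

Metrics exist in two algebraically equivalent formulations: the
conventional confusion-matrix form

    Sn = TP/(TP+FN),  Sp = TN/(TN+FP),
    Acc = (TP+TN)/total,
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

and the intuitive form over Chou's symbols (Y+ true positives in total,
Y- true negatives in total, Y+- positives predicted negative, Y-+
negatives predicted positive).  Both are implemented and must agree to
1e-12 whenever both are defined; the bijection between count systems is

    TP = Y+ - Y+-,  TN = Y- - Y-+,  FP = Y-+,  FN = Y+-.

Zero denominators yield NaN (an explicit undefined sentinel), except the
MCC whose zero denominator conventionally maps to 0.  Internal metrics are
fractions; percent formatting belongs to the reporting layer.

Cross-validation is stratified and seeded (k = 5, 10, or leave-one-out,
the jackknife); a fresh forest is trained per fold, predictions are pooled
into one confusion matrix for headline metrics, and per-fold metrics plus
continuous scores are retained for dispersion and ROC/PR analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    auc as _trapezoid_auc,
    average_precision_score,
    precision_recall_curve,
    roc_curve,
)
from sklearn.model_selection import LeaveOneOut, StratifiedKFold

from .classify import LAYER_CLASSES, POSITIVE_CLASS, ForestConfig, _layer_training_data
from .features import FeatureTable

UNDEFINED = float("nan")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class ChouCounts:
    """Totals-based counts: Y+ / Y- are class totals, Y+- / Y-+ the errors."""

    y_plus: int
    y_minus: int
    y_plus_as_minus: int
    y_minus_as_plus: int

    def __post_init__(self) -> None:
        if self.y_plus_as_minus > self.y_plus or self.y_minus_as_plus > self.y_minus:
            raise ValueError("error counts cannot exceed class totals")


@dataclass(frozen=True)
class Metrics:
    sn: float
    sp: float
    acc: float
    mcc: float
    auc: Optional[float] = None
    aupr: Optional[float] = None

    def as_dict(self) -> dict[str, float]:
        out = {"sn": self.sn, "sp": self.sp, "acc": self.acc, "mcc": self.mcc}
        if self.auc is not None:
            out["auc"] = self.auc
        if self.aupr is not None:
            out["aupr"] = self.aupr
        return out


def chou_convert(counts: ConfusionCounts) -> ChouCounts:
    return ChouCounts(
        y_plus=counts.tp + counts.fn,
        y_minus=counts.tn + counts.fp,
        y_plus_as_minus=counts.fn,
        y_minus_as_plus=counts.fp,
    )


def chou_invert(counts: ChouCounts) -> ConfusionCounts:
    return ConfusionCounts(
        tp=counts.y_plus - counts.y_plus_as_minus,
        tn=counts.y_minus - counts.y_minus_as_plus,
        fp=counts.y_minus_as_plus,
        fn=counts.y_plus_as_minus,
    )


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else UNDEFINED


def compute_metrics(counts: ConfusionCounts) -> Metrics:
    """Conventional-form metrics; NaN marks an undefined ratio, MCC(0/0) = 0."""
    if counts.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    sn = _safe_div(tp, tp + fn)
    sp = _safe_div(tn, tn + fp)
    acc = (tp + tn) / counts.total
    denom = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = (tp * tn - fp * fn) / denom if denom != 0 else 0.0
    return Metrics(sn=sn, sp=sp, acc=acc, mcc=mcc)


def compute_metrics_chou(counts: ChouCounts) -> Metrics:
    """Metrics in Chou's intuitive formulation (same conventions for 0/0)."""
    yp, ym = counts.y_plus, counts.y_minus
    ypm, ymp = counts.y_plus_as_minus, counts.y_minus_as_plus
    if yp + ym == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    sn = 1 - ypm / yp if yp != 0 else UNDEFINED
    sp = 1 - ymp / ym if ym != 0 else UNDEFINED
    acc = 1 - (ypm + ymp) / (yp + ym)
    if yp == 0 or ym == 0:
        mcc = 0.0
    else:
        inner = (1 + (ymp - ypm) / yp) * (1 + (ypm - ymp) / ym)
        mcc = (1 - (ypm / yp + ymp / ym)) / math.sqrt(inner) if inner > 0 else 0.0
    return Metrics(sn=sn, sp=sp, acc=acc, mcc=mcc)


def confusion_from_labels(
    y_true: Sequence[str], y_pred: Sequence[str], positive: str
) -> ConfusionCounts:
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    return ConfusionCounts(
        tp=int(((yt == positive) & (yp == positive)).sum()),
        tn=int(((yt != positive) & (yp != positive)).sum()),
        fp=int(((yt != positive) & (yp == positive)).sum()),
        fn=int(((yt == positive) & (yp != positive)).sum()),
    )


# ---------------------------------------------------------------------------
# score curves
# ---------------------------------------------------------------------------

def score_curves(
    y_true: Sequence[int] | Sequence[bool],
    scores: Sequence[float],
) -> dict[str, object]:
    """ROC and precision-recall curves with trapezoid AUC and step-wise AUPR.

    ``y_true`` is binary (1 = positive); scores are positive-class vote
    fractions in [0, 1].  A perfect ranker has AUC = AUPR = 1; a constant
    scorer has AUC = 0.5.
    """
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=float)
    if s.min() < 0 or s.max() > 1:
        raise ValueError("scores must lie in [0, 1]")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to draw score curves")
    fpr, tpr, roc_thresh = roc_curve(y, s)
    precision, recall, pr_thresh = precision_recall_curve(y, s)
    return {
        "roc": pd.DataFrame({"fpr": fpr, "tpr": tpr}),
        "auc": float(_trapezoid_auc(fpr, tpr)),
        "pr": pd.DataFrame({"recall": recall, "precision": precision}),
        "aupr": float(average_precision_score(y, s)),
    }


# ---------------------------------------------------------------------------
# cross-validation protocols
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    pooled: Metrics
    pooled_counts: ConfusionCounts
    per_fold: list[Metrics]
    fold_assignment: np.ndarray
    y_true: np.ndarray
    y_pred: np.ndarray
    scores: np.ndarray  # positive-class score per sample, from its test fold
    curves: dict[str, object]


def cross_validate(
    table: FeatureTable,
    layer: Literal[1, 2],
    k: int | Literal["loo"] = 5,
    config: ForestConfig | None = None,
    seed: int | None = None,
) -> CVResult:
    """Stratified k-fold (or jackknife) evaluation of one forest layer.

    Every sample is predicted exactly once by a forest that never saw it;
    headline metrics come from the pooled confusion matrix, per-fold
    metrics are kept for dispersion, and pooled scores feed ROC/PR.
    """
    config = config or ForestConfig()
    seed = config.random_seed if seed is None else seed
    X, y = _layer_training_data(table, layer)
    positive = POSITIVE_CLASS[layer]
    class_sizes = pd.Series(y).value_counts()
    if k == "loo":
        splitter = LeaveOneOut()
    else:
        if k < 2:
            raise ValueError("k must be >= 2")
        if k > class_sizes.min():
            raise ValueError(
                f"k={k} exceeds the smallest class size {class_sizes.min()}"
            )
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)

    n = len(y)
    fold_assignment = np.full(n, -1, dtype=int)
    y_pred = np.empty(n, dtype=object)
    scores = np.full(n, np.nan)
    per_fold: list[Metrics] = []
    for fold, (train_idx, test_idx) in enumerate(splitter.split(X, y)):
        model = RandomForestClassifier(
            n_estimators=config.n_trees,
            bootstrap=True,
            max_features=config.max_features,
            random_state=seed,
            n_jobs=1,
        )
        model.fit(X[train_idx], y[train_idx])
        pos_col = list(model.classes_).index(positive)
        y_pred[test_idx] = model.predict(X[test_idx])
        scores[test_idx] = model.predict_proba(X[test_idx])[:, pos_col]
        fold_assignment[test_idx] = fold
        if k != "loo":  # single-row folds have no meaningful per-fold metrics
            per_fold.append(
                compute_metrics(
                    confusion_from_labels(y[test_idx], y_pred[test_idx], positive)
                )
            )

    pooled_counts = confusion_from_labels(y, y_pred.astype(str), positive)
    curves = score_curves((y == positive).astype(int), scores)
    pooled = Metrics(
        **compute_metrics(pooled_counts).as_dict(),
        auc=curves["auc"],
        aupr=curves["aupr"],
    )
    return CVResult(
        pooled=pooled,
        pooled_counts=pooled_counts,
        per_fold=per_fold,
        fold_assignment=fold_assignment,
        y_true=y,
        y_pred=y_pred.astype(str),
        scores=scores,
        curves=curves,
    )


def metrics_percent(metrics: Metrics) -> dict[str, float]:
    """Reporting-layer formatting: Sn/Sp/Acc as percentages, MCC/AUC as fractions."""
    out = metrics.as_dict()
    return {
        key: round(value * 100, 2) if key in ("sn", "sp", "acc") else round(value, 4)
        for key, value in out.items()
    }
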