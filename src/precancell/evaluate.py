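"""Performance metrics and cross-validation.

Malignant is the positive class throughout. Reported metrics: accuracy,
sensitivity, specificity, balanced accuracy (the arithmetic mean of
sensitivity and specificity) and AUROC. AUROC is computed rank-based
(Mann–Whitney): the probability that a randomly chosen malignant cell
outscores a randomly chosen non-malignant cell, ties counted one half.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .classify import knn_base_classify
from .markers import MALIGNANT, MarkerGeneSet, ReferenceDataset
from .matrix import minmax_scale


@dataclass
class ConfusionSummary:
    """2×2 confusion counts with malignant as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def false_negative_rate(self) -> float:
        denom = self.tp + self.fn
        return self.fn / denom if denom else math.nan

    @property
    def false_positive_rate(self) -> float:
        denom = self.fp + self.tn
        return self.fp / denom if denom else math.nan


@dataclass
class PerformanceReport:
    accuracy: float
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    auroc: float = math.nan


def _as_positive_mask(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype == bool:
        return arr
    return arr.astype(str) == MALIGNANT


def confusion_metrics(truth, predicted) -> tuple[ConfusionSummary, PerformanceReport]:
    """Confusion counts and threshold metrics for hard label predictions.

    ``truth``/``predicted`` are label sequences (``malignant`` /
    ``non_malignant``, or booleans with True = malignant). If the truth
    contains a single class the undefined rate is NaN with a warning;
    AUROC is left NaN (see :func:`auroc`).
    """
    t = _as_positive_mask(truth)
    p = _as_positive_mask(predicted)
    if t.shape != p.shape:
        raise ValueError("truth and predicted must have equal length")
    cm = ConfusionSummary(
        tp=int(np.sum(t & p)),
        fp=int(np.sum(~t & p)),
        tn=int(np.sum(~t & ~p)),
        fn=int(np.sum(t & ~p)),
    )
    n_pos = cm.tp + cm.fn
    n_neg = cm.tn + cm.fp
    if n_pos == 0 or n_neg == 0:
        warnings.warn(
            "truth contains a single class; sensitivity or specificity undefined",
            RuntimeWarning,
            stacklevel=2,
        )
    sensitivity = cm.tp / n_pos if n_pos else math.nan
    specificity = cm.tn / n_neg if n_neg else math.nan
    accuracy = (cm.tp + cm.tn) / cm.total if cm.total else math.nan
    return cm, PerformanceReport(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        balanced_accuracy=(sensitivity + specificity) / 2,
    )


def auroc(scores, truth) -> float:
    """Rank-based AUROC of continuous malignancy scores.

    Equals the fraction of (malignant, non-malignant) pairs in which the
    malignant cell has the higher score, counting tied pairs 0.5.
    """
    s = np.asarray(scores, dtype=float)
    pos = _as_positive_mask(truth)
    if s.shape != pos.shape:
        raise ValueError("scores and truth must have equal length")
    n_pos = int(pos.sum())
    n_neg = int(s.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("auroc requires both classes in truth")
    ranks = rankdata(s)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def cross_validate(
    ds: ReferenceDataset,
    markers: MarkerGeneSet,
    folds: int = 10,
    k: int = 5,
    seed: int = 0,
    metric: str = "euclidean",
) -> tuple[PerformanceReport, ConfusionSummary]:
    """Stratified k-fold cross-validation of a single-reference k-NN
    classifier within one dataset.

    Each fold's held-out cells are predicted by one base classifier whose
    reference is the remaining folds (no ensemble); predictions are pooled
    over all folds before computing metrics. Train and test partitions are
    each min–max scaled with their own per-gene statistics, matching how
    reference and query datasets are scaled at prediction time. The
    continuous score for AUROC is the malignant-neighbor fraction.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    n_mal, n_non = ds.class_counts()
    if min(n_mal, n_non) < folds:
        raise ValueError(f"each class needs at least {folds} cells for {folds}-fold CV")

    features = [g for g in markers.all_genes if g in set(ds.expr.gene_ids)]
    if not features:
        raise ValueError("dataset shares no genes with the marker set")

    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    y = ds.malignant_mask
    pooled_truth = np.zeros(ds.expr.n_cells, dtype=bool)
    pooled_pred = np.zeros(ds.expr.n_cells, dtype=bool)
    pooled_score = np.zeros(ds.expr.n_cells, dtype=float)

    cols = np.arange(ds.expr.n_cells)
    for train_idx, test_idx in splitter.split(cols, y):
        train = ReferenceDataset(
            expr=minmax_scale(
                _subset_cells(ds.expr, train_idx).subset_genes(features)
            ),
            labels=ds.labels[train_idx],
            name=ds.name,
        )
        test_expr = minmax_scale(_subset_cells(ds.expr, test_idx).subset_genes(features))
        votes = knn_base_classify(train, test_expr, features, k=k, metric=metric)
        pooled_truth[test_idx] = y[test_idx]
        pooled_pred[test_idx] = [v.label == MALIGNANT for v in votes]
        pooled_score[test_idx] = [v.malignant_neighbor_fraction for v in votes]

    cm, report = confusion_metrics(pooled_truth, pooled_pred)
    report.auroc = auroc(pooled_score, pooled_truth)
    return report, cm


def _subset_cells(expr, idx):
    import dataclasses

    return dataclasses.replace(
        expr,
        values=expr.values[:, idx],
        cell_ids=[expr.cell_ids[i] for i in idx],
    )
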