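"""Accuracy, binary and one-versus-all AUC, and the two testing protocols
(stratified 10-fold cross-validation; fixed train/test split).

Both protocols refit the [0,1] normalizer and the SVM grid search on the
training portion of every fold only; an audit log records which rows each
stage touched so train/test isolation is assertable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .ensemble import (DEFAULT_C_GRID, DEFAULT_GAMMA_GRID, predict_scores,
                       train_classifier, weighted_sum_fusion)


def accuracy(predicted, truth) -> float:
    """Fraction of samples correctly classified."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must have equal length")
    if predicted.size == 0:
        raise ValueError("empty input")
    return float((predicted == truth).mean())


def auc_binary(scores, truth, positive=None) -> float:
    """Rank-based area under the ROC curve (higher score = positive;
    ties count one half)."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    classes = np.unique(truth)
    if len(classes) != 2:
        raise ValueError("binary AUC needs exactly 2 classes in truth")
    if positive is None:
        positive = classes[1]
    return float(roc_auc_score(truth == positive, scores))


def auc_ovr(score_matrix, truth, classes=None) -> float:
    """One-versus-all AUC: unweighted mean of per-class one-vs-rest AUCs.

    ``classes`` gives the column order of the score matrix (defaults to
    the sorted unique labels); classes absent from ``truth`` are skipped
    with a warning."""
    scores = np.asarray(score_matrix, dtype=float)
    truth = np.asarray(truth)
    if classes is None:
        classes = np.unique(truth)
    if scores.shape[1] != len(classes):
        raise ValueError("one score column per class required")
    aucs = []
    for col, cls in enumerate(classes):
        mask = truth == cls
        if not mask.any() or mask.all():
            warnings.warn(f"class {cls!r} has no positive or no negative "
                          "samples; skipped in one-vs-all AUC")
            continue
        aucs.append(roc_auc_score(mask, scores[:, col]))
    if not aucs:
        raise ValueError("no class admits a one-vs-rest AUC")
    return float(np.mean(aucs))


# ---------------------------------------------------------------------------
# protocols

@dataclass
class AuditLog:
    """Row indices touched by each training-side stage, per fold."""

    entries: list[tuple[str, int, frozenset]] = field(default_factory=list)

    def record(self, stage: str, fold: int, rows) -> None:
        self.entries.append((stage, fold, frozenset(int(r) for r in rows)))

    def assert_isolation(self, test_rows_by_fold: dict[int, frozenset]
                         ) -> None:
        """Raise if any training-side stage touched a test row of its
        fold."""
        for stage, fold, rows in self.entries:
            leaked = rows & test_rows_by_fold[fold]
            if leaked:
                raise AssertionError(
                    f"{stage} in fold {fold} touched test rows "
                    f"{sorted(leaked)[:5]}")


@dataclass
class EvaluationResult:
    """Headline metrics with the per-fold breakdown that produced them.

    ``accuracy`` and ``auc`` are fold averages.  ``pooled_scores`` holds the
    out-of-fold fused score matrix (rows covered by some test fold listed in
    ``pooled_rows``), from which :func:`pooled_auc` computes one ROC over all
    held-out samples — a lower-variance summary for small benchmarks.
    """

    accuracy: float
    auc: float
    protocol: str
    per_fold: list[dict] = field(default_factory=list)
    audit: AuditLog | None = None
    pooled_scores: np.ndarray | None = None
    pooled_rows: np.ndarray | None = None


def pooled_auc(result: EvaluationResult, labels) -> float:
    """One-versus-all AUC of the pooled out-of-fold scores."""
    if result.pooled_scores is None:
        raise ValueError("result carries no pooled scores")
    labels = np.asarray(labels)
    rows = result.pooled_rows
    return auc_ovr(result.pooled_scores[rows], labels[rows],
                   classes=np.unique(labels))


def cv10_folds(labels, seed: int, n_folds: int = 10):
    """Stratified, seeded fold assignment: a disjoint, exhaustive
    partition balanced within one sample per class."""
    labels = np.asarray(labels)
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(cv.split(np.zeros(len(labels)), labels))


def run_protocol(feature_tables, labels, weights=None,
                 protocol: str = "cv10", seed: int = 0, *,
                 holdout_test=None, n_folds: int = 10,
                 c_grid=DEFAULT_C_GRID, gamma_grid=DEFAULT_GAMMA_GRID,
                 use_probabilities: bool = True) -> EvaluationResult:
    """Train the weighted-sum ensemble under a testing protocol.

    ``feature_tables`` is one (n_samples x dim) table per ensemble
    component; ``weights`` the sum-rule weights (unit by default).
    ``protocol`` is ``"cv10"`` (stratified seeded folds) or ``"holdout"``
    (``holdout_test`` gives the test-row indices or boolean mask).  Per
    fold, the normalizer and the grid search are refit on the training
    portion only, and the audit log records the rows each stage used.
    """
    tables = [np.asarray(t, dtype=float) for t in feature_tables]
    labels = np.asarray(labels)
    n = len(labels)
    if any(t.shape[0] != n for t in tables):
        raise ValueError("all feature tables must have one row per sample")
    if weights is None:
        weights = np.ones(len(tables))

    if protocol == "cv10":
        folds = cv10_folds(labels, seed, n_folds)
    elif protocol == "holdout":
        if holdout_test is None:
            raise ValueError("holdout protocol needs a declared test split")
        test_idx = np.asarray(holdout_test)
        if test_idx.dtype == bool:
            test_idx = np.flatnonzero(test_idx)
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        folds = [(train_idx, test_idx)]
    else:
        raise ValueError(f"unknown protocol {protocol!r}")

    audit = AuditLog()
    per_fold = []
    pooled = None
    for fold_no, (train_idx, test_idx) in enumerate(folds):
        train_classes = np.unique(labels[train_idx])
        if len(train_classes) < len(np.unique(labels)):
            raise ValueError(f"fold {fold_no}: stratification failure, a "
                             "class is missing from the training portion")
        score_mats = []
        for table in tables:
            audit.record("normalizer+grid_search", fold_no, train_idx)
            scorer = train_classifier(
                table[train_idx], labels[train_idx], seed=seed,
                c_grid=c_grid, gamma_grid=gamma_grid,
                use_probabilities=use_probabilities)
            score_mats.append(predict_scores(scorer, table[test_idx]))
        fused = weighted_sum_fusion(score_mats, weights)
        classes = np.unique(labels)
        if pooled is None:
            pooled = np.zeros((n, fused.shape[1]))
        pooled[test_idx] = fused
        pred = classes[np.argmax(fused, axis=1)]
        per_fold.append({
            "fold": fold_no,
            "test_rows": frozenset(int(i) for i in test_idx),
            "accuracy": accuracy(pred, labels[test_idx]),
            "auc": auc_ovr(fused, labels[test_idx], classes=classes),
        })
    audit.assert_isolation({f["fold"]: f["test_rows"] for f in per_fold})
    covered = sorted(set().union(*(f["test_rows"] for f in per_fold)))
    return EvaluationResult(
        accuracy=float(np.mean([f["accuracy"] for f in per_fold])),
        auc=float(np.mean([f["auc"] for f in per_fold])),
        protocol=protocol, per_fold=per_fold, audit=audit,
        pooled_scores=pooled, pooled_rows=np.array(covered))
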