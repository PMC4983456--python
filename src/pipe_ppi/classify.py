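"""Max-margin classification over precomputed kernel matrices, and the three
evaluation protocols: within-corpus cross-validation (CV), cross-learning
(CL: train on the union of the other corpora) and cross-corpus (CC: train on
one corpus, test on each other).

Metrics are precision, recall and F1 per corpus, plus a micro-average in two
modes: "pooled" (F1 from summed TP/FP/FN) and "printed"
(sum_k 2 P_k R_k / sum_k (P_k + R_k)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "TrainConfig",
    "Metrics",
    "KernelSVM",
    "derive_c",
    "train",
    "predict",
    "compute_metrics",
    "micro_average",
    "stratified_fold_indices",
    "cross_validation",
    "cross_learning",
    "cross_corpus",
]


@dataclass
class TrainConfig:
    """SVM penalty configuration; ``derived_c`` sets C to #neg/#pos."""

    C: float = 1.0
    derived_C: bool = True

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")


@dataclass
class Metrics:
    """Confusion counts with derived precision/recall/F1.

    An undefined ratio (0/0) is reported as 0 and flagged.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    undefined_precision: bool = False
    undefined_recall: bool = False

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0

    @staticmethod
    def from_pr(precision: float, recall: float) -> float:
        """F1 from already-computed precision and recall."""
        if precision + recall == 0:
            return 0.0
        return 2 * precision * recall / (precision + recall)


@dataclass
class KernelSVM:
    """A fitted max-margin model over a precomputed similarity matrix."""

    svc: SVC
    n_train: int
    C: float
    train_labels: np.ndarray = field(repr=False, default=None)


def derive_c(labels: Sequence[int]) -> float:
    """C = #negatives / #positives, the class-ratio penalty convention."""
    y = np.asarray(labels)
    n_pos = int((y > 0).sum())
    n_neg = int((y <= 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("deriving C requires both classes in the training labels")
    return n_neg / n_pos


def train(gram: np.ndarray, labels: Sequence[int],
          config: TrainConfig | None = None) -> KernelSVM:
    """Fit an SVM on a precomputed train x train kernel matrix.

    Labels must be in {+1, -1} with both classes present.
    """
    config = config or TrainConfig()
    y = np.asarray(labels)
    if set(np.unique(y)) - {-1, 1}:
        raise ValueError("labels must be +1/-1")
    if len(np.unique(y)) < 2:
        raise ValueError("training requires both classes")
    gram = np.asarray(gram)
    if gram.shape[0] != gram.shape[1] or gram.shape[0] != len(y):
        raise ValueError("gram matrix shape does not match labels")
    C = derive_c(y) if config.derived_C else config.C
    svc = SVC(kernel="precomputed", C=C)
    svc.fit(gram, y)
    return KernelSVM(svc=svc, n_train=len(y), C=C, train_labels=y)


def predict(model: KernelSVM, kernel_rows: np.ndarray) -> np.ndarray:
    """Predict labels from kernel rows against the training candidates.

    The decision boundary itself (decision value exactly 0) is called
    positive.
    """
    rows = np.atleast_2d(np.asarray(kernel_rows, dtype=float))
    if rows.shape[1] != model.n_train:
        raise ValueError(
            f"kernel rows have {rows.shape[1]} columns; model was trained on "
            f"{model.n_train} candidates")
    scores = model.svc.decision_function(rows)
    return np.where(scores >= 0.0, 1, -1)


def compute_metrics(pred: Sequence[int], gold: Sequence[int]) -> Metrics:
    pred = np.asarray(pred)
    gold = np.asarray(gold)
    if pred.shape != gold.shape:
        raise ValueError("pred and gold must have equal length")
    tp = int(((pred > 0) & (gold > 0)).sum())
    fp = int(((pred > 0) & (gold <= 0)).sum())
    tn = int(((pred <= 0) & (gold <= 0)).sum())
    fn = int(((pred <= 0) & (gold > 0)).sum())
    return Metrics(tp=tp, fp=fp, tn=tn, fn=fn,
                   undefined_precision=(tp + fp) == 0,
                   undefined_recall=(tp + fn) == 0)


def micro_average(per_corpus: list[Metrics], mode: str = "pooled") -> float:
    """Micro-averaged F-measure across corpora.

    mode "pooled" computes F1 from summed TP/FP/FN; mode "printed" evaluates
    sum_k 2 P_k R_k / sum_k (P_k + R_k) from the per-corpus precision/recall
    values.
    """
    if not per_corpus:
        raise ValueError("micro_average needs at least one corpus")
    if mode == "pooled":
        tp = sum(m.tp for m in per_corpus)
        fp = sum(m.fp for m in per_corpus)
        fn = sum(m.fn for m in per_corpus)
        pooled = Metrics(tp=tp, fp=fp, tn=sum(m.tn for m in per_corpus), fn=fn)
        return pooled.f1
    if mode == "printed":
        num = sum(2 * m.precision * m.recall for m in per_corpus)
        den = sum(m.precision + m.recall for m in per_corpus)
        return num / den if den else 0.0
    raise ValueError(f"unknown micro-average mode {mode!r}")


def stratified_fold_indices(labels: Sequence[int], folds: int, seed: int) -> list[np.ndarray]:
    """Seeded stratified fold assignment; degrades to plain folds (with a
    warning) when a class has fewer members than folds."""
    y = np.asarray(labels)
    counts = [int((y == v).sum()) for v in np.unique(y)]
    if min(counts) < folds:
        warnings.warn(
            "a class has fewer members than folds; using unstratified folds",
            stacklevel=2)
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
        return [test for _, test in splitter.split(y)]
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return [test for _, test in splitter.split(np.zeros_like(y), y)]


def cross_validation(instances: list, labels: Sequence[int], fit_predict,
                     folds: int = 10, seed: int = 0) -> Metrics:
    """k-fold CV of an arbitrary fit/predict pipeline, metrics pooled over
    held-out folds.

    ``fit_predict(train_instances, train_labels, test_instances)`` must
    return predicted labels for the test instances; it is re-run per fold so
    every data-derived artifact (patterns, stop words, C) comes from the
    training folds only.
    """
    y = np.asarray(labels)
    fold_tests = stratified_fold_indices(y, folds, seed)
    pred = np.zeros_like(y)
    for test_idx in fold_tests:
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[test_idx] = False
        train_idx = np.where(train_mask)[0]
        train_inst = [instances[i] for i in train_idx]
        test_inst = [instances[i] for i in test_idx]
        pred[test_idx] = fit_predict(train_inst, y[train_idx], test_inst)
    return compute_metrics(pred, y)


def cross_learning(corpora: dict[str, tuple[list, Sequence[int]]],
                   fit_predict) -> dict[str, Metrics]:
    """Hold out each corpus once, training on the union of the others."""
    if len(corpora) < 2:
        raise ValueError("cross-learning requires at least two corpora")
    out: dict[str, Metrics] = {}
    for name, (test_inst, test_y) in corpora.items():
        train_inst: list = []
        train_y: list[int] = []
        for other, (inst, yy) in corpora.items():
            if other == name:
                continue
            train_inst.extend(inst)
            train_y.extend(list(yy))
        pred = fit_predict(train_inst, np.asarray(train_y), test_inst)
        out[name] = compute_metrics(pred, np.asarray(test_y))
    return out


def cross_corpus(corpora: dict[str, tuple[list, Sequence[int]]], fit_predict,
                 diagonal_cv: bool = False, folds: int = 10,
                 seed: int = 0) -> dict[str, dict[str, Metrics]]:
    """Full train x test matrix; off-diagonal cells train on one corpus and
    test on another, the diagonal optionally holds CV results."""
    if len(corpora) < 2:
        raise ValueError("cross-corpus requires at least two corpora")
    out: dict[str, dict[str, Metrics]] = {}
    for train_name, (train_inst, train_y) in corpora.items():
        row: dict[str, Metrics] = {}
        for test_name, (test_inst, test_y) in corpora.items():
            if test_name == train_name:
                if diagonal_cv:
                    row[test_name] = cross_validation(
                        train_inst, train_y, fit_predict, folds=folds, seed=seed)
                continue
            pred = fit_predict(train_inst, np.asarray(train_y), test_inst)
            row[test_name] = compute_metrics(pred, np.asarray(test_y))
        out[train_name] = row
    return out
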