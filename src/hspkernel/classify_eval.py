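"""Precomputed-kernel classification and evaluation.

The maximum-margin classifier is a support-vector machine consumed through
the precomputed-kernel contract: it only ever sees Gram matrices, so the
kernel stays the single point where graph structure enters.  Evaluation
reports the confusion counts plus precision, recall, F-score, accuracy,
Matthews correlation and AUC; AUC is the rank statistic (the probability
that a random positive outscores a random negative, ties counted 1/2),
computed on raw decision values.

Cross-validation splits at the *document* level so no sentence of one
document ever appears in both a training and a test fold.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC

from .errors import InputError
from .graph_model import SentenceGraph
from .kernel import HSPKernel

__all__ = [
    "EvaluationReport",
    "report_from_counts",
    "rank_auc",
    "evaluate",
    "train",
    "HSPClassifier",
    "cross_validate",
]


@dataclass
class EvaluationReport:
    """Confusion counts and derived metrics for a binary decision task.

    Metric conventions: precision/recall/F default to 0 when their
    denominator is 0; the MCC denominator-zero case is defined as 0.
    ``auc`` is None when the report was built from counts alone.  For
    cross-validation, ``per_fold`` holds one report per test fold,
    ``f_std``/``auc_std`` their standard deviations, and the top-level
    metrics are micro-averaged (pooled confusion counts); ``f_macro`` and
    ``auc_macro`` average the per-fold metrics instead.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f_score: float
    accuracy: float
    mcc: float
    auc: float | None = None
    per_fold: list["EvaluationReport"] | None = None
    f_std: float | None = None
    auc_std: float | None = None
    f_macro: float | None = None
    auc_macro: float | None = None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_dict(self) -> dict:
        d = asdict(self)
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.as_dict(), **kwargs)

    def table(self) -> str:
        """One-row text table in the conventional column order."""
        header = "TP\tFP\tFN\tTN\tP\tR\tF\tAcc\tMCC\tAUC"
        auc = f"{100 * self.auc:.1f}" if self.auc is not None else "-"
        row = (
            f"{self.tp}\t{self.fp}\t{self.fn}\t{self.tn}\t"
            f"{100 * self.precision:.1f}\t{100 * self.recall:.1f}\t"
            f"{100 * self.f_score:.1f}\t{100 * self.accuracy:.1f}\t"
            f"{100 * self.mcc:.1f}\t{auc}"
        )
        return header + "\n" + row


def report_from_counts(tp: int, fp: int, fn: int, tn: int, auc: float | None = None) -> EvaluationReport:
    """Derive all confusion-based metrics from the four counts."""
    p = tp / (tp + fp) if tp + fp > 0 else 0.0
    r = tp / (tp + fn) if tp + fn > 0 else 0.0
    f = 2 * p * r / (p + r) if p + r > 0 else 0.0
    n = tp + fp + fn + tn
    acc = (tp + tn) / n if n > 0 else 0.0
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom > 0 else 0.0
    return EvaluationReport(
        tp=tp, fp=fp, fn=fn, tn=tn, precision=p, recall=r, f_score=f, accuracy=acc, mcc=mcc, auc=auc
    )


def rank_auc(decision_values: Sequence[float], gold: Sequence[bool]) -> float:
    """Mann-Whitney rank AUC with ties counted 1/2; 0.5 if one class is absent."""
    scores = np.asarray(decision_values, dtype=float)
    y = np.asarray(gold, dtype=bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        return 0.5
    ranks = rankdata(scores)  # average ranks on ties
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def evaluate(decision_values: Sequence[float], gold: Sequence[bool]) -> EvaluationReport:
    """Threshold decision values at 0 and report all metrics."""
    scores = np.asarray(decision_values, dtype=float)
    y = np.asarray(gold, dtype=bool)
    if scores.shape != y.shape or scores.size == 0:
        raise InputError(
            f"decision values and gold labels must be equal-length and non-empty "
            f"(got {scores.shape} vs {y.shape})"
        )
    pred = scores > 0
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    fn = int(np.sum(~pred & y))
    tn = int(np.sum(~pred & ~y))
    return report_from_counts(tp, fp, fn, tn, auc=rank_auc(scores, y))


def train(gram: np.ndarray, labels: Sequence[bool], C: float = 1.0) -> SVC:
    """Fit the margin classifier on a precomputed training Gram matrix.

    Deterministic for fixed inputs.  Decision value for instance i is
    sum_j alpha_j y_j K(i, j) + b over the support set.
    """
    y = np.asarray(labels, dtype=int)
    if len(set(y.tolist())) < 2:
        raise InputError("training set contains a single class")
    gram = np.asarray(gram, dtype=float)
    if gram.shape[0] != gram.shape[1] or not np.allclose(gram, gram.T, atol=1e-8):
        raise InputError("training Gram matrix must be square and symmetric")
    svc = SVC(kernel="precomputed", C=C)
    svc.fit(gram, y)
    return svc


class HSPClassifier(BaseEstimator, ClassifierMixin):
    """Sentence-graph classifier: HSP kernel + precomputed-kernel SVM.

    ``fit`` takes a sequence of :class:`SentenceGraph` and boolean labels;
    ``decision_function`` and ``predict`` take graphs.  All kernel
    parameters are exposed flat so the estimator composes with scikit-learn
    model selection.
    """

    def __init__(
        self,
        C: float = 1.0,
        D: int = 24,
        R: int = 2,
        beta: float = 0.6,
        gamma: float = 0.25,
        w: float = 1.0,
        rot_center: int = 1,
        rot_in: int = 2,
        rot_out: int = 3,
        normalize: bool = True,
        symmetrize_walks: bool = True,
        tag_components: bool = True,
    ):
        self.C = C
        self.D = D
        self.R = R
        self.beta = beta
        self.gamma = gamma
        self.w = w
        self.rot_center = rot_center
        self.rot_in = rot_in
        self.rot_out = rot_out
        self.normalize = normalize
        self.symmetrize_walks = symmetrize_walks
        self.tag_components = tag_components

    def _kernel_params(self) -> dict:
        p = self.get_params()
        p.pop("C")
        return p

    def fit(self, X: Sequence[SentenceGraph], y) -> "HSPClassifier":
        self.kernel_ = HSPKernel(**self._kernel_params())
        gram = self.kernel_.fit_transform(X)
        self.svc_ = train(gram, y, C=self.C)
        self.classes_ = self.svc_.classes_
        return self

    def decision_function(self, X: Sequence[SentenceGraph]) -> np.ndarray:
        return self.svc_.decision_function(self.kernel_.transform(X))

    def predict(self, X: Sequence[SentenceGraph]) -> np.ndarray:
        return self.svc_.predict(self.kernel_.transform(X))

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y, dtype=int)))


def assign_folds(document_ids: Sequence[str], n_folds: int, seed: int = 0) -> list[int]:
    """Deterministic document-level fold assignment.

    Documents are shuffled by the seed and dealt round-robin, so every
    sentence of a document lands in the same fold and shuffling the
    *instance* order never changes the assignment.
    """
    docs = sorted(set(document_ids))
    if len(docs) < n_folds:
        raise InputError(f"{len(docs)} documents cannot fill {n_folds} folds")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(docs)))
    fold_of_doc = {docs[d]: i % n_folds for i, d in enumerate(order)}
    return [fold_of_doc[d] for d in document_ids]


def cross_validate(
    graphs: Sequence[SentenceGraph],
    labels: Sequence[bool],
    document_ids: Sequence[str],
    n_folds: int = 10,
    seed: int = 0,
    **classifier_params,
) -> EvaluationReport:
    """Document-level k-fold cross-validation of the full pipeline.

    Each fold refits the vocabulary and the classifier on its training
    portion only (test-fold labels unseen at fit time).  The top-level
    report pools decisions over all folds (micro); per-fold reports and the
    macro means/standard deviations of F and AUC are attached.
    """
    if n_folds < 2:
        raise InputError("need at least 2 folds")
    labels = list(labels)
    folds = assign_folds(document_ids, n_folds, seed)
    all_scores: list[float] = []
    all_gold: list[bool] = []
    per_fold: list[EvaluationReport] = []
    for fold in range(n_folds):
        train_idx = [i for i, f in enumerate(folds) if f != fold]
        test_idx = [i for i, f in enumerate(folds) if f == fold]
        if not test_idx:
            continue
        clf = HSPClassifier(**classifier_params)
        clf.fit([graphs[i] for i in train_idx], [labels[i] for i in train_idx])
        scores = clf.decision_function([graphs[i] for i in test_idx])
        gold = [labels[i] for i in test_idx]
        per_fold.append(evaluate(scores, gold))
        all_scores.extend(scores.tolist())
        all_gold.extend(gold)
    pooled = evaluate(all_scores, all_gold)
    fs = [r.f_score for r in per_fold]
    aucs = [r.auc for r in per_fold]
    pooled.per_fold = per_fold
    pooled.f_std = float(np.std(fs))
    pooled.auc_std = float(np.std(aucs))
    pooled.f_macro = float(np.mean(fs))
    pooled.auc_macro = float(np.mean(aucs))
    return pooled
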