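"""Proportional cross-validation, the balanced error metric, and classifiers.

Class imbalance is endemic in clinical microbiome cohorts, so model quality
is measured by the mean per-class error rate: the unweighted average over
classes of the fraction of that class misclassified.  Cross-validation folds
are proportional (stratified): every fold carries each class in proportion
±1 sample.

Classifiers plug in through a minimal fit/predict contract.  Provided:

* :class:`KnnClassifier` — distance-weighted kNN (weights 1/d², an exact-zero
  distance short-circuits to that neighbour's label), on standardized inputs;
* :class:`SvmRbf` — RBF-kernel SVM with kernel K(x, y) = exp(−‖x−y‖²/c);
* :class:`CascadeClassifier` — three-class cascade: control vs rest, then the
  two remaining classes;
* :func:`balanced_vote_train_predict` — the imbalanced two-class scheme that
  clusters the majority class into subgroups and lets one model per subgroup
  vote.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Protocol, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.svm import SVC

from .data_model import class_summary

__all__ = [
    "FoldAssignment",
    "proportional_kfold",
    "mean_per_class_error",
    "knn_predict",
    "KnnClassifier",
    "SvmRbf",
    "CascadeClassifier",
    "kmeans_cluster",
    "cascade_classify_3class",
    "balanced_vote_train_predict",
    "BalancedVoteClassifier",
]


class ClassifierContract(Protocol):
    def fit(self, X, labels): ...

    def predict(self, X): ...


@dataclass
class FoldAssignment:
    fold_of_sample: np.ndarray
    k: int

    def split(self):
        for f in range(self.k):
            test = self.fold_of_sample == f
            yield np.nonzero(~test)[0], np.nonzero(test)[0]


def proportional_kfold(labels, k: int, seed: int) -> FoldAssignment:
    """Stratified k-fold assignment: shuffle within class, deal round-robin."""
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    summ = class_summary(labels)
    for name, n_k in zip(summ.class_names, summ.counts):
        if n_k < k:
            raise ValueError(
                f"class {name!r} has {n_k} samples, fewer than k={k} folds"
            )
    rng = np.random.default_rng(seed)
    fold = np.empty(len(labels), dtype=int)
    for name in summ.class_names:
        idx = np.nonzero(labels == name)[0]
        idx = rng.permutation(idx)
        fold[idx] = np.arange(idx.size) % k
    return FoldAssignment(fold, k)


def mean_per_class_error(true_labels, predicted_labels) -> float:
    """Unweighted mean over classes of the per-class misclassification rate."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError("length mismatch")
    summ = class_summary(t)
    errs = []
    for name in summ.class_names:
        m = t == name
        errs.append(float(np.mean(p[m] != name)))
    return float(np.mean(errs))


# ---------------------------------------------------------------------------
# k-nearest neighbour with inverse-square-distance voting
# ---------------------------------------------------------------------------


def knn_predict(train_X, train_labels, query_X, k: int):
    """Distance-weighted kNN vote with weights 1/d².

    A query coinciding exactly with a training sample takes that sample's
    label (the first such neighbour in training order).  Vote ties go to the
    class appearing first in the training labels.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    train_X = np.asarray(train_X, dtype=float)
    query_X = np.atleast_2d(np.asarray(query_X, dtype=float))
    train_labels = np.asarray(train_labels)
    if k > train_X.shape[0]:
        raise ValueError("k exceeds the number of training samples")
    classes = list(dict.fromkeys(train_labels.tolist()))
    class_rank = {c: r for r, c in enumerate(classes)}
    D = cdist(query_X, train_X)
    out = []
    for q in range(query_X.shape[0]):
        d = D[q]
        zero = np.nonzero(d == 0.0)[0]
        if zero.size:
            if len({train_labels[z] for z in zero}) > 1:
                warnings.warn(
                    "multiple zero-distance neighbours with conflicting "
                    "labels; using the first in training order"
                )
            out.append(train_labels[zero[0]])
            continue
        nn = np.argsort(d, kind="stable")[:k]
        votes: dict = {}
        for i in nn:
            votes[train_labels[i]] = votes.get(train_labels[i], 0.0) + 1.0 / d[i] ** 2
        best = max(votes.items(), key=lambda kv: (kv[1], -class_rank[kv[0]]))
        out.append(best[0])
    return np.array(out)


class KnnClassifier:
    """kNN contract wrapper; standardizes features on training statistics.

    Features constant within the training set get unit scale (they then
    contribute nothing to distances).  ``k="cv"`` picks k over 1..10 by
    proportional CV on the training data.
    """

    def __init__(self, k: int | str = 1, cv_folds: int = 5, seed: int = 0):
        self.k = k
        self.cv_folds = cv_folds
        self.seed = seed

    def _scale(self, X):
        return (np.asarray(X, dtype=float) - self._means) / self._stds

    def fit(self, X, labels):
        X = np.asarray(X, dtype=float)
        self._means = X.mean(axis=0)
        stds = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.ones(X.shape[1])
        self._stds = np.where(stds > 0, stds, 1.0)
        self._train = self._scale(X)
        self._labels = np.asarray(labels)
        if self.k == "cv":
            self.k_ = self._select_k()
        else:
            self.k_ = int(self.k)
        return self

    def _select_k(self) -> int:
        grid = range(1, min(10, self._train.shape[0] - 1) + 1)
        folds = proportional_kfold(self._labels, self.cv_folds, self.seed)
        best_k, best_err = 1, np.inf
        for k in grid:
            errs = []
            for tr, te in folds.split():
                pred = knn_predict(
                    self._train[tr], self._labels[tr], self._train[te], k
                )
                errs.append(mean_per_class_error(self._labels[te], pred))
            err = float(np.mean(errs))
            if err < best_err - 1e-12:
                best_k, best_err = k, err
        return best_k

    def predict(self, X):
        return knn_predict(self._train, self._labels, self._scale(X), self.k_)

    @property
    def description(self) -> str:
        return f"kNN(k={self.k})"


class SvmRbf:
    """RBF-kernel SVM with kernel exp(−‖x−y‖²/c).

    ``c`` maps to sklearn's gamma = 1/c.  ``c=None`` uses the scale heuristic
    (gamma="scale"); ``c="cv"`` selects c over a geometric grid by
    proportional CV on the training data at fit time.
    """

    _C_GRID = (0.25, 1.0, 4.0, 16.0, 64.0, 256.0)

    def __init__(self, c: float | str | None = None, cv_folds: int = 3, seed: int = 0):
        self.c = c
        self.cv_folds = cv_folds
        self.seed = seed

    def _make(self, c):
        gamma = "scale" if c is None else 1.0 / float(c)
        return SVC(kernel="rbf", gamma=gamma, C=1.0)

    def fit(self, X, labels):
        X = np.asarray(X, dtype=float)
        labels = np.asarray(labels)
        c = self.c
        if c == "cv":
            c = self._select_c(X, labels)
        self.c_ = c
        self._svc = self._make(c).fit(X, labels)
        return self

    def _select_c(self, X, labels):
        folds = proportional_kfold(labels, self.cv_folds, self.seed)
        best_c, best_err = self._C_GRID[0], np.inf
        for c in self._C_GRID:
            errs = []
            for tr, te in folds.split():
                clf = self._make(c).fit(X[tr], labels[tr])
                errs.append(mean_per_class_error(labels[te], clf.predict(X[te])))
            err = float(np.mean(errs))
            if err < best_err - 1e-12:
                best_c, best_err = c, err
        return best_c

    def predict(self, X):
        return self._svc.predict(np.asarray(X, dtype=float))

    @property
    def description(self) -> str:
        return f"SVM(rbf, c={self.c})"


# ---------------------------------------------------------------------------
# k-means with deterministic first-k seeding
# ---------------------------------------------------------------------------


def kmeans_cluster(X, k: int, max_iter: int = 1000) -> np.ndarray:
    """Lloyd's algorithm seeded with the first k samples.

    Deterministic: no randomness anywhere.  Terminates when the means stop
    changing.  A cluster emptied during iteration keeps its previous mean.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for {n} samples")
    means = X[:k].copy()
    assign = np.zeros(n, dtype=int)
    for _ in range(max_iter):
        assign = np.argmin(cdist(X, means), axis=1)
        new_means = means.copy()
        for c in range(k):
            members = X[assign == c]
            if members.shape[0]:
                new_means[c] = members.mean(axis=0)
        if np.array_equal(new_means, means):
            break
        means = new_means
    return assign


# ---------------------------------------------------------------------------
# Multi-class schemes
# ---------------------------------------------------------------------------


def cascade_classify_3class(
    train_X,
    train_labels,
    test_X,
    classifier_factory: Callable[[], ClassifierContract],
    control_class,
):
    """Two-stage cascade for a three-class problem.

    Stage 1 separates the control class from everything else; stage 2,
    trained only on the two non-control classes, resolves the remainder.
    """
    train_X = np.asarray(train_X, dtype=float)
    test_X = np.atleast_2d(np.asarray(test_X, dtype=float))
    train_labels = np.asarray(train_labels)
    summ = class_summary(train_labels)
    if summ.n_classes != 3:
        raise ValueError(f"cascade needs exactly 3 classes, got {summ.n_classes}")
    if control_class not in summ.class_names:
        raise ValueError(f"control class {control_class!r} not in training labels")
    rest = "\x00rest\x00"  # internal token, never a real class name
    stage1_labels = np.where(train_labels == control_class, train_labels, rest)
    stage1 = classifier_factory().fit(train_X, stage1_labels)
    pred1 = np.asarray(stage1.predict(test_X))
    out = np.array(pred1, dtype=object)
    to_stage2 = pred1 == rest
    if np.any(to_stage2):
        m2 = train_labels != control_class
        stage2 = classifier_factory().fit(train_X[m2], train_labels[m2])
        out[to_stage2] = np.asarray(stage2.predict(test_X[to_stage2]))
    return np.array([x for x in out])


class CascadeClassifier:
    """Contract adapter for the three-class cascade."""

    def __init__(self, classifier_factory, control_class):
        self.classifier_factory = classifier_factory
        self.control_class = control_class

    def fit(self, X, labels):
        self._X = np.asarray(X, dtype=float)
        self._labels = np.asarray(labels)
        return self

    def predict(self, X):
        return cascade_classify_3class(
            self._X, self._labels, X, self.classifier_factory, self.control_class
        )

    @property
    def description(self) -> str:
        return f"cascade(control={self.control_class!r})"


def balanced_vote_train_predict(
    train_X,
    train_labels,
    test_X,
    classifier_factory: Callable[[], ClassifierContract],
    n_subgroups: int = 3,
):
    """Imbalanced two-class scheme: subgroup the majority class and vote.

    The majority class is k-means-clustered (on standardized features) into
    ``n_subgroups``; each subgroup plus the whole minority class trains one
    classifier; each classifier casts one vote per test sample; majority
    wins.  An empty subgroup loses its vote.
    """
    train_X = np.asarray(train_X, dtype=float)
    test_X = np.atleast_2d(np.asarray(test_X, dtype=float))
    train_labels = np.asarray(train_labels)
    summ = class_summary(train_labels)
    if summ.n_classes != 2:
        raise ValueError("balanced voting is a two-class scheme")
    order = np.argsort(summ.counts)[::-1]
    major = summ.class_names[order[0]]
    minor = summ.class_names[order[1]]
    maj_idx = np.nonzero(train_labels == major)[0]
    min_idx = np.nonzero(train_labels == minor)[0]
    if maj_idx.size < n_subgroups:
        raise ValueError("majority class smaller than the number of subgroups")
    Xm = train_X[maj_idx]
    stds = Xm.std(axis=0, ddof=1) if Xm.shape[0] > 1 else np.ones(Xm.shape[1])
    Z = (Xm - Xm.mean(axis=0)) / np.where(stds > 0, stds, 1.0)
    assign = kmeans_cluster(Z, n_subgroups)
    class_rank = {c: r for r, c in enumerate(summ.class_names)}
    votes = []
    for g in range(n_subgroups):
        members = maj_idx[assign == g]
        if members.size == 0:
            continue
        idx = np.concatenate([members, min_idx])
        clf = classifier_factory().fit(train_X[idx], train_labels[idx])
        votes.append(np.asarray(clf.predict(test_X)))
    votes = np.vstack(votes)
    out = []
    for q in range(test_X.shape[0]):
        names, counts = np.unique(votes[:, q], return_counts=True)
        best = max(
            zip(names, counts), key=lambda nc: (nc[1], -class_rank[nc[0]])
        )
        out.append(best[0])
    return np.array(out)


class BalancedVoteClassifier:
    """Contract adapter for the subgroup-voting two-class scheme."""

    def __init__(self, classifier_factory, n_subgroups: int = 3):
        self.classifier_factory = classifier_factory
        self.n_subgroups = n_subgroups

    def fit(self, X, labels):
        self._X = np.asarray(X, dtype=float)
        self._labels = np.asarray(labels)
        return self

    def predict(self, X):
        return balanced_vote_train_predict(
            self._X, self._labels, X, self.classifier_factory, self.n_subgroups
        )

    @property
    def description(self) -> str:
        return f"balanced-vote(n_subgroups={self.n_subgroups})"
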