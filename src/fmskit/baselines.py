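"""Baseline feature-ranking methods: mRMR, Information Gain, χ², Kruskal–Wallis.

The first three operate on presence/absence data — abundances binarized to
1 (taxon observed) / 0 (absent), which suits the extreme sparsity of 16S
surveys; Kruskal–Wallis ranks the continuous abundances directly.  All
information quantities are in bits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_model import class_summary
from .stats_core import mutual_information_discrete
from .validation import mean_per_class_error, proportional_kfold

__all__ = [
    "FeatureRanking",
    "binarize_presence",
    "mrmr_rank",
    "information_gain_rank",
    "chi2_rank",
    "kruskal_wallis_rank",
    "select_top_q_by_cv",
]

_MRMR_EPS = 1e-12  # MIQ convention: avoid a zero redundancy denominator


@dataclass
class FeatureRanking:
    """Ordered (feature index, score) pairs, best first."""

    ranking: list[tuple[int, float]]
    method: str

    @property
    def indices(self) -> list[int]:
        return [i for i, _ in self.ranking]

    def top(self, q: int) -> list[int]:
        return self.indices[:q]


def binarize_presence(X) -> np.ndarray:
    """1 where a taxon is observed (> 0), 0 where absent."""
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise ValueError("abundances must be non-negative")
    return (X > 0).astype(int)


def mrmr_rank(binary_X, labels, n_select: int | None = None) -> FeatureRanking:
    """Greedy mRMR with the quotient (MIQ) criterion.

    The first pick maximizes relevance I(g; c); each later pick maximizes
    I(g; c) / mean_{s ∈ selected} I(g; s).  Ties break to the lowest index.
    """
    B = np.asarray(binary_X)
    labels = np.asarray(labels)
    d = B.shape[1]
    if n_select is None:
        n_select = d
    if not 1 <= n_select <= d:
        raise ValueError(f"n_select={n_select} out of range for {d} features")
    relevance = np.array(
        [mutual_information_discrete(B[:, j], labels) for j in range(d)]
    )
    mi_cache = np.full((d, d), np.nan)
    selected: list[tuple[int, float]] = []
    chosen: list[int] = []
    remaining = list(range(d))
    for m in range(n_select):
        best_j, best_score = None, -np.inf
        for j in remaining:
            if m == 0:
                score = relevance[j]
            else:
                red = 0.0
                for s in chosen:
                    if np.isnan(mi_cache[j, s]):
                        mi_cache[j, s] = mi_cache[s, j] = (
                            mutual_information_discrete(B[:, j], B[:, s])
                        )
                    red += mi_cache[j, s]
                red /= m
                score = relevance[j] / (red + _MRMR_EPS)
            if score > best_score:
                best_j, best_score = j, score
        selected.append((best_j, float(best_score)))
        chosen.append(best_j)
        remaining.remove(best_j)
    return FeatureRanking(selected, "mRMR")


def information_gain_rank(binary_X, labels) -> FeatureRanking:
    """Rank by information gain H(class) − H(class | feature), descending.

    For a feature/class pair this equals their mutual information.
    """
    B = np.asarray(binary_X)
    labels = np.asarray(labels)
    ig = [
        (j, mutual_information_discrete(B[:, j], labels))
        for j in range(B.shape[1])
    ]
    ig.sort(key=lambda t: (-t[1], t[0]))
    return FeatureRanking(ig, "InformationGain")


def _chi2_stat(binary_col, labels, class_names) -> float:
    # 2 × K contingency: rows = presence interval, cols = class
    A = np.array(
        [
            [np.sum((binary_col == v) & (labels == c)) for c in class_names]
            for v in (0, 1)
        ],
        dtype=float,
    )
    N = A.sum()
    Mi = A.sum(axis=1, keepdims=True)
    Bj = A.sum(axis=0, keepdims=True)
    E = Mi * Bj / N
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(E > 0, (A - E) ** 2 / np.where(E > 0, E, 1.0), 0.0)
    return float(terms.sum())


def chi2_rank(binary_X, labels) -> FeatureRanking:
    """Rank by the χ² statistic of the 2 × K presence/class table, descending.

    Cells with zero expected count contribute nothing.
    """
    B = np.asarray(binary_X)
    labels = np.asarray(labels)
    names = list(class_summary(labels).class_names)
    scores = [
        (j, _chi2_stat(B[:, j], labels, names)) for j in range(B.shape[1])
    ]
    scores.sort(key=lambda t: (-t[1], t[0]))
    return FeatureRanking(scores, "chi2")


def kruskal_wallis_rank(X, labels) -> FeatureRanking:
    """Rank continuous features by the Kruskal–Wallis H test, best p first.

    A constant feature gets H = 0 (p = 1) by convention.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    names = list(class_summary(labels).class_names)
    groups_of = [np.nonzero(labels == c)[0] for c in names]
    rows = []
    for j in range(X.shape[1]):
        samples = [X[g, j] for g in groups_of]
        if np.ptp(X[:, j]) == 0:
            h, p = 0.0, 1.0
        else:
            h, p = stats.kruskal(*samples)
        rows.append((j, float(h), float(p)))
    rows.sort(key=lambda t: (t[2], -t[1], t[0]))
    return FeatureRanking([(j, h) for j, h, _ in rows], "KruskalWallis")


def select_top_q_by_cv(
    ranking: FeatureRanking,
    X,
    labels,
    classifier_factory,
    *,
    cv_folds: int = 5,
    seed: int = 0,
    q_max: int | None = None,
) -> tuple[int, list[float]]:
    """Choose how many top-ranked features to keep, by proportional CV error.

    Returns (q, errors) where errors[i] is the CV mean per-class error using
    the top i+1 features; ties break toward fewer features.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    folds = proportional_kfold(labels, cv_folds, seed)
    splits = list(folds.split())
    q_max = q_max or len(ranking.ranking)
    errors = []
    for q in range(1, q_max + 1):
        cols = ranking.top(q)
        errs = []
        for tr, te in splits:
            clf = classifier_factory().fit(X[tr][:, cols], labels[tr])
            errs.append(
                mean_per_class_error(labels[te], clf.predict(X[te][:, cols]))
            )
        errors.append(float(np.mean(errs)))
    best_q = int(np.argmin(errors)) + 1  # argmin takes the first => fewest
    return best_q, errors
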