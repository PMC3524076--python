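"""Scalar statistics: Fisher score, Pearson correlation, discretized mutual
information, and the noisy-dataset rule.

The Fisher statistic of a single (possibly combined) feature is the one-way
ANOVA F ratio

    F = [ Σ_k n_k (m_k − m)² / (K−1) ] / [ Σ_k (n_k−1) σ_k² / (n−K) ]

with K classes of sizes n_k, class means m_k, grand mean m and unbiased class
variances σ_k².  Mutual information is always computed on discretized data;
two discretization schemes are used, cutting each feature at midpoints of
adjacent sorted class means, or of class medians.  All information quantities
are in bits (base 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import mutual_info_score

from .data_model import class_summary

__all__ = [
    "fisher_statistic",
    "pearson_correlation",
    "DiscretizationRule",
    "classmean_cutpoints",
    "classmedian_cutpoints",
    "mutual_information_discrete",
    "entropy_discrete",
    "is_noisy_dataset",
    "NOISY_MI_THRESHOLD",
]

#: Datasets whose best feature carries less than this much information (bits,
#: median-discretized) about the class are treated as noisy.
NOISY_MI_THRESHOLD = 0.03

_LN2 = np.log(2.0)


def _class_masks(labels) -> tuple[list, list[np.ndarray]]:
    summ = class_summary(labels)
    labels = np.asarray(labels)
    return list(summ.class_names), [labels == c for c in summ.class_names]


def fisher_statistic(x, labels) -> float:
    """One-way ANOVA F ratio of a single feature against class labels.

    Returns ``inf`` when classes are perfectly separated with zero
    within-class variance (the sentinel ranks above every finite score).
    """
    x = np.asarray(x, dtype=float)
    names, masks = _class_masks(labels)
    K = len(names)
    n = x.size
    if n <= K:
        raise ValueError(f"need more samples ({n}) than classes ({K})")
    counts = np.array([m.sum() for m in masks])
    if np.any(counts == 0):
        raise ValueError("empty class")
    grand = x.mean()
    means = np.array([x[m].mean() for m in masks])
    ss_between = float(np.sum(counts * (means - grand) ** 2))
    ss_within = float(sum(np.sum((x[m] - mu) ** 2) for m, mu in zip(masks, means)))
    num = ss_between / (K - 1)
    den = ss_within / (n - K)
    if den == 0.0:
        return 0.0 if num == 0.0 else float("inf")
    return num / den


def pearson_correlation(x, y) -> float:
    """Product-moment correlation; errors on constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("vectors must have equal length >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(np.sqrt(np.sum(xc * xc)))
    sy = float(np.sqrt(np.sum(yc * yc)))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("zero-variance input to pearson_correlation")
    return float(np.clip(np.sum(xc * yc) / (sx * sy), -1.0, 1.0))


@dataclass(frozen=True)
class DiscretizationRule:
    """Binning rule: value x falls in bin = number of cut points ≤ x."""

    cut_points: tuple[float, ...]
    scheme: str  # "class-mean-midpoints" | "class-median"

    def apply(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if not self.cut_points:
            return np.zeros(x.shape, dtype=int)
        return np.searchsorted(np.asarray(self.cut_points), x, side="right")


def _midpoint_rule(centers: np.ndarray, scheme: str) -> DiscretizationRule:
    uniq = np.unique(centers)
    cuts = tuple(((uniq[:-1] + uniq[1:]) / 2.0).tolist())
    return DiscretizationRule(cuts, scheme)


def classmean_cutpoints(x, labels) -> DiscretizationRule:
    """Cut points at midpoints of adjacent sorted class means."""
    x = np.asarray(x, dtype=float)
    _, masks = _class_masks(labels)
    centers = np.array([x[m].mean() for m in masks])
    return _midpoint_rule(centers, "class-mean-midpoints")


def classmedian_cutpoints(x, labels) -> DiscretizationRule:
    """Cut points at midpoints of adjacent sorted class medians."""
    x = np.asarray(x, dtype=float)
    _, masks = _class_masks(labels)
    centers = np.array([np.median(x[m]) for m in masks])
    return _midpoint_rule(centers, "class-median")


def mutual_information_discrete(a, b) -> float:
    """Empirical mutual information of two discrete vectors, in bits.

    Plug-in (maximum-likelihood) estimate: cells with zero joint frequency
    contribute nothing.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty vectors")
    if a.size != b.size:
        raise ValueError("length mismatch")
    return float(mutual_info_score(a, b)) / _LN2


def entropy_discrete(a) -> float:
    """Empirical Shannon entropy in bits."""
    a = np.asarray(a)
    if a.size == 0:
        raise ValueError("empty vector")
    _, counts = np.unique(a, return_counts=True)
    p = counts / a.size
    return float(-np.sum(p * np.log2(p)))


def is_noisy_dataset(
    X,
    labels,
    threshold: float = NOISY_MI_THRESHOLD,
    *,
    summary: str = "max",
) -> tuple[bool, np.ndarray]:
    """Noisy-data test: per-feature MI with the class, median-discretized.

    The dataset is flagged noisy when the summary (default: the maximum — if
    even the best feature carries < ``threshold`` bits about the class, Fisher
    ranking is unreliable) falls below ``threshold``.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    mi = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        binned = classmedian_cutpoints(X[:, j], labels).apply(X[:, j])
        mi[j] = mutual_information_discrete(binned, labels)
    if summary == "max":
        stat = mi.max() if mi.size else 0.0
    elif summary == "mean":
        stat = mi.mean() if mi.size else 0.0
    else:
        raise ValueError(f"unknown summary {summary!r}")
    return bool(stat < threshold), mi
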