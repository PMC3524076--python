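"""Feature merging and selection (FMS).

FMS reduces a sparse, redundant abundance table by greedily *merging*
correlated discriminative feature pairs into weighted linear combinations
(directions found by pairwise LDA), then *deleting* unimportant original
features — keeping, unlike plain LDA, a partition of the surviving features
into non-overlapping combinations that remains interpretable.

The greedy criterion for which pair to merge is the merging value

    merging_value = F(a·x_i + b·x_j) · |r_ij| / √(F(x_i) · F(x_j))

where F is the Fisher statistic and r the Pearson correlation of the pair:
a pair is merged when the combination keeps (or improves) discrimination
*and* the members are redundant.  After merging, each combination's weights
are refit by LDA on its member features.  Features are then ranked by
|weight| × combination Fisher score (or by mutual information with the class
on noisy data) and deleted one by one.  Both the merge degree and the
deletion count are chosen by proportional 5-fold cross-validation of a
plug-in classifier; on noisy data the deletion degree is chosen by an
error-plus-dimension-penalty criterion.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import lda as _lda
from .data_model import AbundanceTable, class_summary
from .stats_core import (
    NOISY_MI_THRESHOLD,
    classmedian_cutpoints,
    fisher_statistic,
    is_noisy_dataset,
    mutual_information_discrete,
)
from .validation import (
    CascadeClassifier,
    KnnClassifier,
    SvmRbf,
    BalancedVoteClassifier,
    mean_per_class_error,
    proportional_kfold,
)

__all__ = [
    "FmsConfig",
    "FeatureCombination",
    "MergeRecord",
    "CurvePoint",
    "LearningCurve",
    "MergeModel",
    "merging_value",
    "fit_merging",
    "merge_once",
    "refit_combination_weights",
    "feature_importance",
    "delete_features",
    "select_degree_by_cv",
    "select_degree_by_penalty",
    "fit",
    "transform",
]

MODEL_SCHEMA = "fmskit-model-v1"

#: cap used in place of an infinite Fisher score inside merging values, so
#: perfectly separating combinations still rank (highest) without producing
#: inf/inf indeterminacy
_FISHER_CAP = 1e30
#: rank scale for pairs whose Fisher geometric mean is zero: such pairs merge
#: last, ordered among themselves by the merged Fisher score
_ZERO_FISHER_RANK = 1e-12


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class FmsConfig:
    """Tunable parameters of an FMS fit.

    Defaults follow the reference procedure: 5 proportional CV folds, noisy
    threshold 0.03 bits, 3 subgroups for the imbalanced voting scheme,
    |Pearson| in the merging value, and the (n_k−1)-weighted between-class
    scatter convention.
    """

    classifier: str = "svm"  # "svm" | "knn"
    knn_k: int | str = 1
    svm_c: float | str | None = None
    three_class: str = "cascade"  # "cascade" | "ova"
    control_class: object | None = None
    two_class: str = "plain"  # "plain" | "balanced_vote"
    n_subgroups: int = 3
    cv_folds: int = 5
    seed: int = 0
    noise_threshold: float = NOISY_MI_THRESHOLD
    noise_summary: str = "max"
    pearson_abs: bool = True
    scatter_convention: str = "nk_minus_one"
    eps: float | None = None
    step8: str = "per_combination"  # "per_combination" | "off"
    weight_norm: str = "l2"  # "l2" | "l1"
    n_merges: int | None = None  # force the merge degree (skip its CV curve)
    n_deletions: int | None = None  # force the deletion count

    def classifier_factory(self, labels) -> Callable:
        """Build a fresh-classifier factory appropriate to the label set."""
        summ = class_summary(labels)

        def base():
            if self.classifier == "svm":
                return SvmRbf(c=self.svm_c, seed=self.seed)
            if self.classifier == "knn":
                return KnnClassifier(k=self.knn_k, seed=self.seed)
            raise ValueError(f"unknown classifier {self.classifier!r}")

        if summ.n_classes == 3 and self.three_class == "cascade":
            control = self.control_class
            if control is None:
                control = summ.class_names[0]
            return lambda: CascadeClassifier(base, control)
        if summ.n_classes == 2 and self.two_class == "balanced_vote":
            return lambda: BalancedVoteClassifier(base, self.n_subgroups)
        return base


def _normalize(w: np.ndarray, norm: str) -> np.ndarray:
    if norm == "l2":
        s = float(np.linalg.norm(w))
    elif norm == "l1":
        s = float(np.sum(np.abs(w)))
    else:
        raise ValueError(f"unknown weight norm {norm!r}")
    if s == 0.0:
        raise ValueError("cannot normalize a zero weight vector")
    return w / s


# ---------------------------------------------------------------------------
# Model data types
# ---------------------------------------------------------------------------


@dataclass
class FeatureCombination:
    """One output dimension: a weighted set of original features."""

    member_indices: list[int]
    weights: np.ndarray
    fisher: float

    def column(self, X: np.ndarray) -> np.ndarray:
        return X[:, self.member_indices] @ self.weights


@dataclass
class MergeRecord:
    iteration: int
    left_members: list[int]
    right_members: list[int]
    a: float
    b: float
    merging_value: float


@dataclass(frozen=True)
class CurvePoint:
    degree: int
    cv_mean_error: float
    dimension: int
    n_features: int


@dataclass
class LearningCurve:
    points: list[CurvePoint]

    def __len__(self):
        return len(self.points)

    def __iter__(self):
        return iter(self.points)


@dataclass
class MergeModel:
    """Frozen result of an FMS fit; sufficient to transform new data."""

    combinations: list[FeatureCombination]
    merge_log: list[MergeRecord]
    deleted_features: list[int]
    n_merges_selected: int
    n_deletions_selected: int
    zero_variance_removed: list[int]
    n_features_in: int
    noisy_branch: bool
    merge_curve: LearningCurve | None = None
    deletion_curve: LearningCurve | None = None
    feature_labels: list[str] | None = None
    cv_error_selected: float | None = None  # CV error at the chosen degrees

    @property
    def dimension(self) -> int:
        return len(self.combinations)

    @property
    def n_features_surviving(self) -> int:
        return sum(len(c.member_indices) for c in self.combinations)

    def transform(self, X_new) -> np.ndarray:
        return transform(self, X_new)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema": MODEL_SCHEMA,
            "n_features_in": self.n_features_in,
            "zero_variance_removed": list(self.zero_variance_removed),
            "noisy_branch": self.noisy_branch,
            "n_merges_selected": self.n_merges_selected,
            "n_deletions_selected": self.n_deletions_selected,
            "deleted_features": list(self.deleted_features),
            "feature_labels": self.feature_labels,
            "combinations": [
                {
                    "members": list(c.member_indices),
                    "weights": [float(w) for w in c.weights],
                    "fisher": float(c.fisher) if math.isfinite(c.fisher) else "inf",
                }
                for c in self.combinations
            ],
            "merge_log": [
                {
                    "iteration": r.iteration,
                    "left": list(r.left_members),
                    "right": list(r.right_members),
                    "a": r.a,
                    "b": r.b,
                    "merging_value": r.merging_value
                    if math.isfinite(r.merging_value)
                    else "inf",
                }
                for r in self.merge_log
            ],
            "curves": {
                name: None
                if curve is None
                else [
                    [p.degree, p.cv_mean_error, p.dimension, p.n_features]
                    for p in curve
                ]
                for name, curve in (
                    ("merge", self.merge_curve),
                    ("deletion", self.deletion_curve),
                )
            },
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "MergeModel":
        if doc.get("schema") != MODEL_SCHEMA:
            raise ValueError(f"unsupported model schema {doc.get('schema')!r}")

        def _num(x):
            return float("inf") if x == "inf" else float(x)

        curves = {}
        for name in ("merge", "deletion"):
            raw = doc["curves"].get(name)
            curves[name] = (
                None
                if raw is None
                else LearningCurve(
                    [CurvePoint(int(d), float(e), int(dim), int(nf)) for d, e, dim, nf in raw]
                )
            )
        return cls(
            combinations=[
                FeatureCombination(
                    [int(i) for i in c["members"]],
                    np.array(c["weights"], dtype=float),
                    _num(c["fisher"]),
                )
                for c in doc["combinations"]
            ],
            merge_log=[
                MergeRecord(
                    int(r["iteration"]),
                    [int(i) for i in r["left"]],
                    [int(i) for i in r["right"]],
                    float(r["a"]),
                    float(r["b"]),
                    _num(r["merging_value"]),
                )
                for r in doc["merge_log"]
            ],
            deleted_features=[int(i) for i in doc["deleted_features"]],
            n_merges_selected=int(doc["n_merges_selected"]),
            n_deletions_selected=int(doc["n_deletions_selected"]),
            zero_variance_removed=[int(i) for i in doc["zero_variance_removed"]],
            n_features_in=int(doc["n_features_in"]),
            noisy_branch=bool(doc["noisy_branch"]),
            merge_curve=curves["merge"],
            deletion_curve=curves["deletion"],
            feature_labels=doc.get("feature_labels"),
        )

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path: str) -> "MergeModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def transform(model: MergeModel, X_new) -> np.ndarray:
    """Apply a frozen model's combinations to new data (original columns)."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.n_features_in:
        raise ValueError(
            f"expected {model.n_features_in} features, got {X_new.shape[1]}"
        )
    if not model.combinations:
        return np.empty((X_new.shape[0], 0))
    return np.column_stack([c.column(X_new) for c in model.combinations])


# ---------------------------------------------------------------------------
# Merging value
# ---------------------------------------------------------------------------


def merging_value(
    fisher_i: float,
    fisher_j: float,
    fisher_new: float,
    r: float,
    *,
    pearson_abs: bool = True,
) -> float:
    """Greedy merge criterion: F_new · |r| / √(F_i · F_j).

    A zero Fisher geometric mean (an uninformative member) does not divide by
    zero: such pairs get a vanishing rank proportional to F_new so they merge
    last.  Infinite Fisher scores are capped so the ratio stays ordered.
    """
    if abs(r) > 1 + 1e-12:
        raise ValueError("|r| must be <= 1")
    rr = abs(r) if pearson_abs else r
    fi = min(fisher_i, _FISHER_CAP)
    fj = min(fisher_j, _FISHER_CAP)
    fn = min(fisher_new, _FISHER_CAP)
    gm = math.sqrt(fi * fj)
    if gm == 0.0:
        return _ZERO_FISHER_RANK * fn
    return fn * rr / gm


def _merging_values_vec(fi, fj, fnew, r, pearson_abs: bool) -> np.ndarray:
    rr = np.abs(r) if pearson_abs else r
    fi = np.minimum(fi, _FISHER_CAP)
    fj = np.minimum(fj, _FISHER_CAP)
    fn = np.minimum(fnew, _FISHER_CAP)
    gm = np.sqrt(fi * fj)
    with np.errstate(divide="ignore", invalid="ignore"):
        mv = np.where(gm > 0.0, fn * rr / np.where(gm > 0.0, gm, 1.0),
                      _ZERO_FISHER_RANK * fn)
    return mv


# ---------------------------------------------------------------------------
# In-progress fit state
# ---------------------------------------------------------------------------


class _FitState:
    """Mutable merge/delete state over a fixed training matrix."""

    def __init__(self, X: np.ndarray, labels, config: FmsConfig):
        self.X = np.asarray(X, dtype=float)
        self.labels = np.asarray(labels)
        self.config = config
        var = self.X.var(axis=0, ddof=1)
        surviving = np.nonzero(var > 0.0)[0]
        self.zero_variance_removed = [int(j) for j in np.nonzero(var == 0.0)[0]]
        if surviving.size == 0:
            raise ValueError("all features have zero variance")
        self.combos: list[FeatureCombination] = [
            FeatureCombination([int(j)], np.array([1.0]),
                               fisher_statistic(self.X[:, j], self.labels))
            for j in surviving
        ]
        self.U = self.X[:, surviving].astype(float)
        self.merge_log: list[MergeRecord] = []
        self.deleted: list[int] = []
        self.noisy_branch = False

    # -- merging -----------------------------------------------------------

    def merge_once(self) -> None:
        if len(self.combos) < 2:
            raise ValueError("fewer than two combinations remain")
        cfg = self.config
        ii, jj, a_all, b_all, fnew = _lda.pairwise_merge_stats(
            self.U, self.labels, cfg.eps, convention=cfg.scatter_convention
        )
        # Pearson correlation between current combined columns
        sd = self.U.std(axis=0, ddof=1)
        Z = (self.U - self.U.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
        C = (Z.T @ Z) / (self.U.shape[0] - 1)
        r = np.where((sd[ii] > 0) & (sd[jj] > 0), C[ii, jj], 0.0)
        r = np.clip(r, -1.0, 1.0)
        fi = np.array([c.fisher for c in self.combos])
        mv = _merging_values_vec(fi[ii], fi[jj], fnew, r, cfg.pearson_abs)
        best = int(np.argmax(mv))  # lexicographic pair order breaks ties
        i, j = int(ii[best]), int(jj[best])
        a, b = float(a_all[best]), float(b_all[best])
        left, right = self.combos[i], self.combos[j]
        new_w = _normalize(
            np.concatenate([a * left.weights, b * right.weights]), cfg.weight_norm
        )
        members = left.member_indices + right.member_indices
        combo = FeatureCombination(members, new_w, float(fnew[best]))
        col = combo.column(self.X)
        self.merge_log.append(
            MergeRecord(
                iteration=len(self.merge_log) + 1,
                left_members=list(left.member_indices),
                right_members=list(right.member_indices),
                a=a,
                b=b,
                merging_value=float(mv[best]),
            )
        )
        keep = [t for t in range(len(self.combos)) if t not in (i, j)]
        self.combos = [self.combos[t] for t in keep] + [combo]
        self.U = np.column_stack([self.U[:, keep], col]) if keep else col[:, None]

    def merge_to(self, n_merges: int) -> None:
        done = len(self.merge_log)
        if not 0 <= n_merges <= done + len(self.combos) - 1:
            raise ValueError(
                f"n_merges={n_merges} out of range (have {len(self.combos)} "
                "combinations)"
            )
        for _ in range(n_merges - done):
            self.merge_once()

    # -- Step 8 refit ------------------------------------------------------

    def refit_weights(self) -> None:
        cfg = self.config
        for t, c in enumerate(self.combos):
            if len(c.member_indices) < 2:
                continue
            dirs = _lda.lda_directions(
                self.X[:, c.member_indices],
                self.labels,
                cfg.eps,
                convention=cfg.scatter_convention,
            )
            best = max(dirs, key=lambda d: d.fisher_of_projection)
            w = _normalize(best.w, cfg.weight_norm)
            self.combos[t] = FeatureCombination(
                list(c.member_indices), w, best.fisher_of_projection
            )
        self._recompute_columns()

    def _recompute_columns(self) -> None:
        if self.combos:
            self.U = np.column_stack([c.column(self.X) for c in self.combos])
        else:
            self.U = np.empty((self.X.shape[0], 0))

    # -- deletion ----------------------------------------------------------

    def importance_order(self, noisy: bool) -> list[int]:
        """Surviving original features sorted ascending by importance."""
        scores = feature_importance(self, noisy=noisy)
        return [f for f, _ in sorted(scores.items(), key=lambda kv: (kv[1], kv[0]))]

    def delete(self, order: Sequence[int], n_delete: int) -> None:
        surviving = sum(len(c.member_indices) for c in self.combos)
        if not 0 <= n_delete < surviving:
            raise ValueError(
                f"n_delete={n_delete} out of range (surviving {surviving})"
            )
        doomed = set(order[:n_delete])
        new_combos = []
        for c in self.combos:
            keep = [t for t, f in enumerate(c.member_indices) if f not in doomed]
            if not keep:
                continue
            members = [c.member_indices[t] for t in keep]
            w = _normalize(c.weights[keep], self.config.weight_norm)
            col = self.X[:, members] @ w
            new_combos.append(
                FeatureCombination(members, w, fisher_statistic(col, self.labels))
            )
        self.combos = new_combos
        self.deleted.extend(f for f in order[:n_delete])
        self._recompute_columns()

    def snapshot(self) -> "_FitState":
        import copy

        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# Public operations on states/models
# ---------------------------------------------------------------------------


def fit_merging(X, labels, n_merges: int, config: FmsConfig | None = None) -> _FitState:
    """Preprocess (drop zero variance) and apply exactly n_merges merges."""
    config = config or FmsConfig()
    state = _FitState(X, labels, config)
    state.merge_to(n_merges)
    return state


def merge_once(state: _FitState) -> _FitState:
    state.merge_once()
    return state


def refit_combination_weights(state: _FitState) -> _FitState:
    """Step-8 refit: per-combination LDA re-estimation of the weights."""
    state.refit_weights()
    return state


def feature_importance(state: _FitState, *, noisy: bool = False) -> dict[int, float]:
    """Deletion score per surviving original feature.

    Fisher branch: |weight within combination| × combination Fisher score.
    Noisy branch: mutual information of the feature with the class
    (median-discretized), ignoring combination structure.
    """
    scores: dict[int, float] = {}
    if noisy:
        for c in state.combos:
            for f in c.member_indices:
                x = state.X[:, f]
                binned = classmedian_cutpoints(x, state.labels).apply(x)
                scores[f] = mutual_information_discrete(binned, state.labels)
        return scores
    for c in state.combos:
        fisher = min(c.fisher, _FISHER_CAP)
        for f, w in zip(c.member_indices, c.weights):
            scores[f] = abs(float(w)) * fisher
    return scores


def delete_features(state: _FitState, n_delete: int, *, noisy: bool = False) -> _FitState:
    """Delete the n_delete least-important surviving original features."""
    order = state.importance_order(noisy)
    state.delete(order, n_delete)
    return state


# ---------------------------------------------------------------------------
# Degree selection
# ---------------------------------------------------------------------------


def select_degree_by_cv(curve: LearningCurve, mode: str) -> int:
    """Pick the degree minimizing CV error.

    Merge ties break toward the *largest* degree (lowest dimension);
    deletion ties break toward fewest dimensions, then fewest features.
    """
    if not len(curve):
        raise ValueError("empty learning curve")
    if mode == "merge":
        best = min(curve, key=lambda p: (p.cv_mean_error, -p.degree))
    elif mode == "delete":
        best = min(
            curve, key=lambda p: (p.cv_mean_error, p.dimension, p.n_features, p.degree)
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return best.degree


def select_degree_by_penalty(curve: LearningCurve, N_original: int) -> int:
    """Occam's-razor selection: error plus a dimension penalty.

    Among the m = ⌈log₂ N⌉ lowest-error curve points, the penalty weight is
    λ = (error range) / (dimension range); the chosen degree minimizes
    error + λ·dimension.  If the top t points tie exactly on that criterion,
    the rule is re-run once with m ← m + t − 1; remaining ties go to the
    lowest dimension.
    """
    if not len(curve):
        raise ValueError("empty learning curve")
    if N_original < 2:
        raise ValueError("N_original must be >= 2")

    def run(m: int):
        m = min(m, len(curve))
        chosen = sorted(curve, key=lambda p: (p.cv_mean_error, p.dimension, p.degree))[:m]
        errs = [p.cv_mean_error for p in chosen]
        dims = [p.dimension for p in chosen]
        dim_range = max(dims) - min(dims)
        lam = (max(errs) - min(errs)) / dim_range if dim_range > 0 else 0.0
        crit = [(p.cv_mean_error + lam * p.dimension, p) for p in chosen]
        best_val = min(v for v, _ in crit)
        ties = [p for v, p in crit if abs(v - best_val) <= 1e-12]
        return ties

    m0 = max(2, math.ceil(math.log2(N_original)))
    ties = run(m0)
    if len(ties) > 1:
        ties = run(m0 + len(ties) - 1)
    best = min(ties, key=lambda p: (p.dimension, p.n_features, p.degree))
    return best.degree


# ---------------------------------------------------------------------------
# Orchestrated fit
# ---------------------------------------------------------------------------


def _cv_error(clf_factory, U_tr, y_tr, U_te, y_te) -> float:
    clf = clf_factory().fit(U_tr, y_tr)
    return mean_per_class_error(y_te, np.asarray(clf.predict(U_te)))


def _merge_curve(
    X, labels, folds, config: FmsConfig, clf_factory, full_d: int
) -> LearningCurve:
    """CV error per merge degree; merge paths grown incrementally per fold."""
    fold_states = []
    fold_data = []
    for tr, te in folds.split():
        st = _FitState(X[tr], labels[tr], config)
        fold_states.append(st)
        fold_data.append((tr, te))
    max_degree = min(len(st.combos) for st in fold_states) - 1
    errors_per_degree = []
    for g in range(max_degree + 1):
        errs = []
        for st, (tr, te) in zip(fold_states, fold_data):
            st.merge_to(g)
            members = [c.member_indices for c in st.combos]
            weights = [c.weights for c in st.combos]
            U_te = np.column_stack(
                [X[te][:, m] @ w for m, w in zip(members, weights)]
            )
            errs.append(_cv_error(clf_factory, st.U, labels[tr], U_te, labels[te]))
        errors_per_degree.append(float(np.mean(errs)))
    return LearningCurve(
        [
            CurvePoint(g, e, dimension=full_d - g, n_features=full_d)
            for g, e in enumerate(errors_per_degree)
        ]
    )


def _deletion_curve(
    X, labels, folds, config: FmsConfig, clf_factory, merge_degree: int,
    full_state: _FitState,
) -> LearningCurve:
    """CV error per deletion count.

    Each fold re-learns merges + refit + importance ranking on its own
    training part, then deletes incrementally; dimension/feature counts for
    the curve (and its tie-breaks) come from applying the same deletions to
    the full-data model.
    """
    noisy = getattr(full_state, "noisy_branch", False)
    fold_runs = []
    for tr, te in folds.split():
        st = _FitState(X[tr], labels[tr], config)
        st.merge_to(min(merge_degree, len(st.combos) - 1))
        if config.step8 == "per_combination":
            st.refit_weights()
        order = st.importance_order(noisy)
        fold_runs.append((st, order, tr, te))
    max_del = min(
        sum(len(c.member_indices) for c in st.combos) - 1
        for st, _, _, _ in fold_runs
    )
    full_order = full_state.importance_order(noisy)
    full_surviving = sum(len(c.member_indices) for c in full_state.combos)
    max_del = min(max_del, full_surviving - 1)

    shadow = full_state.snapshot()  # tracks full-data dimension per degree
    points = []
    fold_models = [
        (st.snapshot(), order, tr, te) for st, order, tr, te in fold_runs
    ]
    for g in range(max_del + 1):
        errs = []
        for t, (st, order, tr, te) in enumerate(fold_models):
            if g > 0:
                st.delete([order[g - 1]], 1)
            U_te = np.column_stack(
                [c.column(X[te]) for c in st.combos]
            )
            errs.append(_cv_error(clf_factory, st.U, labels[tr], U_te, labels[te]))
        if g > 0:
            shadow.delete([full_order[g - 1]], 1)
        points.append(
            CurvePoint(
                g,
                float(np.mean(errs)),
                dimension=len(shadow.combos),
                n_features=sum(len(c.member_indices) for c in shadow.combos),
            )
        )
    return LearningCurve(points)


def fit(table, labels=None, config: FmsConfig | None = None) -> MergeModel:
    """Full FMS fit: merge-degree CV, Step-8 refit, deletion-count CV.

    ``table`` may be an :class:`AbundanceTable` (with labels attached) or a
    plain samples × features matrix with ``labels`` given separately.
    """
    config = config or FmsConfig()
    if isinstance(table, AbundanceTable):
        X = table.values
        labels = table.labels if labels is None else labels
        feature_labels = table.feature_labels
    else:
        X = np.asarray(table, dtype=float)
        feature_labels = None
    if labels is None:
        raise ValueError("class labels are required")
    labels = np.asarray(labels)

    probe = _FitState(X, labels, config)  # records zero-variance removal
    d_after = len(probe.combos)
    surviving_cols = [c.member_indices[0] for c in probe.combos]
    noisy, _ = is_noisy_dataset(
        X[:, surviving_cols], labels, config.noise_threshold,
        summary=config.noise_summary,
    )

    clf_factory = config.classifier_factory(labels)
    folds = proportional_kfold(labels, config.cv_folds, config.seed)

    # --- merge degree ---
    merge_curve = None
    if config.n_merges is not None:
        n_merges = config.n_merges
    else:
        merge_curve = _merge_curve(X, labels, folds, config, clf_factory, d_after)
        if noisy:
            n_merges = select_degree_by_penalty(merge_curve, d_after)
        else:
            n_merges = select_degree_by_cv(merge_curve, "merge")

    state = _FitState(X, labels, config)
    state.merge_to(n_merges)
    if config.step8 == "per_combination":
        state.refit_weights()
    state.noisy_branch = noisy

    # --- deletion count ---
    deletion_curve = None
    if config.n_deletions is not None:
        n_deletions = config.n_deletions
    else:
        deletion_curve = _deletion_curve(
            X, labels, folds, config, clf_factory, n_merges, state
        )
        if noisy:
            n_deletions = select_degree_by_penalty(deletion_curve, d_after)
        else:
            n_deletions = select_degree_by_cv(deletion_curve, "delete")

    order = state.importance_order(noisy)
    state.delete(order, n_deletions)

    cv_error = None
    if deletion_curve is not None:
        cv_error = next(
            p.cv_mean_error for p in deletion_curve if p.degree == n_deletions
        )
    elif merge_curve is not None:
        cv_error = next(
            p.cv_mean_error for p in merge_curve if p.degree == n_merges
        )

    return MergeModel(
        combinations=state.combos,
        merge_log=state.merge_log,
        deleted_features=state.deleted,
        n_merges_selected=n_merges,
        n_deletions_selected=n_deletions,
        zero_variance_removed=state.zero_variance_removed,
        n_features_in=X.shape[1],
        noisy_branch=noisy,
        merge_curve=merge_curve,
        deletion_curve=deletion_curve,
        feature_labels=feature_labels,
        cv_error_selected=cv_error,
    )


def combination_report(model: MergeModel) -> list[dict]:
    """Rows for the combination report, sorted by Fisher score descending."""
    rows = []
    for k, c in enumerate(model.combinations):
        labels = (
            [model.feature_labels[f] for f in c.member_indices]
            if model.feature_labels
            else [str(f) for f in c.member_indices]
        )
        rows.append(
            {
                "combination": f"FMS_comb_{k}",
                "fisher": c.fisher,
                "members": labels,
                "weights": [float(w) for w in c.weights],
            }
        )
    rows.sort(key=lambda r: r["fisher"], reverse=True)
    return rows
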