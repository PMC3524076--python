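"""Scatter matrices, regularized LDA, and pairwise merge directions.

LDA finds directions w maximizing the Rayleigh quotient
J(w) = wᵀS_B w / wᵀS_W w.  Two conventions for the between-class scatter are
supported:

* ``nk_minus_one``   — S_B = Σ_k (n_k−1)(m_k−m)(m_k−m)ᵀ / (K−1)
* ``standard``— S_B = Σ_k  n_k   (m_k−m)(m_k−m)ᵀ / (K−1)

The within-class scatter is S_W = Σ_k Σ_{y∈k} (y−m_k)(y−m_k)ᵀ / (N−K).  With
more features than samples S_W is singular; it is repaired by repeatedly
adding a small multiple of the identity until it passes a scale-aware
nonsingularity test.  For the two-class problem both conventions give the
same leading direction (the between scatter is rank one either way).

The Fisher statistic of the projection Xw equals wᵀN w / wᵀS_W w with N the
``standard``-weighted between matrix, which is how projected Fisher scores
are evaluated regardless of the convention driving the eigenproblem.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cholesky, eigh, solve_triangular

from .data_model import class_summary
from .stats_core import fisher_statistic

__all__ = [
    "ScatterPair",
    "LdaDirection",
    "scatter_matrices",
    "regularize_until_nonsingular",
    "lda_directions",
    "merge_direction",
    "pairwise_merge_stats",
]

#: relative scale of the nonsingularity threshold on the smallest eigenvalue
_SINGULAR_RTOL = 1e-10
#: default regularization step, relative to the mean diagonal of S_W
_EPS_RTOL = 1e-6
_EPS_FLOOR = 1e-12


@dataclass
class ScatterPair:
    s_b: np.ndarray
    s_w: np.ndarray
    regularization_added: float = 0.0


@dataclass
class LdaDirection:
    w: np.ndarray
    rayleigh: float
    fisher_of_projection: float


def _class_stats(X, labels):
    summ = class_summary(labels)
    labels = np.asarray(labels)
    masks = [labels == c for c in summ.class_names]
    counts = np.array(summ.counts)
    if np.any(counts == 0):
        raise ValueError("empty class")
    means = np.vstack([X[m].mean(axis=0) for m in masks])
    return summ, masks, counts, means


def scatter_matrices(X, labels, *, convention: str = "nk_minus_one") -> ScatterPair:
    """Between- and within-class scatter of samples × features ``X``."""
    if convention not in ("nk_minus_one", "standard"):
        raise ValueError(f"unknown scatter convention {convention!r}")
    X = np.asarray(X, dtype=float)
    summ, masks, counts, means = _class_stats(X, labels)
    N, K = X.shape[0], summ.n_classes
    if N <= K:
        raise ValueError(f"need more samples ({N}) than classes ({K})")
    grand = X.mean(axis=0)
    dev = means - grand
    wts = counts - 1 if convention == "nk_minus_one" else counts
    s_b = (dev.T * wts) @ dev / (K - 1)
    s_w = np.zeros((X.shape[1], X.shape[1]))
    for m, mu in zip(masks, means):
        C = X[m] - mu
        s_w += C.T @ C
    s_w /= N - K
    return ScatterPair(s_b=0.5 * (s_b + s_b.T), s_w=0.5 * (s_w + s_w.T))


def _nonsingular_threshold(s_w: np.ndarray) -> float:
    d = s_w.shape[0]
    return _SINGULAR_RTOL * (1.0 + float(np.trace(s_w)) / d)


def default_eps(s_w: np.ndarray) -> float:
    return max(_EPS_RTOL * float(np.mean(np.diag(s_w))), _EPS_FLOOR)


def regularize_until_nonsingular(
    s_w: np.ndarray, eps: float
) -> tuple[np.ndarray, float]:
    """Add eps·I repeatedly until S_W passes the nonsingularity test.

    Returns ``(S_W + j·eps·I, j·eps)`` with the minimal count j ≥ 0 of
    additions.  A PSD input always terminates.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    s_w = np.asarray(s_w, dtype=float)
    thr = _nonsingular_threshold(s_w)
    lam_min = float(np.linalg.eigvalsh(s_w)[0])
    j = 0 if lam_min > thr else int(np.ceil((thr - lam_min) / eps))
    while lam_min + j * eps <= thr:  # guard against rounding at the boundary
        j += 1
    if j == 0:
        return s_w, 0.0
    return s_w + (j * eps) * np.eye(s_w.shape[0]), j * eps


def _fix_sign(w: np.ndarray) -> np.ndarray:
    nz = np.nonzero(np.abs(w) > 1e-12 * np.linalg.norm(w))[0]
    if nz.size and w[nz[0]] < 0:
        return -w
    return w


def lda_directions(
    X,
    labels,
    eps: float | None = None,
    *,
    convention: str = "nk_minus_one",
) -> list[LdaDirection]:
    """All generalized eigendirections of (S_B, S_W_reg), leading first.

    Solved by symmetric whitening: Cholesky L of the regularized S_W, then an
    ordinary symmetric eigenproblem on L⁻¹ S_B L⁻ᵀ.  Deterministic: sorted by
    descending eigenvalue, each vector unit-norm with its first significant
    component positive.
    """
    X = np.asarray(X, dtype=float)
    scat = scatter_matrices(X, labels, convention=convention)
    if eps is None:
        eps = default_eps(scat.s_w)
    s_w_reg, added = regularize_until_nonsingular(scat.s_w, eps)
    scat.regularization_added = added
    L = cholesky(s_w_reg, lower=True)
    Li_sb = solve_triangular(L, scat.s_b, lower=True)
    A = solve_triangular(L, Li_sb.T, lower=True)
    A = 0.5 * (A + A.T)
    vals, vecs = eigh(A)
    order = np.argsort(vals)[::-1]
    out = []
    for idx in order:
        w = solve_triangular(L.T, vecs[:, idx], lower=False)
        w = w / np.linalg.norm(w)
        w = _fix_sign(w)
        out.append(
            LdaDirection(
                w=w,
                rayleigh=float(max(vals[idx], 0.0)),
                fisher_of_projection=fisher_statistic(X @ w, labels),
            )
        )
    return out


def merge_direction(
    x_i,
    x_j,
    labels,
    eps: float | None = None,
    *,
    convention: str = "nk_minus_one",
) -> tuple[float, float, float]:
    """Best linear combination a·x_i + b·x_j by pairwise LDA.

    Returns ``(a, b, fisher_new)`` with (a, b) the leading LDA direction in
    the 2-D feature space, unit-norm, first significant component positive.
    """
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    if np.ptp(x_i) == 0 and np.ptp(x_j) == 0:
        raise ValueError("both features constant; nothing to merge")
    X = np.column_stack([x_i, x_j])
    lead = lda_directions(X, labels, eps, convention=convention)[0]
    a, b = lead.w
    return float(a), float(b), lead.fisher_of_projection


# ---------------------------------------------------------------------------
# Vectorized all-pairs solver used by the greedy merge loop.  The 2×2 scatter
# matrices of every feature pair are submatrices of the full d×d scatters, so
# one pass builds them all; the 2×2 generalized eigenproblem has a closed
# form.
# ---------------------------------------------------------------------------


def pairwise_merge_stats(
    U,
    labels,
    eps: float | None = None,
    *,
    convention: str = "nk_minus_one",
):
    """Merge direction and projected Fisher score for every column pair.

    Returns ``(ii, jj, a, b, fisher_new)`` — flat arrays over pairs i < j in
    lexicographic order.  Matches :func:`merge_direction` applied per pair.
    """
    U = np.asarray(U, dtype=float)
    scat = scatter_matrices(U, labels, convention=convention)
    s_w, s_b = scat.s_w, scat.s_b
    if convention == "standard":
        f_num = s_b
    else:
        f_num = scatter_matrices(U, labels, convention="standard").s_b

    ii, jj = np.triu_indices(U.shape[1], k=1)
    wii, wjj, wij = s_w[ii, ii], s_w[jj, jj], s_w[ii, jj]
    bii, bjj, bij = s_b[ii, ii], s_b[jj, jj], s_b[ii, jj]

    # per-pair regularization, mirroring the full-matrix rule at d = 2
    tr = wii + wjj
    disc = np.sqrt((wii - wjj) ** 2 + 4.0 * wij**2)
    lam_min = 0.5 * (tr - disc)
    thr = _SINGULAR_RTOL * (1.0 + tr / 2.0)
    eps_p = (
        np.maximum(_EPS_RTOL * tr / 2.0, _EPS_FLOOR)
        if eps is None
        else np.full_like(tr, float(eps))
    )
    j_add = np.where(lam_min > thr, 0.0, np.ceil((thr - lam_min) / eps_p))
    bump = lam_min + j_add * eps_p <= thr
    j_add[bump] += 1.0
    add = j_add * eps_p
    wii_r, wjj_r = wii + add, wjj + add

    det = wii_r * wjj_r - wij**2
    m11 = (wjj_r * bii - wij * bij) / det
    m12 = (wjj_r * bij - wij * bjj) / det
    m21 = (wii_r * bij - wij * bii) / det
    m22 = (wii_r * bjj - wij * bij) / det
    lam = 0.5 * (
        (m11 + m22) + np.sqrt(np.maximum((m11 - m22) ** 2 + 4 * m12 * m21, 0.0))
    )
    v1 = np.stack([m12, lam - m11])
    v2 = np.stack([lam - m22, m21])
    n1 = np.linalg.norm(v1, axis=0)
    n2 = np.linalg.norm(v2, axis=0)
    v = np.where(n1 >= n2, v1, v2)
    degenerate = np.maximum(n1, n2) <= 1e-300
    v[0, degenerate] = 1.0
    v[1, degenerate] = 0.0
    v /= np.linalg.norm(v, axis=0)
    a, b = v[0], v[1]
    # first-significant-component-positive sign convention
    norm_scale = np.maximum(np.abs(a), np.abs(b))
    a_sig = np.abs(a) > 1e-12 * norm_scale
    flip = np.where(a_sig, a < 0, b < 0)
    a = np.where(flip, -a, a)
    b = np.where(flip, -b, b)

    num = a**2 * f_num[ii, ii] + 2 * a * b * f_num[ii, jj] + b**2 * f_num[jj, jj]
    den = a**2 * wii + 2 * a * b * wij + b**2 * wjj
    with np.errstate(divide="ignore", invalid="ignore"):
        fisher_new = np.where(
            den > 0.0, num / np.where(den > 0.0, den, 1.0),
            np.where(num > 1e-30, np.inf, 0.0),
        )
    return ii, jj, a, b, fisher_new
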