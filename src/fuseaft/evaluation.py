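"""Result metrics: relative overlap, relative Euclidean distance,
hierarchical clustering of cohorts, concordance, and TPR/FPR/NG for
simulation studies."""

from __future__ import annotations

import warnings

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .exceptions import (
    DataFormatError,
    UndefinedConcordanceError,
    UndefinedDistanceError,
)

__all__ = [
    "relative_overlap",
    "relative_overlap_matrix",
    "relative_euclidean_distance",
    "distance_matrix",
    "cluster_cancers",
    "c_statistic",
    "c_statistic_ipcw",
    "identification_metrics",
]


def relative_overlap(setA, setB) -> float:
    """Jaccard index |A n B| / |A u B|; two empty sets give 0 with a warning."""
    A, B = set(setA), set(setB)
    union = A | B
    if not union:
        warnings.warn("relative overlap of two empty sets defined as 0")
        return 0.0
    return len(A & B) / len(union)


def relative_overlap_matrix(selected: np.ndarray, gene_ids=None) -> np.ndarray:
    """K x K ROL matrix from a p x K selection indicator."""
    sel = np.asarray(selected, dtype=bool)
    K = sel.shape[1]
    out = np.ones((K, K))
    for a in range(K):
        for b in range(a + 1, K):
            A = set(np.flatnonzero(sel[:, a]))
            B = set(np.flatnonzero(sel[:, b]))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out[a, b] = out[b, a] = relative_overlap(A, B)
        if not sel[:, a].any():
            out[a, a] = 0.0  # empty set: diagonal convention follows ROL(A,A)
    return out


def relative_euclidean_distance(coefA, coefB) -> float:
    """sum_j (a_j - b_j)^2 / sqrt(sum_j a_j^2 * sum_j b_j^2).

    Zero iff the vectors coincide; equals 2 for equal-norm orthogonal
    vectors.  Undefined (error) when both vectors are all-zero.
    """
    a = np.asarray(coefA, dtype=float)
    b = np.asarray(coefB, dtype=float)
    na2, nb2 = float(a @ a), float(b @ b)
    if na2 == 0.0 and nb2 == 0.0:
        raise UndefinedDistanceError("both coefficient vectors are all-zero")
    denom = np.sqrt(na2 * nb2)
    if denom == 0.0:
        return float(np.inf)
    return float(np.sum((a - b) ** 2) / denom)


def distance_matrix(coef: np.ndarray) -> np.ndarray:
    """K x K relative Euclidean distance matrix from a p x K coefficient
    matrix."""
    coef = np.asarray(coef, dtype=float)
    K = coef.shape[1]
    out = np.zeros((K, K))
    for a in range(K):
        for b in range(a + 1, K):
            out[a, b] = out[b, a] = relative_euclidean_distance(
                coef[:, a], coef[:, b]
            )
    return out


def cluster_cancers(dist: np.ndarray) -> np.ndarray:
    """Average-linkage agglomerative clustering of a symmetric distance
    matrix.  Returns the scipy linkage matrix (merge history); scipy's
    deterministic index-order tie-break applies.
    """
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise DataFormatError("distance matrix must be square")
    if not np.allclose(dist, dist.T):
        raise DataFormatError("distance matrix must be symmetric")
    if np.any(np.diag(dist) != 0):
        raise DataFormatError("distance matrix must have a zero diagonal")
    if np.any(dist < 0):
        raise DataFormatError("distances must be nonnegative")
    return linkage(squareform(dist, checks=False), method="average")


def c_statistic(scores, y, delta, clip: bool = False) -> float:
    """Censoring-aware pairwise concordance.

    Usable pairs are (i, j) with ``y_i < y_j`` and ``delta_i = 1``; a pair is
    concordant when the earlier-event subject has the lower predicted score
    (scores are predicted log times: higher = longer survival).  Score ties
    count 1/2.  ``clip=True`` truncates the returned value to [0.5, 1] as in
    summary tables; the raw value is returned by default.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=float)
    d = np.asarray(delta).astype(bool)
    usable = (y[:, None] < y[None, :]) & d[:, None]
    n_usable = int(usable.sum())
    if n_usable == 0:
        raise UndefinedConcordanceError("no usable pair for the C-statistic")
    conc = (s[:, None] < s[None, :]) & usable
    ties = (s[:, None] == s[None, :]) & usable
    c = (conc.sum() + 0.5 * ties.sum()) / n_usable
    if clip:
        c = min(max(c, 0.5), 1.0)
    return float(c)


def c_statistic_ipcw(scores, y, delta) -> float:
    """Uno-type IPCW concordance (via scikit-survival), truncated at the
    largest event time.  Provided as a fidelity variant of :func:`c_statistic`.
    """
    from sksurv.metrics import concordance_index_ipcw

    y = np.asarray(y, dtype=float)
    d = np.asarray(delta).astype(bool)
    surv = np.array(list(zip(d, y)), dtype=[("event", bool), ("time", float)])
    tau = y[d].max()
    # risk score: higher = worse outcome, so negate predicted log time
    c, *_ = concordance_index_ipcw(surv, surv, -np.asarray(scores), tau=tau)
    return float(c)


def identification_metrics(selected: np.ndarray, truth: np.ndarray):
    """(TPR, FPR, NG) of a p x K selection indicator against the truth.

    TPR/FPR are per-cohort rates averaged over cohorts; NG counts genes that
    are causal in *every* cohort and selected in every cohort.
    """
    sel = np.asarray(selected, dtype=bool)
    tru = np.asarray(truth, dtype=bool)
    if sel.shape != tru.shape:
        raise DataFormatError("selected and truth shapes differ")
    p, K = tru.shape
    sizes = tru.sum(axis=0)
    if np.any(sizes == 0):
        raise ValueError("a cohort has an empty causal set")
    tp = (sel & tru).sum(axis=0)
    fp = (sel & ~tru).sum(axis=0)
    tpr = float(np.mean(tp / sizes))
    fpr = float(np.mean(fp / (p - sizes)))
    common_causal = tru.all(axis=1)
    ng = int(np.sum(common_causal & sel.all(axis=1)))
    return tpr, fpr, ng
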