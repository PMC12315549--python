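"""Functional clustering of biomarkers: Jaccard distances over GO-group
annotation vectors, Ward agglomeration, and a minimum-size cutoff.

Ward's criterion formally assumes squared-Euclidean geometry; here the
Lance-Williams Ward update is applied directly to the supplied Jaccard
dissimilarities (no embedding), matching the semantics of common hierarchical
clustering libraries.  Because such input can violate the triangle/Euclidean
conditions, merge heights may occasionally invert; flat clusterings are
therefore defined by merge *index* (all merges up to a cut applied in merge
order), which stays well-defined regardless.

Ties between equally distant pairs are broken toward the lexicographically
smallest node-index pair, making the dendrogram deterministic across
platforms.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .containers import ClusterAssignment


def jaccard_distance_matrix(incidence: np.ndarray, protein_ids=None) -> np.ndarray:
    """Pairwise ``1 - |A∩B| / |A∪B|`` over annotation rows of a binary matrix."""
    inc = np.asarray(incidence)
    if inc.ndim != 2:
        raise ValueError("incidence must be 2-D (proteins x annotation groups)")
    if not np.isin(inc, (0, 1)).all():
        raise ValueError("incidence entries must be binary")
    empty = np.flatnonzero(inc.sum(axis=1) == 0)
    if empty.size:
        name = protein_ids[empty[0]] if protein_ids is not None else f"row {empty[0]}"
        raise ValueError(f"protein {name} has no annotations; Jaccard distance undefined")
    return squareform(pdist(inc.astype(bool), metric="jaccard"))


def ward_linkage(D: np.ndarray) -> np.ndarray:
    """Agglomerative merge sequence under the Lance-Williams Ward update.

    Returns a ``(p-1, 4)`` array of ``(left, right, height, size)`` records in
    scipy linkage convention: leaves are ``0..p-1`` and the merge produced by
    row ``t`` is node ``p + t``.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError(f"distance matrix must be square, got {D.shape}")
    if np.any(D < 0) or not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("distance matrix must be symmetric, nonnegative, zero-diagonal")
    p = D.shape[0]
    if p < 2:
        raise ValueError("need at least two leaves")
    # squared distances drive the Ward recursion; heights are reported on the
    # original distance scale
    D2 = D.astype(float) ** 2
    size = {i: 1 for i in range(p)}
    active = list(range(p))
    dist2 = {}
    for a in range(p):
        for b in range(a + 1, p):
            dist2[(a, b)] = D2[a, b]
    merges = np.empty((p - 1, 4))
    next_id = p
    for t in range(p - 1):
        best = None
        for ia in range(len(active)):
            for ib in range(ia + 1, len(active)):
                a, b = active[ia], active[ib]
                key = (a, b) if a < b else (b, a)
                d = dist2[key]
                if best is None or d < best[0] - 1e-15 or (
                    abs(d - best[0]) <= 1e-15 and key < best[1]
                ):
                    best = (d, key)
        d2_ab, (a, b) = best
        na, nb = size[a], size[b]
        nu = na + nb
        merges[t] = (a, b, np.sqrt(max(d2_ab, 0.0)), nu)
        u = next_id
        next_id += 1
        active = [c for c in active if c not in (a, b)]
        for c in active:
            nc = size[c]
            ka = (a, c) if a < c else (c, a)
            kb = (b, c) if b < c else (c, b)
            d2_new = (
                (na + nc) * dist2[ka] + (nb + nc) * dist2[kb] - nc * d2_ab
            ) / (nu + nc)
            dist2[(c, u)] = d2_new
        active.append(u)
        size[u] = nu
    return merges


def _flat_clusters(merges: np.ndarray, p: int, n_merges: int) -> list[list[int]]:
    """Partition after applying the first ``n_merges`` merges in order."""
    comp = {i: [i] for i in range(p)}
    for t in range(n_merges):
        a, b = int(merges[t, 0]), int(merges[t, 1])
        comp[p + t] = comp.pop(a) + comp.pop(b)
    clusters = [sorted(members) for members in comp.values()]
    clusters.sort(key=lambda c: c[0])
    return clusters


def cut_at_min_size(merges: np.ndarray, p: int, min_size: int = 2) -> ClusterAssignment:
    """Lowest cut at which every flat cluster has at least ``min_size`` members.

    Candidate cuts lie between runs of equal merge heights (equal-height runs
    are applied atomically), scanned in merge order from no merges upward; the
    root cut is always feasible for ``min_size <= p``.
    """
    merges = np.asarray(merges, dtype=float)
    if min_size > p:
        raise ValueError(f"min_size {min_size} exceeds the number of proteins {p}")
    heights = merges[:, 2]
    # candidate numbers of merges to apply: 0, then after each equal-height run
    candidates = [0]
    t = 0
    while t < len(heights):
        u = t
        while u + 1 < len(heights) and abs(heights[u + 1] - heights[t]) <= 1e-12:
            u += 1
        candidates.append(u + 1)
        t = u + 1
    for n_merges in candidates:
        clusters = _flat_clusters(merges, p, n_merges)
        if min(len(c) for c in clusters) >= min_size:
            return ClusterAssignment(clusters, p)
    raise AssertionError("unreachable: the root cut satisfies any min_size <= p")


_METRICS = {"jaccard", "cosine", "euclidean", "cityblock"}


class FunctionalClusterer(BaseEstimator, ClusterMixin):
    """Groups proteins by shared functional annotation.

    Parameters
    ----------
    metric : {"jaccard", "cosine", "euclidean", "cityblock"}
        Dissimilarity between annotation rows; Jaccard is the primary choice,
        the others support sensitivity analyses.
    min_size : int
        Smallest admissible cluster; the dendrogram is cut at the lowest
        level where every cluster reaches it.

    Attributes
    ----------
    labels_ : (p,) int array of cluster indices
    assignment_ : :class:`ClusterAssignment`
    linkage_ : (p-1, 4) merge records
    distances_ : (p, p) dissimilarity matrix
    """

    def __init__(self, metric="jaccard", min_size=2):
        self.metric = metric
        self.min_size = min_size

    def fit(self, X, y=None, protein_ids=None):
        if self.metric not in _METRICS:
            raise ValueError(f"unknown metric {self.metric!r}; choose from {sorted(_METRICS)}")
        X = np.asarray(X)
        if self.metric == "jaccard":
            D = jaccard_distance_matrix(X, protein_ids=protein_ids)
        else:
            D = squareform(pdist(X.astype(float), metric=self.metric))
        self.distances_ = D
        self.linkage_ = ward_linkage(D)
        self.assignment_ = cut_at_min_size(self.linkage_, X.shape[0], self.min_size)
        self.labels_ = self.assignment_.labels()
        return self


def cluster_biomarkers(
    incidence: np.ndarray, protein_ids=None, metric: str = "jaccard", min_size: int = 2
) -> ClusterAssignment:
    """Jaccard -> Ward -> minimum-size cut, as a single deterministic call."""
    est = FunctionalClusterer(metric=metric, min_size=min_size)
    est.fit(incidence, protein_ids=protein_ids)
    return est.assignment_
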