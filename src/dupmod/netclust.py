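"""Canberra distances and McQuitty (WPGMA) hierarchical clustering.

Feature vectors of networks are compared with the Canberra distance, which
balances each component by its own scale, and clustered agglomeratively with
the McQuitty update: the distance of a merged cluster to any other cluster is
the plain average of its two constituents' distances ("reciprocal
similarity").  Tie-breaking is lexicographic on labels so runs are fully
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "canberra_distance",
    "DistanceMatrix",
    "Dendrogram",
    "mcquitty_cluster",
    "cut_dendrogram",
    "cluster_networks",
]


def canberra_distance(x, y) -> float:
    """``sum_i |x_i - y_i| / (|x_i| + |y_i|)`` with 0/0 terms contributing 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    num = np.abs(x - y)
    den = np.abs(x) + np.abs(y)
    mask = den > 0
    return float((num[mask] / den[mask]).sum())


@dataclass(frozen=True)
class DistanceMatrix:
    """Labelled symmetric distance matrix with zero diagonal."""

    labels: tuple
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] != len(self.labels):
            raise ValueError("d must be square with one row per label")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(d < 0):
            raise ValueError("distances must be non-negative")


@dataclass
class Dendrogram:
    """Binary merge tree in linkage form.

    Leaves carry ids ``0 .. n-1`` (in ``leaves`` order); the cluster created
    by merge ``t`` has id ``n + t``.  ``merges`` lists ``(id_a, id_b, height,
    size)`` in merge order.  Heights are the inter-cluster distances at merge
    time; the McQuitty update can produce inversions, so heights need not be
    monotone.
    """

    leaves: tuple
    merges: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.leaves)

    def to_linkage(self) -> np.ndarray:
        """SciPy-style ``(n-1) x 4`` linkage matrix."""
        return np.array([[a, b, h, s] for a, b, h, s in self.merges], dtype=float)


def mcquitty_cluster(dm: DistanceMatrix) -> Dendrogram:
    """Agglomerate by repeatedly merging the closest pair of clusters.

    After merging clusters ``a`` and ``b``, the distance of the new cluster to
    any other cluster ``k`` is ``(d(a,k) + d(b,k)) / 2``.  Among equally close
    pairs the one whose (lexicographically smallest-label) representatives
    sort first is merged, so the tree is reproducible.
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("need at least 2 items to cluster")
    d = {}
    for i in range(n):
        for j in range(i + 1, n):
            d[(i, j)] = float(dm.d[i, j])
    # representative label of each active cluster = its smallest member label
    rep = {i: str(dm.labels[i]) for i in range(n)}
    size = {i: 1 for i in range(n)}
    active = set(range(n))
    merges = []
    next_id = n
    while len(active) > 1:
        best = min(
            d.items(),
            key=lambda kv: (kv[1], min(rep[kv[0][0]], rep[kv[0][1]]), max(rep[kv[0][0]], rep[kv[0][1]])),
        )
        (a, b), height = best
        new = next_id
        next_id += 1
        merges.append((a, b, height, size[a] + size[b]))
        active.discard(a)
        active.discard(b)
        for k in active:
            da = d.pop((min(a, k), max(a, k)))
            db = d.pop((min(b, k), max(b, k)))
            d[(min(new, k), max(new, k))] = 0.5 * (da + db)
        del d[(a, b)]
        rep[new] = min(rep[a], rep[b])
        size[new] = size[a] + size[b]
        active.add(new)
    return Dendrogram(leaves=tuple(dm.labels), merges=merges)


def cut_dendrogram(dend: Dendrogram, k: int) -> dict:
    """Undo the last ``k - 1`` merges and label the remaining subtrees.

    Returns ``label -> cluster index`` with contiguous 1-based indices,
    ordered by each cluster's smallest member label.
    """
    n = dend.n
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}, got {k}")
    parent = list(range(n + len(dend.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for t, (a, b, _h, _s) in enumerate(dend.merges[: n - k]):
        new = n + t
        parent[find(a)] = new
        parent[find(b)] = new

    groups: dict[int, list] = {}
    for i, label in enumerate(dend.leaves):
        groups.setdefault(find(i), []).append(label)
    ordered = sorted(groups.values(), key=lambda ms: min(str(x) for x in ms))
    return {label: idx for idx, members in enumerate(ordered, start=1) for label in members}


def cluster_networks(features, subset, min_max_scale: bool = False):
    """Project feature vectors onto ``subset`` and cluster them.

    ``features`` is a sequence of :class:`~dupmod.measures.FeatureVector`;
    their ``name`` fields label the leaves.  Canberra already balances scales
    per component, so features are used raw; ``min_max_scale`` optionally
    rescales each feature to [0, 1] for sensitivity analysis.  Returns
    ``(dendrogram, distance_matrix)``.
    """
    subset = tuple(subset)
    if not subset:
        raise ValueError("feature subset must be non-empty")
    labels = tuple(fv.name for fv in features)
    if len(set(labels)) != len(labels):
        raise ValueError("feature vectors must have unique names")
    x = np.array([fv.values(subset) for fv in features], dtype=float)
    if min_max_scale:
        span = x.max(axis=0) - x.min(axis=0)
        span[span == 0] = 1.0
        x = (x - x.min(axis=0)) / span
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = canberra_distance(x[i], x[j])
    dm = DistanceMatrix(labels=labels, d=d)
    return mcquitty_cluster(dm), dm
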