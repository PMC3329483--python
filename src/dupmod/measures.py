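"""Module-level structural measures.

Once a partition of a network into modules is found, the network is summarised
by its *module network*: a weighted graph on the modules whose edge weight
``a[i][j]`` counts the links running between module ``i`` and module ``j``
(self-connections are set to zero).  All measures below are computed on this
module network, never on the raw graph, so that they capture specifically the
organisation *among* modules:

* ``s_rel`` - relative size of the largest module,
* ``h_conn`` - normalized entropy of the module connectivity (how evenly
  total inter-module connectivity is spread over modules),
* ``h_mod`` - mean normalized module-wise entropy (how evenly each module
  spreads its links over the other modules),
* ``nmi`` - normalized mutual information of the inter-module link matrix.

Together with the module count ``m`` and the modularity ``q`` of the chosen
partition these form the feature vector of a network.

Conventions for degenerate cases (natural log throughout; ``0 ln 0 := 0``):
a single module has no inter-module structure, so ``h_conn = h_mod = nmi = 0``
and ``s_rel = 1``; at ``m = 2`` each module has only one possible partner, a
one-outcome distribution with no diversity, so ``h_mod = 0``; modules with no
inter-module links contribute zero entropy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .communities import giant_connected_component, girvan_newman

__all__ = [
    "ModuleNetwork",
    "FeatureVector",
    "build_module_network",
    "relative_module_size",
    "module_connectivity_entropy",
    "modulewise_entropy",
    "normalized_mutual_information",
    "compute_feature_vector",
    "CORE_FEATURES",
    "EXTRA_FEATURES",
]

CORE_FEATURES = ("m", "q", "s_rel", "h_conn", "h_mod", "nmi")
#: optional extras, off by default: these are whole-network measures, not
#: module-network measures, provided for sensitivity experiments only
EXTRA_FEATURES = ("density", "gcc_frac")


@dataclass(frozen=True)
class ModuleNetwork:
    """Symmetric inter-module link-count matrix plus module sizes.

    ``a`` is an ``m x m`` integer matrix with zero diagonal where ``a[i, j]``
    counts edges between modules ``i`` and ``j``; ``c[i]`` is the number of
    nodes in module ``i``.  Rows follow ascending module index of the source
    partition.
    """

    a: np.ndarray
    c: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.a)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("a must be a square matrix")
        if not np.array_equal(a, a.T):
            raise ValueError("a must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("a must have a zero diagonal")
        if np.any(a < 0):
            raise ValueError("a must be non-negative")
        if len(self.c) != a.shape[0]:
            raise ValueError("c must have one entry per module")

    @property
    def m(self) -> int:
        return self.a.shape[0]

    @property
    def w(self) -> float:
        """Twice the number of inter-module connections."""
        return float(self.a.sum())


def build_module_network(net: nx.Graph, partition: dict) -> ModuleNetwork:
    """Count inter-module edges for every module pair.

    ``partition`` maps every node of ``net`` to a module index; indices are
    ranked ascending to form the matrix rows.  Intra-module edges only affect
    the (zeroed) diagonal and are discarded.
    """
    if set(partition) != set(net.nodes):
        raise ValueError("partition must cover exactly the network's nodes")
    modules = sorted(set(partition.values()))
    rank = {s: i for i, s in enumerate(modules)}
    m = len(modules)
    a = np.zeros((m, m), dtype=np.int64)
    c = np.zeros(m, dtype=np.int64)
    for v, s in partition.items():
        c[rank[s]] += 1
    for u, v in net.edges:
        i, j = rank[partition[u]], rank[partition[v]]
        if i != j:
            a[i, j] += 1
            a[j, i] += 1
    return ModuleNetwork(a=a, c=c)


def relative_module_size(mn: ModuleNetwork) -> float:
    """Size of the largest module relative to the whole network."""
    total = int(mn.c.sum())
    if total == 0:
        raise ValueError("module network has no nodes")
    return float(mn.c.max()) / total


def _entropy(p: np.ndarray) -> float:
    """Shannon entropy in nats with the 0*ln(0) = 0 convention."""
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def module_connectivity_entropy(mn: ModuleNetwork) -> float:
    """Normalized entropy of the module connectivity.

    Each module contributes its total inter-module connectivity
    ``k_i = sum_j a[i, j]`` as a probability ``p_i = k_i / W`` (``W`` twice the
    inter-module edge count); the entropy of ``p`` is normalized by ``ln m``.
    """
    if mn.m <= 1:
        return 0.0
    k = mn.a.sum(axis=1).astype(float)
    w = k.sum()
    if w == 0:
        return 0.0
    return _entropy(k / w) / math.log(mn.m)


def modulewise_entropy(mn: ModuleNetwork, normalization: str = "m-1") -> float:
    """Mean normalized module-wise entropy.

    For each module ``i`` with inter-module connectivity the row of ``a`` is
    turned into a probability vector over the ``m - 1`` other modules and its
    entropy normalized by ``ln(m - 1)`` (``normalization="m"`` switches to
    ``ln m`` for sensitivity checks); the result is averaged over all modules.
    """
    if normalization not in ("m-1", "m"):
        raise ValueError("normalization must be 'm-1' or 'm'")
    if mn.m <= 1:
        return 0.0
    denom = math.log(mn.m - 1) if normalization == "m-1" else math.log(mn.m)
    if denom == 0.0:  # m == 2: one-outcome distributions have no diversity
        return 0.0
    total = 0.0
    for i in range(mn.m):
        k_i = float(mn.a[i].sum())
        if k_i == 0:
            continue
        total += _entropy(mn.a[i] / k_i) / denom
    return total / mn.m


def normalized_mutual_information(mn: ModuleNetwork) -> float:
    """Mutual information of the joint link distribution over module pairs,
    normalized by the marginal entropy.

    ``p[i, j] = a[i, j] / W`` is the probability that a randomly chosen end of
    a randomly chosen inter-module link connects modules ``i`` and ``j``; by
    symmetry the row and column marginals coincide, and ``nmi = I(p) / H(p_i)``.
    """
    if mn.m < 2:
        return 0.0
    w = mn.w
    if w == 0:
        return 0.0
    p = mn.a / w
    marginal = p.sum(axis=1)
    h = _entropy(marginal)
    if h <= 0:
        return 0.0
    info = 0.0
    for i in range(mn.m):
        for j in range(mn.m):
            if p[i, j] > 0:
                info += p[i, j] * math.log(p[i, j] / (marginal[i] * marginal[j]))
    return info / h


@dataclass
class FeatureVector:
    """Module-level feature vector of one network."""

    name: str
    m: int
    q: float
    s_rel: float
    h_conn: float
    h_mod: float
    nmi: float
    extras: dict = field(default_factory=dict)
    class_label: str = "OTHER"

    def as_dict(self) -> dict:
        out = {k: getattr(self, k) for k in CORE_FEATURES}
        out.update(self.extras)
        return out

    def values(self, subset) -> list[float]:
        """Feature values projected onto ``subset`` (order preserved)."""
        table = self.as_dict()
        missing = [f for f in subset if f not in table]
        if missing:
            raise KeyError(f"unknown feature(s) {missing} for network {self.name!r}")
        return [float(table[f]) for f in subset]

    @property
    def feature_names(self) -> tuple:
        return CORE_FEATURES + tuple(self.extras)


def compute_feature_vector(
    net: nx.Graph,
    name: str = "",
    class_label: str = "OTHER",
    gcc: bool = True,
    backend: str = "native",
    extras: tuple = (),
) -> FeatureVector:
    """Full per-network pipeline: GCC -> community detection -> module measures.

    ``extras`` may list optional whole-network features from
    :data:`EXTRA_FEATURES` (edge density of the input network and relative GCC
    size); these are not module-network measures and are off by default.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("cannot compute features of an empty network")
    n_full = net.number_of_nodes()
    work = giant_connected_component(net) if gcc else net
    part, q, _ = girvan_newman(work, backend=backend)
    mn = build_module_network(work, part)
    extra_values = {}
    for f in extras:
        if f == "density":
            e = net.number_of_edges()
            extra_values[f] = 2.0 * e / (n_full * (n_full - 1)) if n_full > 1 else 0.0
        elif f == "gcc_frac":
            extra_values[f] = work.number_of_nodes() / n_full if gcc else 1.0
        else:
            raise KeyError(f"unknown extra feature {f!r}")
    return FeatureVector(
        name=name,
        m=mn.m,
        q=q,
        s_rel=relative_module_size(mn),
        h_conn=module_connectivity_entropy(mn),
        h_mod=modulewise_entropy(mn),
        nmi=normalized_mutual_information(mn),
        extras=extra_values,
        class_label=class_label,
    )
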