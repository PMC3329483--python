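"""Giant-component extraction and edge-betweenness community detection.

The detection algorithm is the classic divisive one: repeatedly remove the
edge lying on the most shortest paths, track the component structure as the
network falls apart, and keep the partition with maximal modularity Q.  Two
backends expose the same contract:

* ``"native"`` - a pure-Python loop around Brandes edge betweenness with
  deterministic lexicographic tie-breaking and a full removal trace;
* ``"igraph"`` - the same algorithm in C, for cohort-scale runs (no trace).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "giant_connected_component",
    "edge_betweenness",
    "modularity",
    "girvan_newman",
    "RemovalTrace",
    "partition_from_components",
]

#: above this many nodes the native divisive loop emits a runtime warning
DEFAULT_NODE_CEILING = 3000


@dataclass
class RemovalTrace:
    """Ordered record of the divisive algorithm's splits.

    ``entries`` holds ``(removed_edge, partition, q)`` triples appended each
    time an edge removal changed the component structure; the initial
    component partition is recorded with ``removed_edge = None``.
    """

    entries: list[tuple[tuple | None, dict, float]] = field(default_factory=list)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def best(self) -> tuple[dict, float]:
        """Partition with maximal modularity (earliest wins ties)."""
        best_part, best_q = None, float("-inf")
        for _, part, q in self.entries:
            if q > best_q:
                best_part, best_q = part, q
        return best_part, best_q


def giant_connected_component(net: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest connected component.

    Ties between equally large components are broken toward the component
    containing the smallest node label (string order).
    """
    if net.number_of_nodes() == 0:
        raise ValueError("cannot take the giant component of an empty network")
    components = sorted(
        nx.connected_components(net),
        key=lambda c: (-len(c), min(str(v) for v in c)),
    )
    return net.subgraph(components[0]).copy()


def edge_betweenness(net: nx.Graph) -> dict:
    """Shortest-path betweenness of every edge.

    For each unordered node pair the unit of path count is split fractionally
    among equal-length shortest paths; the value of an edge is the sum over
    all pairs of the fraction of shortest paths traversing it.
    """
    raw = nx.edge_betweenness_centrality(net, normalized=False)
    return {_canonical_edge(u, v): val for (u, v), val in raw.items()}


def _canonical_edge(u, v) -> tuple:
    return (u, v) if str(u) <= str(v) else (v, u)


def modularity(net: nx.Graph, partition: dict) -> float:
    """Newman-Girvan modularity of a non-overlapping partition.

    ``Q = sum_s [ l_s/L - (d_s/(2L))^2 ]`` with ``L`` total edges, ``l_s``
    intra-module edges and ``d_s`` the total degree of module ``s``.  An
    edgeless network has ``Q = 0`` by convention.
    """
    if set(partition) != set(net.nodes):
        raise ValueError("partition must cover exactly the network's nodes")
    L = net.number_of_edges()
    if L == 0:
        return 0.0
    intra: dict = {}
    degree: dict = {}
    for u, v in net.edges:
        su, sv = partition[u], partition[v]
        degree[su] = degree.get(su, 0) + 1
        degree[sv] = degree.get(sv, 0) + 1
        if su == sv:
            intra[su] = intra.get(su, 0) + 1
    q = 0.0
    for s in set(partition.values()):
        ls = intra.get(s, 0)
        ds = degree.get(s, 0)
        q += ls / L - (ds / (2.0 * L)) ** 2
    return q


def partition_from_components(net: nx.Graph) -> dict:
    """Assign each connected component a contiguous module index (1-based).

    Components are ordered by their smallest node label (string order) so the
    indexing is reproducible.
    """
    comps = sorted(nx.connected_components(net), key=lambda c: min(str(v) for v in c))
    return {v: i for i, comp in enumerate(comps, start=1) for v in comp}


def _singleton_partition(net: nx.Graph) -> dict:
    return {v: i for i, v in enumerate(sorted(net.nodes, key=str), start=1)}


def girvan_newman(
    net: nx.Graph,
    backend: str = "native",
    node_ceiling: int = DEFAULT_NODE_CEILING,
) -> tuple[dict, float, RemovalTrace | None]:
    """Divisive edge-betweenness community detection with modularity-optimal cut.

    Returns ``(partition, q, trace)`` where ``partition`` maps every node to
    a 1-based module index and ``q`` is its modularity.  The native backend
    removes, at each step, the lexicographically smallest edge among those of
    maximal betweenness (full determinism) and records every split in the
    returned :class:`RemovalTrace`; the igraph backend returns ``trace=None``.
    Edgeless input yields the singleton partition with ``q = 0``.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("cannot detect communities in an empty network")
    if net.number_of_edges() == 0:
        return _singleton_partition(net), 0.0, RemovalTrace()
    if backend == "igraph":
        return _girvan_newman_igraph(net)
    if backend != "native":
        raise ValueError(f"unknown backend {backend!r}")
    if net.number_of_nodes() > node_ceiling:
        warnings.warn(
            f"divisive edge-betweenness on {net.number_of_nodes()} nodes exceeds the "
            f"complexity ceiling ({node_ceiling}); expect O(m^2 n) runtime",
            RuntimeWarning,
            stacklevel=2,
        )

    work = net.copy()
    trace = RemovalTrace()
    part = partition_from_components(work)
    trace.entries.append((None, part, modularity(net, part)))
    n_components = max(part.values())

    # betweenness only changes inside the component that lost the edge, so we
    # keep a cache and recompute on that component's induced subgraph
    bet = edge_betweenness(work)
    while work.number_of_edges() > 0:
        target = max(bet, key=lambda e: (bet[e], (str(e[0]), str(e[1]))))
        best_val = bet[target]
        ties = [e for e, val in bet.items() if val == best_val]
        target = min(ties, key=lambda e: (str(e[0]), str(e[1])))
        component = nx.node_connected_component(work, target[0])
        work.remove_edge(*target)
        del bet[target]
        sub = work.subgraph(component)
        for e in list(bet):
            if e[0] in component:
                del bet[e]
        bet.update(edge_betweenness(sub))
        new_n = nx.number_connected_components(work)
        if new_n > n_components:
            n_components = new_n
            part = partition_from_components(work)
            trace.entries.append((target, part, modularity(net, part)))
    best_part, best_q = trace.best()
    return best_part, best_q, trace


def _girvan_newman_igraph(net: nx.Graph) -> tuple[dict, float, None]:
    import igraph

    nodes = sorted(net.nodes, key=str)
    index = {v: i for i, v in enumerate(nodes)}
    g = igraph.Graph(
        n=len(nodes), edges=[(index[u], index[v]) for u, v in net.edges], directed=False
    )
    dendro = g.community_edge_betweenness(directed=False)
    clustering = dendro.as_clustering()
    part = {}
    for module_idx, members in enumerate(clustering, start=1):
        for i in members:
            part[nodes[i]] = module_idx
    return part, modularity(net, part), None
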