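import itertools

import networkx as nx
import numpy as np
import pytest


@pytest.fixture
def two_triangles_bridge():
    """Two 3-cliques joined by a single bridge; modules are the triangles."""
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c"), ("c", "a"),
                      ("d", "e"), ("e", "f"), ("f", "d"),
                      ("c", "d")])
    return g


@pytest.fixture
def triangle_partition():
    return {"a": 1, "b": 1, "c": 1, "d": 2, "e": 2, "f": 2}


def random_graph(n, p, seed):
    return nx.gnp_random_graph(n, p, seed=seed)


def brute_edge_betweenness(g):
    """Independent oracle: enumerate every pair's shortest paths explicitly."""
    bet = {tuple(sorted(e, key=str)): 0.0 for e in g.edges}
    for s, t in itertools.combinations(sorted(g.nodes, key=str), 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        share = 1.0 / len(paths)
        for path in paths:
            for u, v in zip(path, path[1:]):
                bet[tuple(sorted((u, v), key=str))] += share
    return bet


def brute_module_matrix(g, partition):
    """Independent oracle: classify every edge by its endpoint modules."""
    modules = sorted(set(partition.values()))
    rank = {s: i for i, s in enumerate(modules)}
    a = np.zeros((len(modules), len(modules)), dtype=int)
    for u, v in g.edges:
        i, j = rank[partition[u]], rank[partition[v]]
        if i != j:
            a[i, j] += 1
            a[j, i] += 1
    return a
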