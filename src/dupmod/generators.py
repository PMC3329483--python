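"""Seeded stochastic network generators.

Three growth/benchmark models produce the synthetic populations studied by the
pipeline:

* **NGD** (network gene duplication): a gene and all its interactions are
  duplicated, the duplicate pair then diverges by losing edges from common
  edge pairs, and the new gene may gain interactions to the rest of the
  genome.
* **DMC** (duplication-mutation-complementation): duplication and divergence
  as in NGD, but the only new interaction is the complementation link between
  the new gene and its template.
* **SCN** (synthetic community network): an LFR-style benchmark graph with
  planted power-law communities controlled by a mixing parameter ``mu``.

A planted-partition block model is provided as a deterministic-structure test
fixture, together with ensemble helpers.

All generators are fully deterministic given their ``seed``.
"""

from __future__ import annotations

import dataclasses
import random
from collections.abc import Callable, Mapping, Sequence
from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "NgdParams",
    "DmcParams",
    "ScnParams",
    "NetworkEnsemble",
    "generate_ngd",
    "generate_dmc",
    "generate_scn",
    "generate_planted_partition",
    "generate_ensemble",
    "ensemble_summary",
]

#: default seed graph: the smallest connected network (two genes, one link)
_DEFAULT_SEED_EDGES = ((0, 1),)


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value}")


@dataclass(frozen=True)
class NgdParams:
    """Parameters of the network gene duplication model.

    ``alpha_add`` is the per-gene attachment probability: after divergence the
    new gene gains an edge to each existing non-neighbour gene independently
    with this probability.  ``delta_del`` is the probability that a common
    edge pair (template-neighbour, copy-neighbour) diverges; divergence
    removes one uniformly chosen member of the pair, and the surviving member
    is then also lost with probability ``p_second``.  ``p_second`` is a
    calibration constant of the divergence step (see docs/methods.md); 0
    recovers the single-edge-loss reading.
    """

    n_final: int
    alpha_add: float
    delta_del: float
    p_second: float = 0.6
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_final < 2:
            raise ValueError(f"n_final must be >= 2, got {self.n_final}")
        _check_prob("alpha_add", self.alpha_add)
        _check_prob("delta_del", self.delta_del)
        _check_prob("p_second", self.p_second)


@dataclass(frozen=True)
class DmcParams:
    """Parameters of the duplication-mutation-complementation model.

    ``delta_del`` controls the shared divergence step (one member of each
    common edge pair is lost with this probability).  ``template_link``
    selects how the complementation edge copy-template is established:

    * ``"always"`` (default): the link is always added.  This is the variant
      calibrated against the published ensemble means, whose edge counts are
      invariant to the connection probability and follow ``E ~ N/(2*delta-1)``;
      it also keeps every replicate connected by construction.
    * ``"bernoulli"``: the link is added with probability ``q_con`` and
      connectivity is enforced by reverting and redrawing any duplication
      event that disconnects the graph (budget ``redraw_budget`` per event).
    """

    n_final: int
    q_con: float
    delta_del: float
    template_link: str = "always"
    redraw_budget: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_final < 2:
            raise ValueError(f"n_final must be >= 2, got {self.n_final}")
        _check_prob("q_con", self.q_con)
        _check_prob("delta_del", self.delta_del)
        if self.template_link not in ("always", "bernoulli"):
            raise ValueError(
                f"template_link must be 'always' or 'bernoulli', got {self.template_link!r}"
            )


@dataclass(frozen=True)
class ScnParams:
    """Parameters of the planted-community benchmark generator.

    ``mu`` is the mixing parameter: the expected fraction of each node's links
    that leave its own community.  Degrees follow a truncated power law with
    exponent ``tau_degree`` (mean ~ ``k_avg``, max ``k_max``); community sizes
    follow a power law with exponent ``tau_size`` within [c_min, c_max].
    """

    n: int
    k_avg: float
    k_max: int
    mu: float
    c_min: int
    c_max: int
    tau_degree: float = 2.0
    tau_size: float = 1.1
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.c_min <= self.c_max <= self.n:
            raise ValueError("need c_min <= c_max <= n")
        if not self.k_avg <= self.k_max < self.n:
            raise ValueError("need k_avg <= k_max < n")
        _check_prob("mu", self.mu)
        if self.tau_degree <= 1 or self.tau_size <= 1:
            raise ValueError("power-law exponents must be > 1")


@dataclass
class NetworkEnsemble:
    """A population of networks generated with identical parameters.

    ``class_label`` names the generating population (SCN, NGD, DMC, PPI or
    OTHER); replicates differ only in their seeds.
    """

    networks: list[nx.Graph]
    params: object
    class_label: str
    seeds: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.networks)


def _seed_adjacency(seed_graph: nx.Graph | None) -> dict[int, set[int]]:
    if seed_graph is None:
        adj: dict[int, set[int]] = {}
        nodes: set[int] = set()
        for u, v in _DEFAULT_SEED_EDGES:
            nodes.update((u, v))
        for u in sorted(nodes):
            adj[u] = set()
        for u, v in _DEFAULT_SEED_EDGES:
            adj[u].add(v)
            adj[v].add(u)
        return adj
    mapping = {u: i for i, u in enumerate(sorted(seed_graph.nodes, key=str))}
    adj = {i: set() for i in range(len(mapping))}
    for u, v in seed_graph.edges:
        if u == v:
            raise ValueError("seed graph must not contain self-loops")
        adj[mapping[u]].add(mapping[v])
        adj[mapping[v]].add(mapping[u])
    return adj


def _to_graph(adj: Mapping[int, set[int]]) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(sorted(adj))
    for u in sorted(adj):
        for v in adj[u]:
            if u < v:
                g.add_edge(u, v)
    return g


def _diverge_pair(
    rng: random.Random,
    adj: dict[int, set[int]],
    template: int,
    copy: int,
    neighbour: int,
    delta: float,
    p_second: float,
) -> list[tuple[int, int]]:
    """Apply the divergence step to one common edge pair; return removed edges."""
    removed: list[tuple[int, int]] = []
    if rng.random() >= delta:
        return removed
    pair = [(template, neighbour), (copy, neighbour)]
    first = rng.randrange(2)
    a, b = pair[first]
    adj[a].discard(b)
    adj[b].discard(a)
    removed.append((a, b))
    if p_second > 0.0 and rng.random() < p_second:
        a, b = pair[1 - first]
        adj[a].discard(b)
        adj[b].discard(a)
        removed.append((a, b))
    return removed


def generate_ngd(params: NgdParams, seed_graph: nx.Graph | None = None) -> nx.Graph:
    """Grow a network by gene duplication and divergence.

    Each growth event duplicates a uniformly chosen gene with all of its
    interactions, applies the divergence step to every common edge pair, and
    finally attaches the new gene to each pre-existing non-neighbour gene
    independently with probability ``alpha_add``.  Isolated genes are
    retained; connectivity is *not* enforced.
    """
    adj = _seed_adjacency(seed_graph)
    if params.n_final < len(adj):
        raise ValueError(
            f"n_final={params.n_final} is smaller than the seed graph ({len(adj)} nodes)"
        )
    rng = random.Random(params.seed)
    while len(adj) < params.n_final:
        n = len(adj)
        template = rng.randrange(n)
        copy = n
        adj[copy] = set(adj[template])
        for v in adj[copy]:
            adj[v].add(copy)
        for v in sorted(adj[copy]):
            _diverge_pair(rng, adj, template, copy, v, params.delta_del, params.p_second)
        # attachment: the template itself is a candidate, current neighbours are not
        for gene in range(n):
            if gene != copy and gene not in adj[copy] and rng.random() < params.alpha_add:
                adj[copy].add(gene)
                adj[gene].add(copy)
    return _to_graph(adj)


def _is_connected(adj: Mapping[int, set[int]]) -> bool:
    start = next(iter(adj))
    seen = {start}
    stack = [start]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return len(seen) == len(adj)


def generate_dmc(params: DmcParams, seed_graph: nx.Graph | None = None) -> nx.Graph:
    """Grow a network by duplication, divergence and complementation.

    Shares the duplication and divergence steps with :func:`generate_ngd`
    (with ``p_second = 0``: exactly one member of a diverged pair is lost) but
    the only new interaction is the complementation link between the new gene
    and its template.  Every replicate is connected: in ``"always"`` mode the
    template link itself guarantees it, in ``"bernoulli"`` mode disconnecting
    events are reverted and redrawn.
    """
    adj = _seed_adjacency(seed_graph)
    if params.n_final < len(adj):
        raise ValueError(
            f"n_final={params.n_final} is smaller than the seed graph ({len(adj)} nodes)"
        )
    rng = random.Random(params.seed)
    always = params.template_link == "always"
    while len(adj) < params.n_final:
        n = len(adj)
        for attempt in range(params.redraw_budget):
            template = rng.randrange(n)
            copy = n
            adj[copy] = set(adj[template])
            for v in adj[copy]:
                adj[v].add(copy)
            removed: list[tuple[int, int]] = []
            for v in sorted(adj[copy]):
                removed += _diverge_pair(rng, adj, template, copy, v, params.delta_del, 0.0)
            linked = always or rng.random() < params.q_con
            if linked and copy not in adj[template]:
                adj[template].add(copy)
                adj[copy].add(template)
            else:
                linked = False
            if always or _is_connected(adj):
                break
            # revert the event and redraw it
            if linked:
                adj[template].discard(copy)
            for a, b in removed:
                adj[a].add(b)
                adj[b].add(a)
            for v in adj[copy]:
                adj[v].discard(copy)
            del adj[copy]
        else:
            raise RuntimeError(
                "DMC event redraw budget exhausted for "
                f"n_final={params.n_final}, q_con={params.q_con}, delta_del={params.delta_del}"
            )
    return _to_graph(adj)


def generate_scn(params: ScnParams) -> tuple[nx.Graph, dict]:
    """Generate a benchmark network with planted communities.

    Returns the network together with its ground-truth partition (node ->
    community index, 1-based).  The partition is also stored on the graph as
    ``G.graph["planted_partition"]``.  Raises ``ValueError`` when the degree
    and community-size constraints cannot be realised (for example a maximum
    degree whose intra-community part exceeds the largest community).
    """
    rng = random.Random(params.seed)
    last_error: Exception | None = None
    for _ in range(3):  # the sampler is stochastic; a fresh sub-seed can succeed
        sub_seed = rng.randrange(2**31)
        try:
            g = nx.LFR_benchmark_graph(
                params.n,
                params.tau_degree,
                params.tau_size,
                params.mu,
                average_degree=params.k_avg,
                max_degree=params.k_max,
                min_community=params.c_min,
                max_community=params.c_max,
                seed=sub_seed,
            )
            break
        except nx.ExceededMaxIterations as exc:
            last_error = exc
    else:
        raise ValueError(
            f"infeasible degree/community constraints for {params}: {last_error}"
        )
    g.remove_edges_from(nx.selfloop_edges(g))
    communities = {frozenset(g.nodes[v]["community"]) for v in g}
    ordered = sorted(communities, key=min)
    partition = {}
    for idx, comm in enumerate(ordered, start=1):
        for v in comm:
            partition[v] = idx
    out = nx.Graph()
    out.add_nodes_from(sorted(g.nodes))
    out.add_edges_from(g.edges)
    out.graph["planted_partition"] = partition
    return out, partition


def generate_planted_partition(
    n_modules: int,
    module_size: int,
    p_in: float,
    p_out: float,
    seed: int | None = None,
) -> tuple[nx.Graph, dict]:
    """Bernoulli block model with equal-size blocks; returns (network, partition)."""
    if not p_in > p_out:
        raise ValueError(f"need p_in > p_out, got p_in={p_in}, p_out={p_out}")
    g = nx.planted_partition_graph(n_modules, module_size, p_in, p_out, seed=seed)
    partition = {v: v // module_size + 1 for v in g.nodes}
    out = nx.Graph()
    out.add_nodes_from(sorted(g.nodes))
    out.add_edges_from(g.edges)
    out.graph["planted_partition"] = partition
    return out, partition


_CLASS_BY_GENERATOR = {
    "generate_ngd": "NGD",
    "generate_dmc": "DMC",
    "generate_scn": "SCN",
    "generate_planted_partition": "OTHER",
}


def generate_ensemble(
    generator: Callable,
    params: object,
    n_replicates: int,
    base_seed: int,
    class_label: str | None = None,
) -> NetworkEnsemble:
    """Generate ``n_replicates`` networks with seeds ``base_seed .. base_seed+r-1``.

    ``class_label`` defaults to the population implied by the generator
    (NGD/DMC/SCN/OTHER).  Generators returning ``(network, partition)`` pairs
    contribute the network; the planted partition stays available on
    ``G.graph["planted_partition"]``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if class_label is None:
        class_label = _CLASS_BY_GENERATOR.get(getattr(generator, "__name__", ""), "OTHER")
    networks = []
    seeds = list(range(base_seed, base_seed + n_replicates))
    for s in seeds:
        result = generator(dataclasses.replace(params, seed=s))
        g = result[0] if isinstance(result, tuple) else result
        networks.append(g)
    return NetworkEnsemble(networks=networks, params=params, class_label=class_label, seeds=seeds)


def ensemble_summary(ensemble: NetworkEnsemble):
    """Per-replicate node/edge/density/GCC table plus the ensemble means.

    Density is ``2E / (N (N-1))`` computed per network and then averaged.
    Returns a pandas DataFrame with one row per replicate and a final
    ``"mean"`` row of arithmetic means.
    """
    import pandas as pd

    if not ensemble.networks:
        raise ValueError("empty ensemble")
    rows = []
    for g in ensemble.networks:
        n = g.number_of_nodes()
        e = g.number_of_edges()
        density = 2.0 * e / (n * (n - 1)) if n > 1 else 0.0
        gcc = max((len(c) for c in nx.connected_components(g)), default=0)
        rows.append({"nodes": n, "edges": e, "density": density, "gcc": gcc})
    frame = pd.DataFrame(rows, index=[f"rep{i}" for i in range(len(rows))])
    frame.loc["mean"] = frame.mean()
    return frame
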