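"""Prize-collecting subnetwork extraction.

Connects the proteins with temporal evidence (prizes) to the source
receptor through the background interactome, trading excluded-prize cost
against edge cost, in the style of prize-collecting Steiner forest tools for
omics integration. Kinase-substrate edges are projected onto undirected
edges here; direction is re-imposed later by the partial model during
synthesis.

The solver is a deliberately simple randomized greedy: each run jitters the
prizes, grows a source-rooted tree by repeatedly attaching the prized node
with the best (scaled prize - path cost) margin along its cheapest path, and
prunes unprofitable leaves. Edges kept in at least an inclusion fraction of
runs form the subnetwork. An exhaustive optimum over connected node subsets
is provided for small instances as an independent reference.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .containers import Interactome, SubNetwork
from .errors import ConfigError, DataError


@dataclass
class PCSFParams:
    """Extraction parameters.

    dummy_edge_weight (omega) is the cost of attaching the root to the
    network — kept for interface fidelity with Steiner-forest tools; with a
    single designated source it does not influence the rooted construction.
    edge_reliability (beta) scales prizes against edge costs; degree_penalty
    (g) is accepted but zero in this pipeline. n_randomizations greedy runs
    with multiplicative prize jitter of +/- noise_scale are aggregated by
    keeping edges present in >= inclusion_frequency of runs.
    """

    dummy_edge_weight: float = 10.0
    edge_reliability: float = 10.0
    degree_penalty: float = 0.0
    n_randomizations: int = 100
    inclusion_frequency: float = 0.5
    noise_scale: float = 0.1

    def __post_init__(self) -> None:
        if self.dummy_edge_weight <= 0 or self.edge_reliability <= 0:
            raise ConfigError("dummy_edge_weight and edge_reliability must be > 0")
        if self.degree_penalty < 0:
            raise ConfigError("degree_penalty must be >= 0")
        if self.n_randomizations < 1:
            raise ConfigError("need >= 1 randomization run")
        if not 0 < self.inclusion_frequency <= 1:
            raise ConfigError("inclusion_frequency must be in (0,1]")


def edge_cost(confidence: float) -> float:
    """Cost of including an edge: 1 - confidence."""
    return 1.0 - confidence


def projected_graph(net: Interactome) -> nx.Graph:
    """Undirected working graph: PPI edges plus undirected projections of
    kinase-substrate edges (a projected edge inherits confidence 0.5 when
    the pair has no PPI support)."""
    g = nx.Graph()
    for n, d in net.ppi.nodes(data=True):
        g.add_node(n, is_kinase=d["is_kinase"])
    for u, v, d in net.ppi.edges(data=True):
        g.add_edge(u, v, confidence=d["confidence"])
    for u, v in net.ks.edges:
        if not g.has_edge(u, v):
            g.add_edge(u, v, confidence=0.5)
    return g


def pcsf_objective(
    tree_edges: list[tuple[str, str]],
    included_nodes: set[str],
    prizes: dict[str, float],
    params: PCSFParams,
    graph: nx.Graph,
) -> float:
    """Score of a candidate solution; lower is better.

    score = beta * sum of prizes of excluded nodes + sum of edge costs.
    With degree_penalty = 0 there is no degree term.
    """
    beta = params.edge_reliability
    excluded = sum(p for n, p in prizes.items() if n not in included_nodes)
    cost = sum(edge_cost(graph.edges[u, v]["confidence"]) for u, v in tree_edges)
    if params.degree_penalty:
        cost += params.degree_penalty * sum(
            graph.degree(n) for n in included_nodes
        )
    return beta * excluded + cost


def exhaustive_optimum(
    graph: nx.Graph,
    prizes: dict[str, float],
    source: str,
    params: PCSFParams,
    max_nodes: int = 12,
) -> tuple[float, set[str], list[tuple[str, str]]]:
    """Brute-force optimum for small instances.

    Enumerates every node subset containing the source whose induced
    subgraph is connected; the cheapest edge set spanning a fixed subset is
    its minimum spanning tree on edge costs.
    """
    nodes = sorted(graph.nodes)
    if len(nodes) > max_nodes:
        raise ConfigError(f"exhaustive solver limited to {max_nodes} nodes")
    rest = [n for n in nodes if n != source]
    best = (np.inf, {source}, [])
    for r in range(len(rest) + 1):
        for combo in itertools.combinations(rest, r):
            subset = {source, *combo}
            sub = graph.subgraph(subset)
            if not nx.is_connected(sub):
                continue
            mst = nx.minimum_spanning_tree(
                nx.Graph(
                    (u, v, {"weight": edge_cost(d["confidence"]), **d})
                    for u, v, d in sub.edges(data=True)
                )
                if sub.number_of_edges()
                else sub
            )
            edges = list(mst.edges) if subset != {source} else []
            score = pcsf_objective(edges, subset, prizes, params, graph)
            if score < best[0] - 1e-12:
                best = (score, subset, edges)
    return best


def _greedy_tree(
    graph: nx.Graph,
    prizes: dict[str, float],
    source: str,
    params: PCSFParams,
) -> nx.Graph:
    """One greedy source-rooted construction with the given (jittered) prizes."""
    beta = params.edge_reliability
    tree = nx.Graph()
    tree.add_node(source)
    targets = {n for n, p in prizes.items() if p > 0 and n != source}

    cost_attr = {
        (u, v): edge_cost(d["confidence"]) for u, v, d in graph.edges(data=True)
    }

    def w(u, v, d):
        return edge_cost(d["confidence"])

    while targets & (set(graph.nodes) - set(tree.nodes)):
        dist, paths = nx.multi_source_dijkstra(graph, set(tree.nodes), weight=w)
        best_gain, best_node = 0.0, None
        for t in sorted(targets - set(tree.nodes)):
            if t not in dist:
                continue
            gain = beta * prizes[t] - dist[t]
            if gain > best_gain + 1e-12:
                best_gain, best_node = gain, t
        if best_node is None:
            break
        path = paths[best_node]
        for a, b in zip(path, path[1:]):
            tree.add_edge(a, b)
        # free prizes picked up along the way count as reached
    # prune leaf branches whose edge cost exceeds the prize they collect
    changed = True
    while changed:
        changed = False
        for leaf in [n for n in tree.nodes if tree.degree(n) == 1 and n != source]:
            (nbr,) = tree.neighbors(leaf)
            c = cost_attr.get((leaf, nbr), cost_attr.get((nbr, leaf)))
            if beta * prizes.get(leaf, 0.0) < c:
                tree.remove_node(leaf)
                changed = True
    return tree


def extract_subnetwork(
    net: Interactome,
    prizes: dict[str, float],
    source: str,
    params: PCSFParams | None = None,
    seed: int = 0,
) -> SubNetwork:
    """Randomized-greedy prize-collecting extraction.

    Runs n_randomizations greedy constructions with multiplicative prize
    jitter, keeps edges appearing in >= inclusion_frequency of runs, and
    prunes the union to the source-connected component. Deterministic for a
    fixed seed.
    """
    params = params or PCSFParams()
    graph = projected_graph(net)
    if source not in graph:
        raise DataError(f"source {source} not in interactome")
    positive = {n for n, p in prizes.items() if p > 0}
    if not positive:
        empty = nx.Graph()
        empty.add_node(source)
        return SubNetwork(empty, source)
    unreachable = {
        n for n in positive
        if n not in graph or not nx.has_path(graph, source, n)
    }
    if unreachable == positive:
        raise DataError(
            f"no prized protein reachable from source: {sorted(unreachable)}"
        )

    rng = np.random.default_rng(seed)
    counts: dict[tuple[str, str], int] = {}
    for _ in range(params.n_randomizations):
        jitter = {
            n: p * (1 + rng.uniform(-params.noise_scale, params.noise_scale))
            for n, p in prizes.items()
        }
        tree = _greedy_tree(graph, jitter, source, params)
        for e in tree.edges:
            counts[tuple(sorted(e))] = counts.get(tuple(sorted(e)), 0) + 1

    keep = [
        e for e, c in counts.items()
        if c >= params.inclusion_frequency * params.n_randomizations
    ]
    sub = nx.Graph()
    sub.add_node(source)
    for u, v in keep:
        sub.add_edge(u, v, confidence=graph.edges[u, v]["confidence"])
    if sub.number_of_edges():
        comp = nx.node_connected_component(sub, source)
        sub = nx.Graph(sub.subgraph(comp))
    return SubNetwork(sub, source)
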