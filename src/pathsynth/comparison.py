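"""Comparing a summary network against a functional kinase network.

The summary network mixes kinases and substrates; the functional
(screen-derived) network contains only kinase-kinase edges, so the
comparison first restricts the summary network to its kinase-kinase
subnetwork. Percentages follow asymmetric denominators: node overlap is
reported relative to the functional model's kinase set, edge overlap
relative to the summary network's kinase-kinase edge set.
"""

from __future__ import annotations

import networkx as nx

from .containers import KinaseNetwork, SummaryNetwork


def kinase_subnetwork(net: SummaryNetwork, kinases: set[str]) -> KinaseNetwork:
    """Edges of ``net`` with both endpoints in ``kinases``, direction kept.

    The node set is exactly the endpoints of surviving edges. Idempotent.
    """
    g = nx.DiGraph()
    for u, v, d in net.graph.edges(data=True):
        if u in kinases and v in kinases:
            g.add_edge(u, v, **d)
    for n in g.nodes:
        g.nodes[n]["is_kinase"] = True
    return KinaseNetwork(g)


def kinase_network_from_edges(
    edges: list[tuple[str, str]] | list[tuple[str, str, str]],
) -> KinaseNetwork:
    """Build a functional kinase network from (u, v[, functionality]) rows."""
    g = nx.DiGraph()
    for row in edges:
        u, v = row[0], row[1]
        label = row[2] if len(row) > 2 else "none"
        g.add_edge(u, v, functionality=label)
    for n in g.nodes:
        g.nodes[n]["is_kinase"] = True
    return KinaseNetwork(g)


def overlap_stats(a: KinaseNetwork, b: KinaseNetwork) -> dict:
    """Node and directed-edge overlap between two kinase networks.

    node_overlap_pct_of_b = |nodes(a) ∩ nodes(b)| / |nodes(b)|;
    edge_overlap_pct_of_a = |edges(a) ∩ edges(b)| / |edges(a)|, with edges
    identified by their ordered (u, v) pair, labels and signs ignored.
    Percentages are rounded to one decimal; an empty denominator yields
    None, never 0.
    """
    node_overlap = a.nodes() & b.nodes()
    edge_overlap = a.edges() & b.edges()
    n_b = len(b.nodes())
    n_ea = len(a.edges())
    return {
        "node_overlap_count": len(node_overlap),
        "node_overlap_pct_of_b": (
            round(100.0 * len(node_overlap) / n_b, 1) if n_b else None
        ),
        "edge_overlap_count": len(edge_overlap),
        "edge_overlap_pct_of_a": (
            round(100.0 * len(edge_overlap) / n_ea, 1) if n_ea else None
        ),
        "n_nodes_a": len(a.nodes()),
        "n_nodes_b": n_b,
        "n_edges_a": n_ea,
        "n_edges_b": len(b.edges()),
    }
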