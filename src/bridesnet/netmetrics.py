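"""Node-based connectivity metrics and node-removal statistics.

Centralities (degree, betweenness, eigenvector, clustering) and the average
path length are computed on the unweighted topology: on a sparse
population graph these hop-count versions are the ones that discriminate
stepping-stone nodes, and edge weights are genetic distances whose scale
would otherwise dominate. Weighted variants are available via ``weighted=True``
where meaningful. Strength and the average inverse edge weight (AIEW, a
proxy for migrant numbers) use the weights by definition.
"""

from __future__ import annotations

import math
import warnings

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "node_centralities",
    "edge_weight_stats",
    "average_path_length",
    "node_removal_impact",
    "articulation_nodes",
    "metrics_table",
]


def node_centralities(
    graph: nx.Graph, *, weighted: bool = False, cc_undefined_as_zero: bool = True
) -> pd.DataFrame:
    """Degree (DC), betweenness (BC), eigenvector (EC) and clustering (CC).

    BC is unnormalized with fractional counting over co-shortest paths.
    EC is the principal adjacency eigenvector rescaled so its maximum entry
    is 1. CC for nodes of degree < 2 is reported as 0 by default (set
    ``cc_undefined_as_zero=False`` for NaN).
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if not nx.is_connected(graph) and graph.number_of_nodes() > 1:
        warnings.warn("graph is disconnected; BC computed per component")
    wkey = "weight" if weighted else None
    # distance for shortest paths = inverse weight? No: genetic distance is
    # already a cost, so the weight itself is the path cost.
    bc = nx.betweenness_centrality(graph, normalized=False, weight=wkey)
    try:
        ec = nx.eigenvector_centrality_numpy(graph, weight=wkey)
    except (nx.NetworkXException, TypeError):
        ec = {n: float("nan") for n in graph.nodes}
    emax = max(abs(v) for v in ec.values()) or 1.0
    cc = nx.clustering(graph, weight=wkey)
    rows = []
    for n in graph.nodes:
        c = cc[n]
        if graph.degree(n) < 2 and not cc_undefined_as_zero:
            c = float("nan")
        rows.append((n, graph.degree(n), bc[n], abs(ec[n]) / emax, c))
    return pd.DataFrame(rows, columns=["node", "DC", "BC", "EC", "CC"]).set_index(
        "node"
    )


def edge_weight_stats(graph: nx.Graph) -> pd.DataFrame:
    """Per-node strength (sum of incident weights) and AIEW (mean of 1/w).

    Isolated nodes get strength 0 and AIEW NaN.
    """
    rows = []
    for n in graph.nodes:
        ws = [d["weight"] for _, _, d in graph.edges(n, data=True)]
        if any(w <= 0 for w in ws):
            raise ValueError(f"non-positive edge weight at node {n!r}")
        strength = float(sum(ws))
        aiew = float(np.mean([1.0 / w for w in ws])) if ws else float("nan")
        rows.append((n, strength, aiew))
    return pd.DataFrame(rows, columns=["node", "strength", "AIEW"]).set_index(
        "node"
    )


def average_path_length(
    graph: nx.Graph,
    *,
    weighted: bool = False,
    disconnected: str = "reachable",
) -> float:
    """Mean shortest-path length over unordered node pairs (hop counts).

    ``disconnected="reachable"`` (default) averages over reachable pairs and
    warns; ``"inf"`` returns infinity for a disconnected graph. NaN when no
    pair is reachable.
    """
    n = graph.number_of_nodes()
    if n < 2:
        return float("nan")
    wkey = "weight" if weighted else None
    total, pairs = 0.0, 0
    for u, lengths in nx.all_pairs_dijkstra_path_length(graph, weight=wkey):
        for v, d in lengths.items():
            if u != v:
                total += d
                pairs += 1
    pairs //= 2
    total /= 2.0
    all_pairs = n * (n - 1) // 2
    if pairs < all_pairs:
        if disconnected == "inf":
            return math.inf
        warnings.warn("graph disconnected; APL averaged over reachable pairs")
    return total / pairs if pairs else float("nan")


def node_removal_impact(
    graph: nx.Graph, *, weighted: bool = False
) -> pd.DataFrame:
    """APL of the graph after deleting each node in turn.

    Columns: ``APL_removed`` (NaN when no pair remains reachable),
    ``delta`` vs. the intact graph's APL, and ``disconnects`` flagging nodes
    whose removal increases the number of connected components.
    """
    if graph.number_of_nodes() < 3:
        raise ValueError("need at least 3 nodes to assess removals")
    base_apl = average_path_length(graph, weighted=weighted)
    base_comp = nx.number_connected_components(graph)
    rows = []
    for n in graph.nodes:
        rest = graph.copy()
        rest.remove_node(n)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            apl = average_path_length(rest, weighted=weighted)
        disconnects = nx.number_connected_components(rest) > base_comp
        rows.append((n, apl, apl - base_apl, disconnects))
    return pd.DataFrame(
        rows, columns=["node", "APL_removed", "delta", "disconnects"]
    ).set_index("node")


def articulation_nodes(graph: nx.Graph) -> set:
    """Cut nodes: nodes whose deletion disconnects (a component of) the graph."""
    return set(nx.articulation_points(graph))


def metrics_table(graph: nx.Graph, *, weighted: bool = False) -> pd.DataFrame:
    """One row per node with the full metric panel.

    Column order mirrors the conventional report: BC, DC, EC, strength,
    AIEW, CC, APL after removing the node, and a cut-node flag.
    """
    cent = node_centralities(graph, weighted=weighted)
    ew = edge_weight_stats(graph)
    removal = node_removal_impact(graph, weighted=weighted)
    cut = articulation_nodes(graph)
    df = cent.join(ew).join(removal)
    df["is_cut_node"] = [n in cut for n in df.index]
    return df[
        ["BC", "DC", "EC", "strength", "AIEW", "CC", "APL_removed", "delta", "is_cut_node"]
    ]
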