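"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: simple-path enumeration by DFS,
Dijkstra on an explicit (node, visited-required-set?) product graph, and
delete-and-count connectivity checks. None of it shares code with the
library paths it validates.
"""

from __future__ import annotations

import heapq
import itertools
import math

import networkx as nx


def enumerate_simple_paths(graph: nx.Graph, u, v):
    """All simple paths u → v by explicit DFS."""
    stack = [(u, [u])]
    while stack:
        node, path = stack.pop()
        if node == v:
            yield path
            continue
        for nbr in graph.neighbors(node):
            if nbr not in path:
                stack.append((nbr, path + [nbr]))


def path_cost(graph: nx.Graph, path, weighted: bool) -> float:
    if weighted:
        return sum(graph[a][b]["weight"] for a, b in zip(path, path[1:]))
    return len(path) - 1


def brute_shortest(graph: nx.Graph, u, v, weighted: bool = False) -> float:
    """Min cost over all enumerated simple paths; inf when none."""
    if u == v:
        return 0.0
    costs = [path_cost(graph, p, weighted) for p in enumerate_simple_paths(graph, u, v)]
    return min(costs) if costs else math.inf


def brute_betweenness(graph: nx.Graph) -> dict:
    """Unnormalized betweenness with fractional co-shortest-path counting,
    from explicit enumeration of all shortest paths per pair."""
    bc = {n: 0.0 for n in graph.nodes}
    nodes = list(graph.nodes)
    for s, t in itertools.combinations(nodes, 2):
        paths = list(enumerate_simple_paths(graph, s, t))
        if not paths:
            continue
        costs = [path_cost(graph, p, weighted=False) for p in paths]
        best = min(costs)
        shortest = [p for p, c in zip(paths, costs) if c == best]
        for p in shortest:
            for inner in p[1:-1]:
                bc[inner] += 1.0 / len(shortest)
    return bc


def product_dijkstra_constrained(
    graph: nx.Graph, u, v, required, weighted: bool = False
) -> float:
    """Shortest walk u → v touching the required set, via Dijkstra on the
    state space (node, touched-required-yet)."""
    req = {k for k in required if k not in (u, v)}
    if not req:
        return math.inf
    start = (u, u in req)
    dist = {start: 0.0}
    heap = [(0.0, u, u in req)]
    while heap:
        d, node, flag = heapq.heappop(heap)
        if d > dist.get((node, flag), math.inf):
            continue
        if node == v and flag:
            return d
        for nbr in graph.neighbors(node):
            w = graph[node][nbr]["weight"] if weighted else 1.0
            nflag = flag or (nbr in req)
            nd = d + w
            if nd < dist.get((nbr, nflag), math.inf):
                dist[(nbr, nflag)] = nd
                heapq.heappush(heap, (nd, nbr, nflag))
    return math.inf


def brute_articulation(graph: nx.Graph) -> set:
    """Cut nodes by delete-and-count-components."""
    base = nx.number_connected_components(graph)
    out = set()
    for n in graph.nodes:
        g = graph.copy()
        g.remove_node(n)
        if g.number_of_nodes() and nx.number_connected_components(g) > base:
            out.add(n)
    return out


def brute_apl(graph: nx.Graph) -> float:
    """Reachable-pairs mean hop count by per-pair enumeration."""
    total, pairs = 0.0, 0
    for u, v in itertools.combinations(graph.nodes, 2):
        d = brute_shortest(graph, u, v)
        if math.isfinite(d):
            total += d
            pairs += 1
    return total / pairs if pairs else math.nan


def exhaustive_min_solution(base, full_graph, model, mode, score_fn):
    """Smallest subset of candidates achieving the all-candidates score.

    Returns (minimal size, all optimal subsets of that size); (None, [])
    when the maximum score is not positive.
    """
    candidates = [n for n in full_graph.nodes if n not in set(base)]
    max_raw = score_fn(base, frozenset(candidates), full_graph, model, mode)
    if max_raw <= 0:
        return None, []
    for size in range(1, len(candidates) + 1):
        hits = [
            frozenset(sub)
            for sub in itertools.combinations(candidates, size)
            if score_fn(base, frozenset(sub), full_graph, model, mode)
            >= max_raw * (1 - 1e-9)
        ]
        if hits:
            return size, hits
    return len(candidates), [frozenset(candidates)]
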