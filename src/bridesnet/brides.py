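"""Six-type shortest-path classification for evolving graphs (BRIDES).

Given a subgraph X_n induced on a subset of nodes of a larger graph X_all,
every unordered pair of subgraph nodes is classified by comparing (i) the
shortest path between them inside X_n with (ii) the shortest path between
them in X_all *constrained to pass through at least one candidate node*
(a node of X_all absent from X_n):

=============  =====================================================
Breakthrough   impossible in X_n, possible through a candidate
Roadblock      possible in X_n, impossible through any candidate
Impasse        impossible in both
Detour         shorter in X_n than through candidates
Equal          same length
Shortcut       longer in X_n — a candidate provides a better route
=============  =====================================================

The counts are collected in a vector (B, R, I, D, E, S) and scored with a
user-supplied vector of six signed weights.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

__all__ = [
    "PATH_TYPES",
    "BridesVector",
    "WeightModel",
    "path_length",
    "constrained_path_length",
    "classify_pairs",
    "brides_score",
    "parse_weight_model",
]

PATH_TYPES = ("B", "R", "I", "D", "E", "S")

#: Relative tolerance for calling two weighted path lengths equal.
EQUAL_RTOL = 1e-9


@dataclass
class BridesVector:
    """Counts of the six path types plus the per-pair detail table."""

    B: int = 0
    R: int = 0
    I: int = 0
    D: int = 0
    E: int = 0
    S: int = 0
    detail: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)

    def as_tuple(self) -> tuple[int, int, int, int, int, int]:
        return (self.B, self.R, self.I, self.D, self.E, self.S)

    @property
    def total(self) -> int:
        return sum(self.as_tuple())


@dataclass(frozen=True)
class WeightModel:
    """Six signed weights (w_B, w_R, w_I, w_D, w_E, w_S) scoring a vector."""

    weights: tuple[float, float, float, float, float, float]

    def __post_init__(self) -> None:
        if len(self.weights) != 6:
            raise ValueError("exactly six weights required")
        if all(w == 0 for w in self.weights):
            raise ValueError("at least one nonzero weight required")

    @property
    def complexity(self) -> int:
        """Number of nonzero weights."""
        return sum(1 for w in self.weights if w != 0)

    @property
    def label(self) -> str:
        """Field notation: superscript digits for positive weights, e.g.
        ``B^3^S^1^``; negative weights shown with a leading minus as
        subscripts, e.g. ``R_1_``."""
        parts = []
        for letter, w in zip(PATH_TYPES, self.weights):
            if w > 0:
                parts.append(f"{letter}^{w:g}^")
            elif w < 0:
                parts.append(f"{letter}_{-w:g}_")
        return "".join(parts)


def parse_weight_model(text: str) -> WeightModel:
    """Parse ``"B3D1E2S3"``-style notation or a 6-tuple literal.

    Letters absent from the string get weight 0; negative weights are
    written inline (``"B1R-1D-1S1"``). A comma-separated literal such as
    ``"(1, -1, 0, -1, 0, 1)"`` is also accepted.
    """
    text = text.strip()
    if "," in text:
        nums = [t for t in re.split(r"[(),\s]+", text) if t]
        if len(nums) != 6:
            raise ValueError(f"expected 6 weights, got {len(nums)}: {text!r}")
        return WeightModel(tuple(float(x) for x in nums))
    tokens = re.findall(r"([A-Za-z])(-?\d+(?:\.\d+)?)", text)
    if not tokens or "".join(l + n for l, n in tokens) != text:
        raise ValueError(f"cannot parse weight model {text!r}")
    weights = dict.fromkeys(PATH_TYPES, 0.0)
    for letter, num in tokens:
        letter = letter.upper()
        if letter not in weights:
            raise ValueError(
                f"unknown path type {letter!r}; expected one of {PATH_TYPES}"
            )
        if weights[letter] != 0.0:
            raise ValueError(f"path type {letter!r} given twice in {text!r}")
        weights[letter] = float(num)
    return WeightModel(tuple(weights[t] for t in PATH_TYPES))


def _wkey(mode: str) -> str | None:
    if mode == "hops":
        return None
    if mode == "weighted":
        return "weight"
    raise ValueError(f"mode must be 'hops' or 'weighted', got {mode!r}")


def path_length(graph: nx.Graph, u, v, mode: str = "hops") -> float:
    """Shortest-path length between two nodes; ``inf`` when unreachable."""
    for n in (u, v):
        if n not in graph:
            raise KeyError(f"node {n!r} not in graph")
    try:
        return float(nx.shortest_path_length(graph, u, v, weight=_wkey(mode)))
    except nx.NetworkXNoPath:
        return math.inf


def constrained_path_length(
    graph: nx.Graph, u, v, required, mode: str = "hops"
) -> float:
    """Shortest length of a route from u to v via at least one required node.

    Computed as ``min over k of d(u,k) + d(k,v)``: with non-negative
    lengths this is the exact optimum over walks touching the required set
    (the realized route may revisit nodes). ``inf`` when the required set is
    empty or no member is reachable from both endpoints.
    """
    for n in (u, v):
        if n not in graph:
            raise KeyError(f"node {n!r} not in graph")
    required = [k for k in required if k != u and k != v]
    if not required:
        return math.inf
    wkey = _wkey(mode)
    du = nx.single_source_dijkstra_path_length(graph, u, weight=wkey)
    dv = nx.single_source_dijkstra_path_length(graph, v, weight=wkey)
    best = math.inf
    for k in required:
        if k in du and k in dv:
            best = min(best, du[k] + dv[k])
    return best


def _lengths_equal(a: float, b: float, mode: str) -> bool:
    if mode == "hops":
        return a == b
    return abs(a - b) <= EQUAL_RTOL * max(abs(a), abs(b))


def classify_pairs(
    subgraph_nodes, full_graph: nx.Graph, mode: str = "hops"
) -> BridesVector:
    """Classify every unordered pair of subgraph nodes into B/R/I/D/E/S.

    ``subgraph_nodes`` must be a subset of the full graph's nodes; X_n is
    the subgraph of ``full_graph`` induced on them, and the candidate set is
    the complement. Counts satisfy B+R+I+D+E+S = C(n, 2).
    """
    sub_nodes = list(dict.fromkeys(subgraph_nodes))
    extra = [n for n in sub_nodes if n not in full_graph]
    if extra:
        raise ValueError(f"nodes not in the full graph: {extra}")
    candidates = [n for n in full_graph.nodes if n not in set(sub_nodes)]
    xn = full_graph.subgraph(sub_nodes)
    wkey = _wkey(mode)

    # single-source sweeps instead of per-pair searches
    d_sub = {
        u: nx.single_source_dijkstra_path_length(xn, u, weight=wkey)
        for u in sub_nodes
    }
    d_full = {
        u: nx.single_source_dijkstra_path_length(full_graph, u, weight=wkey)
        for u in sub_nodes
    }

    vec = BridesVector()
    records = []
    for i, u in enumerate(sub_nodes):
        for v in sub_nodes[i + 1 :]:
            dn = float(d_sub[u].get(v, math.inf))
            du, dv = d_full[u], d_full[v]
            dc = math.inf
            for k in candidates:
                if k in du and k in dv:
                    dc = min(dc, du[k] + dv[k])
            if math.isinf(dn) and math.isinf(dc):
                ptype = "I"
            elif math.isinf(dn):
                ptype = "B"
            elif math.isinf(dc):
                ptype = "R"
            elif _lengths_equal(dn, dc, mode):
                ptype = "E"
            elif dn < dc:
                ptype = "D"
            else:
                ptype = "S"
            setattr(vec, ptype, getattr(vec, ptype) + 1)
            records.append((u, v, dn, dc, ptype))
    vec.detail = pd.DataFrame(
        records, columns=["u", "v", "d_subgraph", "d_constrained", "type"]
    )
    return vec


def brides_score(vector: BridesVector, model: WeightModel) -> float:
    """Weighted sum of the six path-type counts."""
    return float(
        sum(w * c for w, c in zip(model.weights, vector.as_tuple()))
    )
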