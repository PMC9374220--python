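"""Stepwise BRIDES node selection under conservation scenarios.

A scenario picks the starting subgraph X_n from per-population attributes
(heterozygosity, census size, or element-occurrence rank), either
*proactively* (keep the least vulnerable populations as a reservoir) or
*reactively* (keep the most vulnerable, needing immediate action). The
selection algorithm then adds candidate nodes one at a time, keeping at
every step all additions that tie for the best normalized BRIDES score,
until some branch attains the maximal score (normalized to 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd
from scipy import stats

from .brides import (
    WeightModel,
    brides_score,
    classify_pairs,
    parse_weight_model,
)
from .genio import EO_RANKS, PopulationAttributes

__all__ = [
    "EO_ORDER",
    "Scenario",
    "SelectionResult",
    "standard_scenarios",
    "standard_models",
    "build_scenario_subgraph",
    "normalized_score",
    "stepwise_select",
    "selection_frequency",
    "model_complexity",
    "complexity_node_correlation",
]

#: Ordinal value of each element-occurrence rank; larger = better viability.
EO_ORDER = {rank: len(EO_RANKS) - 1 - i for i, rank in enumerate(EO_RANKS)}

#: Normalized score within this distance of 1 counts as maximal.
SCORE_TOL = 1e-9


@dataclass(frozen=True)
class Scenario:
    """Subgraph-construction rule.

    ``criterion`` is one of ``heterozygosity`` (threshold on H_E),
    ``pop_size`` (threshold on estimated census size) or ``eo_rank``
    (threshold pair of EO tokens). ``direction`` is ``proactive`` (keep
    populations strictly better than the threshold) or ``reactive`` (keep
    strictly worse); boundary-equal populations fall in neither subgraph and
    stay available as candidates.
    """

    criterion: str
    direction: str
    threshold: float | tuple[str, str]
    name: str = ""

    def __post_init__(self) -> None:
        if self.criterion not in ("heterozygosity", "pop_size", "eo_rank"):
            raise ValueError(f"unknown criterion {self.criterion!r}")
        if self.direction not in ("proactive", "reactive"):
            raise ValueError(f"unknown direction {self.direction!r}")


def standard_scenarios(
    *, he_threshold: float = 0.72, size_threshold: float = 75,
    eo_thresholds: tuple[str, str] = ("BC", "B"),
) -> list[Scenario]:
    """The six proactive/reactive scenarios over H_E, size and EO rank.

    Defaults: H_E split at 0.72, census size at 75 individuals, EO
    proactive = rank strictly better than BC, reactive = strictly worse
    than B.
    """
    return [
        Scenario("heterozygosity", "proactive", he_threshold, "A_P"),
        Scenario("heterozygosity", "reactive", he_threshold, "A_R"),
        Scenario("pop_size", "proactive", size_threshold, "B_P"),
        Scenario("pop_size", "reactive", size_threshold, "B_R"),
        Scenario("eo_rank", "proactive", eo_thresholds, "C_P"),
        Scenario("eo_rank", "reactive", eo_thresholds, "C_R"),
    ]


def standard_models() -> list[WeightModel]:
    """The five weighting schemes, simplest (shortcuts only) to richest."""
    return [
        parse_weight_model(m)
        for m in ("S1", "B3S1", "B1S3", "B1R-1D-1S1", "B3D1E2S3")
    ]


def build_scenario_subgraph(
    graph: nx.Graph,
    attributes: Iterable[PopulationAttributes],
    scenario: Scenario,
) -> set:
    """Node set of the scenario subgraph (strict-inequality selection)."""
    by_id = {a.id: a for a in attributes}
    missing = [n for n in graph.nodes if n not in by_id]
    if missing:
        raise ValueError(f"no attributes for node(s): {missing}")
    chosen = set()
    for n in graph.nodes:
        a = by_id[n]
        if scenario.criterion == "heterozygosity":
            value, cut = a.he, float(scenario.threshold)
        elif scenario.criterion == "pop_size":
            value, cut = a.psize, float(scenario.threshold)
        else:
            pro_cut, rea_cut = scenario.threshold
            value = EO_ORDER[a.eo]
            cut = EO_ORDER[pro_cut if scenario.direction == "proactive" else rea_cut]
        if scenario.direction == "proactive" and value > cut:
            chosen.add(n)
        elif scenario.direction == "reactive" and value < cut:
            chosen.add(n)
    return chosen


def _raw_score(
    base: Sequence, added: frozenset, full_graph: nx.Graph,
    model: WeightModel, mode: str,
) -> float:
    nodes = list(base) + [n for n in full_graph.nodes if n in added]
    world = full_graph.subgraph(nodes)
    return brides_score(classify_pairs(base, world, mode), model)


def normalized_score(
    subgraph_nodes,
    added,
    full_graph: nx.Graph,
    model: WeightModel,
    mode: str = "hops",
) -> float:
    """Score of a partial addition, scaled by the all-candidates maximum.

    The raw score classifies the base pairs against the graph induced on
    base ∪ added (the added nodes are the required-passage candidates).
    When the maximum is not positive, normalization is undefined and the
    raw score is returned unscaled.
    """
    base = list(dict.fromkeys(subgraph_nodes))
    candidates = frozenset(n for n in full_graph.nodes if n not in set(base))
    added = frozenset(added)
    if not added <= candidates:
        raise ValueError("added nodes must be candidates (outside the subgraph)")
    max_raw = _raw_score(base, candidates, full_graph, model, mode)
    raw = _raw_score(base, added, full_graph, model, mode)
    if max_raw <= 0:
        return raw
    return raw / max_raw


@dataclass
class SelectionResult:
    """Trace of one stepwise selection run."""

    scenario: Scenario | None
    model: WeightModel
    steps: list[dict] = field(default_factory=list)
    solutions: list[frozenset] = field(default_factory=list)
    min_nodes: int | None = None
    max_raw: float = 0.0
    no_solution: bool = False

    @property
    def n_solutions(self) -> int:
        return len(self.solutions)

    def selected_nodes(self) -> set:
        """Union of nodes appearing in at least one optimal solution."""
        out: set = set()
        for s in self.solutions:
            out |= s
        return out


def stepwise_select(
    subgraph_nodes,
    full_graph: nx.Graph,
    model: WeightModel,
    mode: str = "hops",
    scenario: Scenario | None = None,
    max_frontier: int = 10000,
) -> SelectionResult:
    """Greedy breadth-first selection with full tie branching.

    At each depth every frontier set is extended by every remaining
    candidate; all extensions tying for the depth's best raw score survive
    (deduplicated as sets). The first depth at which some branch reaches the
    maximal score (normalized 1) is reported as the minimal node count, with
    every distinct terminating set as a co-optimal solution. When even the
    full candidate set cannot achieve a positive score, the run is flagged
    ``no_solution`` (no node is worth adding).
    """
    base = list(dict.fromkeys(subgraph_nodes))
    candidates = frozenset(n for n in full_graph.nodes if n not in set(base))
    if not candidates:
        raise ValueError("no candidate nodes to select from")
    result = SelectionResult(scenario=scenario, model=model)
    max_raw = _raw_score(base, candidates, full_graph, model, mode)
    result.max_raw = max_raw
    if max_raw <= 0:
        result.no_solution = True
        return result

    frontier: set[frozenset] = {frozenset()}
    score_cache: dict[frozenset, float] = {}

    def raw(aset: frozenset) -> float:
        if aset not in score_cache:
            score_cache[aset] = _raw_score(base, aset, full_graph, model, mode)
        return score_cache[aset]

    for depth in range(1, len(candidates) + 1):
        extensions: set[frozenset] = {
            a | {c} for a in frontier for c in candidates - a
        }
        best = max(raw(a) for a in extensions)
        keep = {a for a in extensions if raw(a) >= best - SCORE_TOL * max(1.0, abs(best))}
        result.steps.append(
            {
                "depth": depth,
                "raw_score": best,
                "normalized_score": best / max_raw,
                "n_tied_sets": len(keep),
                "sets": sorted(tuple(sorted(map(str, s))) for s in keep),
            }
        )
        if best >= max_raw * (1.0 - SCORE_TOL):
            result.solutions = sorted(keep, key=lambda s: tuple(sorted(map(str, s))))
            result.min_nodes = depth
            return result
        if len(keep) > max_frontier:
            keep = set(sorted(keep, key=lambda s: tuple(sorted(map(str, s))))[:max_frontier])
        frontier = keep
    # full candidate set always achieves max_raw, so we cannot get here
    raise AssertionError("greedy frontier failed to terminate")


def selection_frequency(
    graph: nx.Graph,
    attributes: Iterable[PopulationAttributes],
    scenarios: Sequence[Scenario],
    models: Sequence[WeightModel],
    mode: str = "hops",
) -> pd.DataFrame:
    """Per-node selection frequency over all scenario × model runs.

    A node counts toward the denominator whenever it is a candidate (not in
    the scenario subgraph), and toward the numerator when it belongs to at
    least one optimal solution of that run; no-solution runs contribute to
    the denominator only. Nodes never in a candidate role get NaN.
    """
    attributes = list(attributes)
    cand_runs = {n: 0 for n in graph.nodes}
    sel_runs = {n: 0 for n in graph.nodes}
    runs = []
    for scenario in scenarios:
        base = build_scenario_subgraph(graph, attributes, scenario)
        candidates = set(graph.nodes) - base
        if not candidates or len(base) < 2:
            continue
        for model in models:
            res = stepwise_select(base, graph, model, mode, scenario=scenario)
            chosen = res.selected_nodes()
            for n in candidates:
                cand_runs[n] += 1
                if n in chosen:
                    sel_runs[n] += 1
            runs.append(res)
    rows = []
    for n in graph.nodes:
        freq = sel_runs[n] / cand_runs[n] if cand_runs[n] else float("nan")
        rows.append((n, cand_runs[n], sel_runs[n], freq))
    df = pd.DataFrame(
        rows, columns=["node", "candidate_runs", "selected_runs", "frequency"]
    ).set_index("node")
    df.attrs["runs"] = runs
    df.attrs["definition"] = (
        "frequency = runs where the node is in >=1 optimal solution / "
        "runs where the node was a candidate"
    )
    return df


def model_complexity(model: WeightModel) -> int:
    """Number of nonzero weights in the model."""
    return model.complexity


def complexity_node_correlation(
    pairs: Iterable[tuple[float, float]],
) -> tuple[float, float]:
    """Kendall tau-b (and normal-approximation p) between model complexity
    and minimal selected-node counts; pairs with a missing count are
    excluded by the caller."""
    pairs = [(x, y) for x, y in pairs]
    if len(pairs) < 2:
        raise ValueError("need at least two pairs")
    xs, ys = zip(*pairs)
    if len(set(xs)) < 2 or len(set(ys)) < 2:
        raise ValueError("Kendall tau undefined when either variable is constant")
    res = stats.kendalltau(xs, ys)
    return float(res.statistic), float(res.pvalue)
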