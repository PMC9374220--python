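import itertools
import math

import networkx as nx
import pytest

from bridesnet.datasets import (
    MODEL_COMPLEXITIES,
    MODEL_LABELS,
    selection_node_counts,
    wood_turtle_attributes,
)
from bridesnet.brides import parse_weight_model
from bridesnet.selection import (
    EO_ORDER,
    Scenario,
    _raw_score,
    build_scenario_subgraph,
    complexity_node_correlation,
    model_complexity,
    normalized_score,
    selection_frequency,
    standard_models,
    standard_scenarios,
    stepwise_select,
)
from bridesnet.synth import random_weighted_graph
from oracles import exhaustive_min_solution


def attr_graph():
    """Graph whose node set is the 19 published populations."""
    g = nx.Graph()
    g.add_nodes_from(a.id for a in wood_turtle_attributes())
    return g


class TestScenarios:
    def test_eo_order_is_strictly_decreasing_in_viability(self):
        assert EO_ORDER["A"] > EO_ORDER["AB"] > EO_ORDER["B"] > EO_ORDER["BC"]
        assert EO_ORDER["BC"] > EO_ORDER["C"] > EO_ORDER["CD"] > EO_ORDER["D"]

    def test_published_attribute_subgraph_sizes(self):
        g = attr_graph()
        attrs = wood_turtle_attributes()
        sizes = {
            s.name: len(build_scenario_subgraph(g, attrs, s))
            for s in standard_scenarios()
        }
        assert sizes == {
            "A_P": 9, "A_R": 9, "B_P": 8, "B_R": 10, "C_P": 13, "C_R": 6,
        }

    def test_eo_scenarios_match_hand_selection(self):
        g = attr_graph()
        attrs = wood_turtle_attributes()
        scen = {s.name: s for s in standard_scenarios()}
        pro = build_scenario_subgraph(g, attrs, scen["C_P"])
        rea = build_scenario_subgraph(g, attrs, scen["C_R"])
        assert pro == {
            "GA3", "GA5", "SM1", "DC1", "MA2", "MA3", "MI1", "SF1", "GA4",
            "LO1", "MD1", "BE1", "MI3",
        }
        assert rea == {"GA2", "LA1", "MA1", "MI2", "SF4", "SF3"}

    def test_boundary_values_excluded_from_both_sides(self):
        g = attr_graph()
        attrs = wood_turtle_attributes()
        scen = {s.name: s for s in standard_scenarios()}
        # GA2 has exactly 75 individuals; GA3 has H_E exactly 0.72
        bp = build_scenario_subgraph(g, attrs, scen["B_P"])
        br = build_scenario_subgraph(g, attrs, scen["B_R"])
        assert "GA2" not in bp and "GA2" not in br
        ap = build_scenario_subgraph(g, attrs, scen["A_P"])
        ar = build_scenario_subgraph(g, attrs, scen["A_R"])
        assert "GA3" not in ap and "GA3" not in ar

    def test_missing_attribute_names_the_node(self):
        g = attr_graph()
        g.add_node("XX9")
        with pytest.raises(ValueError, match="XX9"):
            build_scenario_subgraph(
                g, wood_turtle_attributes(), standard_scenarios()[0]
            )

    def test_scenario_validation(self):
        with pytest.raises(ValueError, match="criterion"):
            Scenario("karma", "proactive", 1.0)
        with pytest.raises(ValueError, match="direction"):
            Scenario("pop_size", "sideways", 1.0)


class TestNormalizedScore:
    def test_all_candidates_reach_one(self, toy, rng):
        fx = toy["selection11"]
        m = parse_weight_model("B1E1S1")
        assert normalized_score(
            fx["subgraph"], fx["candidates"], fx["graph"], m
        ) == pytest.approx(1.0)

    def test_empty_addition_with_no_possible_shortcut(self, toy):
        fx = toy["tri_iso"]  # no candidate can shorten triangle paths
        m = parse_weight_model("S1")
        # max score is 0 → raw (also 0) returned unscaled
        assert normalized_score(fx["subgraph"], set(), fx["graph"], m) == 0.0

    def test_best_single_candidate_in_selection_fixture(self, toy):
        fx = toy["selection11"]
        m = parse_weight_model("B1E1S1")
        scores = {
            c: normalized_score(fx["subgraph"], {c}, fx["graph"], m)
            for c in fx["candidates"]
        }
        assert max(scores, key=scores.get) == fx["best_candidate"]

    def test_non_candidate_addition_rejected(self, toy):
        fx = toy["selection11"]
        with pytest.raises(ValueError, match="candidates"):
            normalized_score(
                fx["subgraph"], {"1"}, fx["graph"], parse_weight_model("S1")
            )


class TestStepwiseSelect:
    def test_single_decisive_candidate(self):
        # k reconnects the two halves; adding it creates every breakthrough
        g = nx.Graph()
        g.add_weighted_edges_from(
            [("a", "b", 1), ("c", "d", 1), ("b", "k", 1), ("k", "c", 1)]
        )
        res = stepwise_select({"a", "b", "c", "d"}, g, parse_weight_model("B1"))
        assert not res.no_solution
        assert res.min_nodes == 1
        assert res.solutions == [frozenset({"k"})]

    def test_symmetric_candidates_are_co_optimal(self):
        # k1 and k2 are swapped by an automorphism → both tie at step 1
        g = nx.Graph()
        g.add_weighted_edges_from(
            [("u", "k1", 1), ("k1", "v", 1), ("u", "k2", 1), ("k2", "v", 1)]
        )
        res = stepwise_select({"u", "v"}, g, parse_weight_model("B1"))
        assert res.min_nodes == 1
        assert set(res.solutions) == {frozenset({"k1"}), frozenset({"k2"})}
        assert res.n_solutions == 2

    def test_no_solution_when_no_shortcut_possible(self, toy):
        fx = toy["tri_iso"]
        res = stepwise_select(fx["subgraph"], fx["graph"], parse_weight_model("S1"))
        assert res.no_solution
        assert res.min_nodes is None and res.solutions == []

    def test_relabeling_invariance(self, rng):
        g = random_weighted_graph(8, 0.45, seed=99, connected=True)
        base = list(g.nodes)[:5]
        m = parse_weight_model("B3D1E2S3")
        res = stepwise_select(base, g, m)
        mapping = {n: f"z{n}" for n in g.nodes}
        res2 = stepwise_select(
            [mapping[n] for n in base], nx.relabel_nodes(g, mapping), m
        )
        assert res.min_nodes == res2.min_nodes
        relabeled = {frozenset(mapping[n] for n in s) for s in res.solutions}
        assert relabeled == set(res2.solutions)

    def test_monotone_scores_for_nonnegative_models(self, rng):
        m = parse_weight_model("B3D1E2S3")
        for _ in range(30):
            g = random_weighted_graph(
                8, 0.35, seed=int(rng.integers(2**31))
            )
            base = list(g.nodes)[:5]
            res = stepwise_select(base, g, m)
            if res.no_solution:
                continue
            scores = [s["normalized_score"] for s in res.steps]
            assert all(b >= a - 1e-9 for a, b in zip(scores, scores[1:]))

    def test_greedy_solutions_reach_max_and_compare_to_exhaustive(self, rng):
        agree = 0
        runs = 0
        for _ in range(50):
            n = int(rng.integers(5, 10))
            g = random_weighted_graph(n, 0.4, seed=int(rng.integers(2**31)))
            nodes = list(g.nodes)
            base = nodes[: int(rng.integers(3, min(7, n)))]
            cands = [x for x in nodes if x not in base][:4]
            if not cands:
                continue
            world = g.subgraph(base + cands)
            m = parse_weight_model("B1E1S1")
            res = stepwise_select(base, world, m)
            exact_size, exact_sets = exhaustive_min_solution(
                base, world, m, "hops", _raw_score
            )
            if res.no_solution:
                assert exact_size is None
                continue
            runs += 1
            for sol in res.solutions:
                assert normalized_score(base, sol, world, m) == pytest.approx(1.0)
            # greedy can only overshoot the exact minimum
            assert res.min_nodes >= exact_size
            if res.min_nodes == exact_size:
                agree += 1
        assert runs > 0
        # the greedy heuristic should find the exact minimum most of the time
        assert agree >= 0.8 * runs


class TestSelectionFrequency:
    def test_toy_grid_matches_hand_enumeration(self):
        # world: path a-b-c-d plus candidates k (reconnects) and m (dangling)
        g = nx.Graph()
        g.add_weighted_edges_from(
            [("a", "b", 1), ("c", "d", 1), ("b", "k", 1), ("k", "c", 1),
             ("m", "a", 1)]
        )
        from bridesnet.genio import PopulationAttributes

        attrs = [
            PopulationAttributes("a", 5, 0.8, 100, "A"),
            PopulationAttributes("b", 5, 0.8, 100, "A"),
            PopulationAttributes("c", 5, 0.8, 100, "A"),
            PopulationAttributes("d", 5, 0.8, 100, "A"),
            PopulationAttributes("k", 5, 0.3, 10, "C"),
            PopulationAttributes("m", 5, 0.3, 10, "C"),
        ]
        scenarios = [Scenario("heterozygosity", "proactive", 0.5, "hi")]
        models = [parse_weight_model("B1"), parse_weight_model("B1E1S1")]
        df = selection_frequency(g, attrs, scenarios, models)
        # k reconnects a-b with c-d in both model runs; m never helps alone
        assert df.loc["k", "frequency"] == 1.0
        assert df.loc["k", "candidate_runs"] == 2
        assert math.isnan(df.loc["a", "frequency"])  # never a candidate

    def test_no_solution_runs_count_in_denominator(self, toy):
        from bridesnet.genio import PopulationAttributes

        fx = toy["tri_iso"]
        attrs = [
            PopulationAttributes(n, 5, 0.9 if n != "x" else 0.1, 10, "A")
            for n in fx["graph"].nodes
        ]
        df = selection_frequency(
            fx["graph"], attrs,
            [Scenario("heterozygosity", "proactive", 0.5, "hi")],
            [parse_weight_model("S1")],
        )
        assert df.loc["x", "candidate_runs"] == 1
        assert df.loc["x", "selected_runs"] == 0
        assert df.loc["x", "frequency"] == 0.0


class TestComplexityCorrelation:
    def test_model_complexities(self):
        for label, c in zip(MODEL_LABELS, MODEL_COMPLEXITIES):
            assert model_complexity(parse_weight_model(label)) == c

    def test_concordant_pairs_give_one(self):
        tau, _ = complexity_node_correlation([(1, 1), (2, 2), (3, 3), (4, 5)])
        assert tau == pytest.approx(1.0)

    def test_hand_counted_tie_example(self):
        # {(1,1),(2,2),(3,1)}: one concordant, one discordant, one y-tie
        tau, _ = complexity_node_correlation([(1, 1), (2, 2), (3, 1)])
        assert tau == pytest.approx(0.0, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            complexity_node_correlation([(1, 1), (1, 2)])

    def test_published_grid_reproduces_reported_tau(self):
        grid = selection_node_counts()
        pairs = [
            (c, grid.loc[scen, label])
            for scen in grid.index
            for label, c in zip(MODEL_LABELS, MODEL_COMPLEXITIES)
            if not math.isnan(grid.loc[scen, label])
        ]
        assert len(pairs) == 27
        tau, p = complexity_node_correlation(pairs)
        assert tau == pytest.approx(0.634, abs=0.005)
        assert p < 0.001
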