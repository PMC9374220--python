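"""Synthetic genotypes and graphs for testing the full pipeline.

Real microsatellite surveys of the kind this package targets (hundreds of
diploid individuals, ~20 sites, ~10 loci) are rarely redistributable, so
the generator emulates their statistical shape: per-locus allele
frequencies drift away from a shared ancestral pool under a Dirichlet
model (a balanced-drift approximation of the island model), optionally
with two clusters of populations that exchange almost no migrants —
mimicking sites separated by a major river barrier. Genotypes are two
independent allele draws per individual per locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .genio import GenotypeTable

__all__ = [
    "SimulationConfig",
    "simulate_genotypes",
    "random_weighted_graph",
    "fixture_toy_graphs",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the Dirichlet-drift genotype generator.

    ``divergence`` (F, in (0, 1)) controls how far population allele
    frequencies drift from the ancestral pool: the Dirichlet concentration
    is ``(1 - F) / F``, so F → 0 recovers panmixia and F → 1 pure drift.
    ``structure="island"`` mixes every population back toward the ancestral
    frequencies with weight ``migration``; ``structure="two_clusters"``
    first drifts two cluster-level pools apart, drifts populations within
    their cluster, then mixes with weight ``m_within`` toward the cluster
    pool and ``m_between`` toward the global pool. ``cluster_divergence``
    sets how far the two cluster pools drift from the ancestral one.
    """

    n_pops: int = 8
    n_individuals: int = 30
    n_loci: int = 9
    n_alleles: int = 8
    divergence: float = 0.1
    structure: str = "island"
    migration: float = 0.05
    m_within: float = 0.2
    m_between: float = 0.001
    cluster_divergence: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.divergence < 1.0:
            raise ValueError("divergence F must be in (0, 1)")
        if self.structure not in ("island", "two_clusters"):
            raise ValueError(f"unknown structure {self.structure!r}")
        for name in ("migration", "m_within", "m_between"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.m_within + self.m_between > 1.0:
            raise ValueError("m_within + m_between must not exceed 1")
        if min(self.n_pops, self.n_individuals, self.n_loci, self.n_alleles) < 1:
            raise ValueError("counts must be positive")


def _drift(rng: np.random.Generator, base: np.ndarray, f: float) -> np.ndarray:
    """One Dirichlet drift step away from ``base`` frequencies."""
    conc = np.clip(base, 1e-9, None) * (1.0 - f) / f
    return rng.dirichlet(conc)


def simulate_genotypes(config: SimulationConfig) -> GenotypeTable:
    """Draw a :class:`GenotypeTable` under the configured structure.

    Fully reproducible: the same config (including seed) yields a
    bitwise-identical table.
    """
    rng = np.random.default_rng(config.seed)
    k, n, m, a = (
        config.n_pops,
        config.n_individuals,
        config.n_loci,
        config.n_alleles,
    )
    ancestral = [rng.dirichlet(np.ones(a)) for _ in range(m)]
    freqs = np.empty((k, m, a))
    if config.structure == "island":
        for p in range(k):
            for l in range(m):
                drifted = _drift(rng, ancestral[l], config.divergence)
                freqs[p, l] = (
                    (1.0 - config.migration) * drifted
                    + config.migration * ancestral[l]
                )
    else:
        cluster_of = np.array([0] * (k // 2) + [1] * (k - k // 2))
        cluster_pools = np.empty((2, m, a))
        for c in range(2):
            for l in range(m):
                cluster_pools[c, l] = _drift(
                    rng, ancestral[l], config.cluster_divergence
                )
        for p in range(k):
            c = cluster_of[p]
            for l in range(m):
                drifted = _drift(rng, cluster_pools[c, l], config.divergence)
                own = 1.0 - config.m_within - config.m_between
                freqs[p, l] = (
                    own * drifted
                    + config.m_within * cluster_pools[c, l]
                    + config.m_between * ancestral[l]
                )

    individuals, populations, calls = [], [], []
    for p in range(k):
        pop = f"P{p + 1:02d}"
        for i in range(n):
            individuals.append(f"{pop}_{i + 1:03d}")
            populations.append(pop)
            row = [
                tuple(rng.choice(a, size=2, p=freqs[p, l]) + 1)
                for l in range(m)
            ]
            calls.append(row)
    loci = [f"loc{l + 1}" for l in range(m)]
    return GenotypeTable(individuals, populations, loci, np.array(calls))


def random_weighted_graph(
    n: int,
    density: float,
    weight_range: tuple[float, float] = (1.0, 10.0),
    seed: int | None = None,
    connected: bool = False,
    max_tries: int = 200,
) -> nx.Graph:
    """Erdős–Rényi graph with uniform edge weights.

    With ``connected=True`` the sampler rejects until the graph is
    connected (bounded retries).
    """
    if not 0.0 < density <= 1.0:
        raise ValueError("density must be in (0, 1]")
    lo, hi = weight_range
    if lo <= 0 or hi < lo:
        raise ValueError("weight range must be positive and ordered")
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        g = nx.Graph()
        g.add_nodes_from(f"n{i}" for i in range(n))
        nodes = list(g.nodes)
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < density:
                    g.add_edge(
                        nodes[i], nodes[j], weight=float(rng.uniform(lo, hi))
                    )
        if not connected or n <= 1 or nx.is_connected(g):
            return g
    raise RuntimeError(
        f"failed to draw a connected graph at density {density} in {max_tries} tries"
    )


def fixture_toy_graphs() -> dict[str, dict]:
    """Small deterministic graphs with known path-type classifications.

    Each entry holds the full graph, the conventional subgraph node set,
    and (where stated) the expected (B, R, I, D, E, S) counts:

    - ``star4``: hub ``c`` with leaves u/v/w; subgraph = leaves → every pair
      is a breakthrough, (3, 0, 0, 0, 0, 0).
    - ``tri_iso``: a triangle plus an isolated extra node; subgraph =
      triangle → every pair is a roadblock, (0, 3, 0, 0, 0, 0).
    - ``two_cluster``: two triangles joined through a bridge node; the
      bridge is the unique articulation point.
    - ``selection11``: an 11-node two-component world with three candidate
      nodes, one of which reconnects the components — a compact exercise
      for the stepwise selector.
    """
    star4 = nx.Graph()
    star4.add_weighted_edges_from([("c", "u", 1.0), ("c", "v", 1.0), ("c", "w", 1.0)])

    tri_iso = nx.Graph()
    tri_iso.add_weighted_edges_from(
        [("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0)]
    )
    tri_iso.add_node("x")

    two_cluster = nx.Graph()
    two_cluster.add_weighted_edges_from(
        [
            ("a1", "a2", 1.0), ("a2", "a3", 1.0), ("a1", "a3", 1.0),
            ("b1", "b2", 1.0), ("b2", "b3", 1.0), ("b1", "b3", 1.0),
            ("a2", "bridge", 1.0), ("a3", "bridge", 1.0),
            ("bridge", "b1", 1.0), ("bridge", "b2", 1.0),
        ]
    )

    sel = nx.Graph()
    # two chains 1-2-3-4 and 5-6-7-8, candidates 9/10/11; 11 joins the
    # chain ends directly, 9 and 10 only attach within one component
    sel.add_weighted_edges_from(
        [
            ("1", "2", 1.0), ("2", "3", 1.0), ("3", "4", 1.0),
            ("5", "6", 1.0), ("6", "7", 1.0), ("7", "8", 1.0),
            ("9", "1", 1.0), ("9", "3", 1.0),
            ("10", "6", 1.0), ("10", "8", 1.0),
            ("11", "4", 1.0), ("11", "5", 1.0), ("11", "2", 1.0),
        ]
    )

    return {
        "star4": {
            "graph": star4,
            "subgraph": {"u", "v", "w"},
            "expected": (3, 0, 0, 0, 0, 0),
        },
        "tri_iso": {
            "graph": tri_iso,
            "subgraph": {"a", "b", "c"},
            "expected": (0, 3, 0, 0, 0, 0),
        },
        "two_cluster": {
            "graph": two_cluster,
            "subgraph": {"a1", "a2", "a3", "b1", "b2", "b3"},
            "articulation": {"bridge"},
        },
        "selection11": {
            "graph": sel,
            "subgraph": {"1", "2", "3", "4", "5", "6", "7", "8"},
            "candidates": {"9", "10", "11"},
            "best_candidate": "11",
        },
    }
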