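"""Population-graph construction from multilocus genotypes.

The pipeline follows the conditional-covariance approach used in landscape
genetics: individuals are encoded as allele-count vectors, populations are
summarized by their centroids, the among-population covariance is turned
into partial correlations, and each potential edge is kept only when its
edge-exclusion deviance is significant under a chi-square(1) test. Retained
edges carry the pairwise genetic distance derived from the covariance, and
conditional genetic distance (cGD) between any two populations is the
shortest-path distance on the pruned graph.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .genio import MISSING, GenotypeTable, PopulationAttributes

__all__ = [
    "CovarianceSummary",
    "encode_genotypes",
    "population_covariance",
    "partial_correlations",
    "prune_popgraph",
    "build_popgraph",
    "cgd_distances",
    "write_graph",
    "read_graph",
]


@dataclass
class CovarianceSummary:
    """Among-population covariance and derived conditional-dependence terms."""

    populations: list[str]
    covariance: np.ndarray  # G, k x k symmetric
    partial_correlations: np.ndarray  # k x k, unit diagonal
    deviance: np.ndarray  # edge-exclusion deviance, k x k, zero diagonal
    n_total: int


def encode_genotypes(
    table: GenotypeTable,
    *,
    missing: Literal["mean", "drop"] = "mean",
) -> tuple[np.ndarray, list[tuple[str, int]], list[str]]:
    """Encode diploid genotypes as an individuals × allele-count matrix.

    One column per (locus, allele) pair observed anywhere in the table; the
    entry is the number of copies (0/1/2) the individual carries. Missing
    genotypes are either grand-mean imputed per column (``"mean"``) or the
    individual is dropped entirely (``"drop"``).

    Returns the matrix, the column labels, and the retained population
    labels (one per matrix row).
    """
    if missing not in ("mean", "drop"):
        raise ValueError("missing must be 'mean' or 'drop'")
    n, m, _ = table.calls.shape
    columns: list[tuple[str, int]] = []
    for l, locus in enumerate(table.loci):
        alleles = np.unique(table.calls[:, l, :])
        alleles = alleles[alleles != MISSING]
        columns.extend((locus, int(a)) for a in alleles)
    col_index = {c: j for j, c in enumerate(columns)}

    X = np.zeros((n, len(columns)))
    missing_mask = np.zeros((n, len(columns)), dtype=bool)
    for i in range(n):
        for l, locus in enumerate(table.loci):
            a, b = table.calls[i, l]
            if a == MISSING or b == MISSING:
                for (loc2, al), j in col_index.items():
                    if loc2 == locus:
                        missing_mask[i, j] = True
                continue
            X[i, col_index[(locus, int(a))]] += 1
            X[i, col_index[(locus, int(b))]] += 1

    pops = list(table.populations)
    if missing == "drop":
        keep = ~missing_mask.any(axis=1)
        X = X[keep]
        missing_mask = missing_mask[keep]
        pops = [p for p, k in zip(pops, keep) if k]
    if missing_mask.any():
        observed = np.ma.masked_array(X, mask=missing_mask)
        col_means = observed.mean(axis=0).filled(0.0)
        X = np.where(missing_mask, col_means[None, :], X)
    return X, columns, pops


def population_covariance(
    encoded: np.ndarray,
    populations: Sequence[str],
    *,
    inversion: Literal["auto", "pinv", "ridge"] = "auto",
) -> CovarianceSummary:
    """Among-population covariance from the encoded genotype matrix.

    Columns are centered over all individuals, population centroids are the
    per-population means, and ``G = C C' / p`` with *p* the number of allele
    columns. Partial correlations and edge-exclusion deviances
    ``EED_ij = -N ln(1 - r_ij^2)`` are attached for pruning.
    """
    encoded = np.asarray(encoded, dtype=float)
    pops = list(dict.fromkeys(populations))
    if len(pops) < 3:
        raise ValueError("need at least 3 populations for partial correlations")
    labels = np.asarray(populations)
    centroids = []
    for pop in pops:
        members = encoded[labels == pop]
        if members.shape[0] == 0:
            raise ValueError(f"population {pop!r} has no individuals")
        centroids.append(members.mean(axis=0))
    C = np.asarray(centroids) - encoded.mean(axis=0)
    G = C @ C.T / encoded.shape[1]
    N = encoded.shape[0]
    P = partial_correlations(G, inversion=inversion)
    with np.errstate(divide="ignore"):
        dev = -N * np.log1p(-np.clip(P**2, 0.0, 1.0 - 1e-15))
    np.fill_diagonal(dev, 0.0)
    return CovarianceSummary(pops, G, P, dev, N)


def partial_correlations(
    cov: np.ndarray,
    *,
    inversion: Literal["auto", "pinv", "ridge"] = "auto",
    rcond: float = 1e-10,
) -> np.ndarray:
    """Partial correlations from a covariance matrix.

    The covariance is scaled to a correlation matrix R and the precision
    Ω obtained by direct solve when R is well conditioned. An
    among-population covariance built from globally centered data is exactly
    rank-deficient (the size-weighted centroid sum vanishes), in which case
    ``"auto"`` falls back to a spectral pseudoinverse that drops eigenvalues
    below ``rcond`` times the largest; ``"ridge"`` instead adds
    ``1e-8 * mean(diag)`` to the diagonal (kept for compatibility — on the
    structurally singular case it drives every partial correlation to −1).
    Off-diagonal entries are ``r_ij = -Ω_ij / sqrt(Ω_ii Ω_jj)``.
    """
    G = np.asarray(cov, dtype=float)
    diag = np.diag(G)
    if (diag < -1e-12).any():
        raise ValueError("covariance has negative diagonal entries")
    # zero-variance rows (populations identical to the global centroid)
    # carry no conditional-dependence signal; flooring keeps them isolated
    d = np.sqrt(np.clip(diag, 1e-30, None))
    R = G / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    eig = np.linalg.eigvalsh(R)
    singular = eig[0] < rcond * eig[-1]
    if singular and inversion == "auto":
        warnings.warn(
            "correlation matrix is singular; using spectral pseudoinverse",
            stacklevel=2,
        )
    if inversion == "ridge":
        eps = 1e-8 * float(np.mean(np.diag(R)))
        omega = np.linalg.inv(R + eps * np.eye(len(R)))
    elif inversion == "pinv" or singular:
        omega = np.linalg.pinv(R, rcond=rcond, hermitian=True)
    else:
        omega = np.linalg.inv(R)
    od = np.sqrt(np.diag(omega))
    P = -omega / np.outer(od, od)
    np.fill_diagonal(P, 1.0)
    return np.clip(P, -1.0, 1.0)


def prune_popgraph(
    cov: CovarianceSummary,
    *,
    alpha: float = 0.05,
    sqrt_weights: bool = True,
    attributes: Iterable[PopulationAttributes] | None = None,
) -> nx.Graph:
    """Prune the saturated population graph by edge-exclusion deviance.

    An edge (i, j) is retained iff ``EED_ij`` exceeds the chi-square(1)
    critical value at level ``alpha`` — i.e. removing it would significantly
    worsen the fit of the conditional-independence model. Retained edges are
    weighted by the pairwise genetic distance
    ``w_ij = sqrt(g_ii + g_jj - 2 g_ij)`` (the square root is skipped when
    ``sqrt_weights=False``).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    crit = stats.chi2.ppf(1.0 - alpha, df=1)
    G = nx.Graph(alpha=alpha, n_total=cov.n_total)
    G.add_nodes_from(cov.populations)
    gmat = cov.covariance
    k = len(cov.populations)
    for i in range(k):
        for j in range(i + 1, k):
            if cov.deviance[i, j] > crit:
                d2 = gmat[i, i] + gmat[j, j] - 2.0 * gmat[i, j]
                w = float(np.sqrt(max(d2, 0.0))) if sqrt_weights else float(max(d2, 0.0))
                G.add_edge(
                    cov.populations[i],
                    cov.populations[j],
                    weight=max(w, 1e-12),
                )
    if attributes is not None:
        attach_attributes(G, attributes)
    return G


def attach_attributes(
    graph: nx.Graph, attributes: Iterable[PopulationAttributes]
) -> nx.Graph:
    """Attach HE / PSize / EO / N node attributes in place."""
    by_id = {a.id: a for a in attributes}
    for node in graph.nodes:
        if node in by_id:
            a = by_id[node]
            graph.nodes[node].update(N=a.n, HE=a.he, PSize=a.psize, EO=a.eo)
    return graph


def build_popgraph(
    table: GenotypeTable,
    *,
    alpha: float = 0.05,
    missing: Literal["mean", "drop"] = "mean",
    inversion: Literal["auto", "pinv", "ridge"] = "auto",
    sqrt_weights: bool = True,
    attributes: Iterable[PopulationAttributes] | None = None,
) -> tuple[nx.Graph, CovarianceSummary]:
    """Genotypes → pruned population graph, in one call."""
    X, _, pops = encode_genotypes(table, missing=missing)
    cov = population_covariance(X, pops, inversion=inversion)
    graph = prune_popgraph(
        cov, alpha=alpha, sqrt_weights=sqrt_weights, attributes=attributes
    )
    return graph, cov


def cgd_distances(graph: nx.Graph) -> pd.DataFrame:
    """All-pairs conditional genetic distance (weighted shortest paths).

    Unreachable pairs get ``inf``; the diagonal is zero.
    """
    nodes = list(graph.nodes)
    dist = pd.DataFrame(np.inf, index=nodes, columns=nodes, dtype=float)
    for u, lengths in nx.all_pairs_dijkstra_path_length(graph, weight="weight"):
        for v, d in lengths.items():
            dist.loc[u, v] = d
    for n in nodes:
        dist.loc[n, n] = 0.0
    return dist


# ---------------------------------------------------------------------------
# Graph IO
# ---------------------------------------------------------------------------

def write_graph(graph: nx.Graph, path: str | Path, fmt: str | None = None) -> None:
    """Write a population graph as GraphML or a weighted edge list.

    The edge-list format is three comma-separated columns ``u,v,w`` with a
    header, plus an ``# node:`` line per node so isolated nodes survive the
    round trip.
    """
    path = Path(path)
    fmt = fmt or ("graphml" if path.suffix == ".graphml" else "edgelist")
    if fmt == "graphml":
        nx.write_graphml(graph, path)
    elif fmt == "edgelist":
        lines = ["u,v,weight"]
        lines.extend(f"# node: {n}" for n in graph.nodes)
        lines.extend(
            f"{u},{v},{d['weight']:.17g}" for u, v, d in graph.edges(data=True)
        )
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown graph format {fmt!r}")


def read_graph(path: str | Path, fmt: str | None = None) -> nx.Graph:
    """Read a graph written by :func:`write_graph`.

    Edge lists may be comma- or whitespace-delimited, with or without the
    header; a duplicate (u,v)/(v,u) entry is accepted only when the weights
    agree.
    """
    path = Path(path)
    fmt = fmt or ("graphml" if path.suffix == ".graphml" else "edgelist")
    if fmt == "graphml":
        g = nx.read_graphml(path)
        return nx.Graph(g)
    if fmt != "edgelist":
        raise ValueError(f"unknown graph format {fmt!r}")
    g = nx.Graph()
    declared: set[str] = set()
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("# node:"):
            node = line.split(":", 1)[1].strip()
            declared.add(node)
            g.add_node(node)
            continue
        if line.startswith("#"):
            continue
        parts = [p for p in re.split(r"[,\s]+", line) if p]
        if parts[0].lower() == "u" and parts[1].lower() == "v":
            continue  # header
        if len(parts) != 3:
            raise ValueError(f"line {lineno}: expected 'u v w'")
        u, v, w = parts[0], parts[1], float(parts[2])
        if g.has_edge(u, v) and abs(g[u][v]["weight"] - w) > 1e-9 * max(1.0, abs(w)):
            raise ValueError(
                f"line {lineno}: conflicting weights for undirected edge ({u}, {v})"
            )
        g.add_edge(u, v, weight=w)
    if declared:
        undeclared = set(g.nodes) - declared
        if undeclared:
            raise ValueError(
                f"edge list references undeclared node(s): {sorted(undeclared)}"
            )
    return g
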