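# Methods

## Population graph

**Encoding.** Each individual becomes a vector with one column per
(locus, allele) pair observed anywhere in the data; the entry is the number
of copies carried (0/1/2). Missing genotypes are grand-mean imputed per
column by default (`missing="mean"`), which keeps every individual usable;
`missing="drop"` removes incompletely typed individuals instead. Both are
exposed because field practice varies and the choice is rarely reported.

**Covariance.** Columns are centered over all individuals; population
centroids are per-population means; the among-population covariance is
`G = C Cᵀ / P` with `P` allele columns. Pairwise genetic distance is
`d²_ij = g_ii + g_jj - 2 g_ij`, and retained edges carry `w_ij = d_ij`
(square root applied; `sqrt_weights=False` gives the squared variant — the
choice only rescales the graph monotonically and does not change hop-count
analyses).

**Pruning.** `G` is rescaled to a correlation matrix `R`; with precision
`Ω = R⁻¹`, partial correlations are `r_ij = -Ω_ij/√(Ω_ii Ω_jj)` and the
edge-exclusion deviance is `EED_ij = -N ln(1 - r_ij²)` with `N` the total
number of individuals (deviance tests in Gaussian graphical models use the
total sample size). An edge is kept iff its EED exceeds the χ² critical
value with 1 df at level α (default 0.05): removing such an edge would
significantly worsen the conditional-independence model, i.e. the pair
carries genetic covariance not explained by the remaining populations.

**Numerical note — structural rank deficiency.** Because the columns are
centered over all individuals, the size-weighted sum of population
centroids is exactly zero, so `G` (and `R`) is always singular by one
rank. A naive ridge inverse (`R + εI`, ε = 1e-8·mean diag) is dominated by
the null direction and drives *every* partial correlation to −1, making
pruning vacuous. The default inversion is therefore a spectral
pseudoinverse that discards eigenvalues below 1e-10 of the largest;
full-rank matrices still use a direct solve (verified against the
three-variable closed form `r_ij·k`). The ridge variant remains available
as `inversion="ridge"` for comparison. Populations with zero distance to
the global centroid carry no conditional signal and are left isolated
rather than raising an error.

**Re-estimation.** Subgraphs used downstream are induced subgraphs of the
full pruned graph; the graph is *not* re-pruned after node removals. A
`reestimate` workflow can be composed manually (rebuild from the genotype
subset), but the default matches standard practice of analysing one fixed
graph.

## Node metrics

Degree, betweenness (unnormalized, fractional counting over co-shortest
paths), eigenvector centrality (principal adjacency eigenvector, rescaled
to max = 1) and clustering coefficient are computed on the **unweighted**
topology; on a sparse population graph the hop-count versions are the ones
that isolate stepping-stone structure, and an APL of ~2.7 on a 19-node
genetic-distance graph is only interpretable as hops. Weighted variants
sit behind `weighted=True`. Clustering for degree-<2 nodes is reported as
0 by convention (option for NaN). Average path length averages hop counts
over unordered pairs; for disconnected graphs it averages reachable pairs
with a warning (or returns ∞ on request), which is what post-removal
graphs need. Strength (Σ incident weights) and AIEW (mean of 1/w over
incident edges; larger = more migrants) use the weights by definition.

## BRIDES classification

For subgraph nodes S of full graph X_all: X_n is the subgraph *induced* on
S, the candidate set K = nodes(X_all) \ S. For every unordered pair
(u, v) ⊆ S:

- `d_n` = shortest path in X_n;
- `d*` = min over k ∈ K of `d(u, k) + d(k, v)` in X_all — the exact optimal
  walk touching K under non-negative lengths (the realized route may
  revisit nodes; this is the documented contract).

Types: B (`d_n = ∞, d* < ∞`), R (`d_n < ∞, d* = ∞`), I (both ∞), D
(`d_n < d*`), E (equal), S (`d_n > d*`). Counts always partition the
C(|S|, 2) pairs. Path mode defaults to hop counts (consistent with the
metric layer); weighted mode treats two lengths as equal within relative
tolerance 1e-9 to avoid spurious D/S from rounding.

One subtlety: adding an edge inside X_n (which, X_n being induced, also
adds it to X_all) can convert an Impasse into a Breakthrough, because the
new edge may open a constrained route through K while the pair stays
disconnected inside X_n. The monotone invariant that genuinely holds — and
that the property suite asserts — is that the unreachable-in-X_n classes
B + I never grow when subgraph edges are added.

## Stepwise selection

A scenario selects the starting subgraph from attributes with **strict**
inequalities: proactive keeps populations strictly better than the
threshold, reactive strictly worse, and boundary-equal populations join
neither side (they remain candidates). EO ranks are ordered
A > AB > B > BC > C > CD > D; "better than BC" = {A, AB, B}, "worse than
B" = {BC, C, CD, D}. With the bundled 19-population panel and thresholds
H_E 0.72 / size 75 / EO (BC, B), the six scenarios span 6 to 13 nodes.

Scores: `raw(A) = Σ w_t · count_t` for the classification of the base
pairs against the graph induced on base ∪ A; the maximum is `raw(K)` (all
candidates) and normalized scores divide by it. The selector is a
breadth-first greedy with full tie branching: at each depth every frontier
set is extended by every remaining candidate, all extensions tying for the
depth's best score survive (deduplicated as sets), and the first depth at
which a branch reaches normalized score 1 (tolerance 1e-9) is reported,
with every distinct terminating set as a co-optimal solution. Because the
full candidate set always attains the maximum, branches that plateau keep
growing and termination is guaranteed. When the maximum raw score is not
positive (possible with negative weights, or with the shortcut-only model
when no shortcut exists anywhere), normalization is undefined and the run
is flagged "no solution" — no node is worth adding.

Greedy stepping does not guarantee exact minimum-cardinality solutions;
the test suite runs an exhaustive subset oracle on small instances and
requires the greedy depth never to undercut the exact optimum and to match
it in ≥80% of solvable instances (observed agreement in practice is
higher). Selection frequency divides, per node, the number of scenario ×
model runs in which it appears in at least one optimal solution by the
number of runs in which it was a candidate; no-solution runs count in the
denominator. This definition is recorded in the output metadata because
published "selection probability" columns rarely state theirs.

Kendall's tau between weighting-scheme complexity (number of nonzero
weights) and minimal node counts uses tau-b with tie corrections
(scipy.stats.kendalltau), hand-checked against a small tied example; on
the bundled published grid (27 non-empty cells, complexities 1, 2, 2, 4, 4)
it reproduces the reported 0.634.

## Synthetic data

The generator emulates the statistical shape of a microsatellite survey —
diploid multiallelic genotypes, ~10 loci, tens of individuals per
population — without forward-time simulation. Per locus, ancestral
frequencies are symmetric Dirichlet(1); population frequencies drift as
Dirichlet with concentration `(1−F)/F` (F ∈ (0,1); F → 0 is panmixia);
island structure mixes each population back toward the ancestral pool with
weight m, and two-cluster structure first drifts two cluster pools
(concentration from `cluster_divergence`), drifts populations within their
cluster, then mixes with `m_within` toward the cluster pool and
`m_between` (default 0.001, near-complete isolation) toward the global
pool. Genotypes are two independent draws per individual per locus.

Defaults — 8 populations × 30 diploids × 9 loci × 8 alleles, F = 0.1,
cluster divergence 0.2 — give expected heterozygosities around 0.6–0.7,
matching what field microsatellite panels report, and keep every test
cheap. Under two-cluster defaults the pruned graph reliably routes
inter-cluster shortest paths through the endpoints of the few
between-shore edges (top betweenness in 20/20 seeds at the property test's
conditions).

What the generator does **not** emulate: linkage, mutation models
(SMM/IAM), null alleles, uneven sampling, isolation-by-distance within
clusters, and temporal structure. Passing tests therefore demonstrate
correctness of the algorithms under the drift-plus-sampling model, not
robustness to every artifact of real data. Two further limits are worth
stating. First, distances under F → 0 do not reach zero but the binomial
sampling floor `(1/P) Σ_j 4 p_j (1−p_j) / n`; the limit test checks
against that floor rather than an absolute constant. Second, pruned-graph
density is *invariant* to the island migration rate by construction:
uniform mixing toward the ancestral pool rescales all centroid deviations
by (1−m), and pruning depends only on the scale-free correlation
structure. Density comparisons across migration regimes require structured
(e.g. stepping-stone) migration, which this generator does not implement.

## Problem sizes

Randomized suites use graphs of ≤10 nodes against brute-force oracles
(simple-path enumeration, product-graph Dijkstra, delete-and-check
articulation, exhaustive subset search), 1000 instances for the counting
invariant and 100 for the oracle-equivalence checks; simulation-backed
properties use 10–20 seeds at the default generator sizes. These sizes
make every oracle exact while keeping the whole suite under ~10 s.
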