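"""Protein-level interaction graph: components, degrees, MCL, failure test.

The high-confidence network has one node per protein and one edge per
predicted pair above the pDockQ threshold.  Components and degree
statistics are delegated to networkx; Markov Clustering (expansion /
inflation on the column-stochastic transition matrix with self-loops)
is implemented here; the prediction-failure randomness check permutes
success labels across attempted pair-slots and applies a
Benjamini-Hochberg correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests


@dataclass
class ComponentSummary:
    n_edges: int
    n_nodes: int
    members: set[str]


@dataclass
class MCLResult:
    clusters: list[set[str]]
    inflation: float
    iterations: int
    converged: bool


def build_graph(summaries, pdockq_min: float = 0.5) -> nx.Graph:
    """Graph of pairs with pDockQ >= ``pdockq_min``.

    ``summaries`` is a DataFrame (or list of dicts) with ``protein_a``,
    ``protein_b`` and ``pdockq``.  Duplicate pairs collapse to one edge
    keeping the maximum pDockQ; nodes are edge endpoints only.
    """
    if not isinstance(summaries, pd.DataFrame):
        summaries = pd.DataFrame(list(summaries))
    for col in ("protein_a", "protein_b", "pdockq"):
        if col not in summaries.columns:
            raise ValueError(f"summaries lack column {col!r}")
    if summaries[["protein_a", "protein_b"]].isna().any().any():
        raise ValueError("missing protein ids")
    graph = nx.Graph()
    kept = summaries[summaries["pdockq"] >= pdockq_min]
    for row in kept.itertuples(index=False):
        a, b = str(row.protein_a), str(row.protein_b)
        if a == b:
            continue  # the network is heterodimeric; no self-loops
        q = float(row.pdockq)
        if graph.has_edge(a, b):
            if q > graph[a][b]["pdockq"]:
                graph[a][b]["pdockq"] = q
        else:
            graph.add_edge(a, b, pdockq=q)
    return graph


def connected_components(graph: nx.Graph) -> list[ComponentSummary]:
    """Components sorted by edge count (descending), then node count."""
    comps = []
    for nodes in nx.connected_components(graph):
        sub = graph.subgraph(nodes)
        comps.append(ComponentSummary(n_edges=sub.number_of_edges(),
                                      n_nodes=len(nodes),
                                      members=set(nodes)))
    comps.sort(key=lambda c: (-c.n_edges, -c.n_nodes,
                              min(c.members) if c.members else ""))
    return comps


def n_singletons(components: list[ComponentSummary]) -> int:
    """Number of singleton PPIs: components with exactly one edge."""
    return sum(1 for c in components if c.n_edges == 1)


def degree_stats(graph: nx.Graph) -> tuple[float, dict[int, int]]:
    """Mean degree (2E/V) and the degree histogram."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    degrees = [d for _, d in graph.degree()]
    hist: dict[int, int] = {}
    for d in degrees:
        hist[d] = hist.get(d, 0) + 1
    return 2 * graph.number_of_edges() / graph.number_of_nodes(), hist


def exclude_nodes(graph: nx.Graph, drop) -> nx.Graph:
    """Induced subgraph on the complement of ``drop``, minus isolated nodes."""
    keep = [n for n in graph.nodes if n not in set(drop)]
    sub = graph.subgraph(keep).copy()
    sub.remove_nodes_from([n for n, d in sub.degree() if d == 0])
    return sub


def mcl_cluster(graph: nx.Graph, inflation: float = 2.0,
                expansion: int = 2, max_iter: int = 100,
                prune_eps: float = 1e-6,
                tol: float = 1e-8) -> MCLResult:
    """Markov Clustering on the undirected graph.

    Self-loops of weight 1 are added, columns are normalized to a
    stochastic transition matrix, and expansion (matrix power) alternates
    with inflation (elementwise power + column renormalization), pruning
    entries below ``prune_eps``, until the matrix change falls below
    ``tol`` or ``max_iter`` is reached.  Clusters are read off attractor
    rows; a node attached to several attractors goes to the largest
    cluster (ties: the lexicographically smallest member set wins).
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    nodes = sorted(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    m = np.zeros((n, n))
    for a, b in graph.edges:
        m[index[a], index[b]] = 1.0
        m[index[b], index[a]] = 1.0
    np.fill_diagonal(m, 1.0)
    m /= m.sum(axis=0, keepdims=True)
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        prev = m
        m = np.linalg.matrix_power(m, expansion)
        m = m ** inflation
        m[m < prune_eps] = 0.0
        colsum = m.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        m /= colsum
        if np.abs(m - prev).max() < tol:
            converged = True
            break
    raw: list[set[int]] = []
    for i in range(n):
        if m[i, i] > prune_eps:  # attractor row
            members = set(np.nonzero(m[i] > prune_eps)[0])
            members.add(i)
            if members not in raw:
                raw.append(members)
    assignment: dict[int, set[int]] = {}
    for cluster in sorted(raw, key=lambda c: (-len(c), sorted(c))):
        for i in cluster:
            assignment.setdefault(i, cluster)
    clusters_idx: dict[frozenset, set[int]] = {}
    for i in range(n):
        cluster = assignment.get(i, {i})  # orphan nodes become singletons
        clusters_idx.setdefault(frozenset(cluster), set()).add(i)
    clusters = [set(nodes[i] for i in members)
                for members in clusters_idx.values()]
    clusters.sort(key=lambda c: (-len(c), sorted(c)))
    return MCLResult(clusters=clusters, inflation=inflation,
                     iterations=iterations, converged=converged)


def failure_randomness_test(attempted: dict[str, int],
                            succeeded: dict[str, int],
                            n_perm: int = 5000,
                            seed: int = 0) -> pd.DataFrame:
    """Are per-protein prediction failures compatible with random failure?

    Success labels are permuted ``n_perm`` times across all attempted
    pair-slots, holding the total number of successes fixed.  For each
    protein the empirical p-value is the (add-one corrected) fraction of
    permutations with a success fraction at most the observed one;
    p-values are Benjamini-Hochberg adjusted across proteins.
    """
    proteins = sorted(attempted)
    counts = np.array([attempted[p] for p in proteins])
    succ = np.array([succeeded.get(p, 0) for p in proteins])
    if np.any(counts <= 0):
        raise ValueError("every protein needs at least one attempt")
    if np.any(succ > counts):
        raise ValueError("more successes than attempts")
    total = int(counts.sum())
    labels = np.zeros(total, dtype=bool)
    labels[:int(succ.sum())] = True
    slot_owner = np.repeat(np.arange(len(proteins)), counts)
    observed = succ / counts
    rng = np.random.default_rng(seed)
    hits = np.zeros(len(proteins), dtype=int)
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        frac = np.bincount(slot_owner, weights=perm,
                           minlength=len(proteins)) / counts
        hits += frac <= observed + 1e-12
    pvals = (1 + hits) / (n_perm + 1)
    fdr = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame({"protein": proteins, "attempted": counts,
                         "succeeded": succ, "success_fraction": observed,
                         "p_value": pvals, "fdr": fdr})
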