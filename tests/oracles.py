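"""Independent reference implementations used only to check the package.

Each oracle deliberately takes the dumbest correct route (exhaustive
enumeration, all-pairs scans) and shares no code with the implementation
it validates.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np


def fisher_tail_enumeration(a: int, b: int, c: int, d: int) -> float:
    """One-sided Fisher p by summing hypergeometric point probabilities.

    Enumerates every 2x2 table with the observed margins whose top-left
    cell is >= a.
    """
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2
    denom = comb(n, col1)
    p = 0.0
    for k in range(a, min(row1, col1) + 1):
        if col1 - k <= row2:
            p += comb(row1, k) * comb(row2, col1 - k) / denom
    return p


def segment_reference(mask, min_len: int, max_gap: int):
    """Reference run segmentation: cluster true indices, bridge, filter."""
    idx = [i for i, v in enumerate(mask) if v]
    if not idx:
        return []
    groups = [[idx[0]]]
    for i in idx[1:]:
        if i - groups[-1][-1] - 1 <= max_gap:
            groups[-1].append(i)
        else:
            groups.append([i])
    return [(g[0] + 1, g[-1] + 1) for g in groups
            if g[-1] - g[0] + 1 >= min_len]


def contacts_brute_force(complex_model, cutoff: float):
    """All-pairs heavy-atom scan; returns {(res_a, res_b): min_distance}."""
    out = {}
    for ra in complex_model.chain_a:
        ca = ra.coords()
        for rb in complex_model.chain_b:
            d = np.sqrt(((ca[:, None, :] - rb.coords()[None, :, :]) ** 2)
                        .sum(axis=2)).min()
            if d <= cutoff:
                out[(ra.residue_index, rb.residue_index)] = d
    return out


def moving_average_reference(values, window: int):
    """Per-position direct summation with shrinking windows."""
    n = len(values)
    half = window // 2
    return np.array([np.mean(values[max(0, i - half):min(n, i + half + 1)])
                     for i in range(n)])


def union_find_components(edges):
    """Connected components via union-find (no networkx)."""
    parent = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    comps = {}
    for node in parent:
        comps.setdefault(find(node), set()).add(node)
    return sorted(comps.values(), key=lambda s: (-len(s), sorted(s)))


def exact_failure_pvalues(attempted: dict, succeeded: dict) -> dict:
    """Exact permutation p-values by enumerating all label assignments.

    Mirrors the permutation scheme: successes are placed uniformly on
    attempted pair-slots; the p-value is the probability (including the
    observed assignment, matching the add-one estimator's target) that a
    protein's success fraction is <= the observed one.
    """
    proteins = sorted(attempted)
    slots = [p for p in proteins for _ in range(attempted[p])]
    total = len(slots)
    n_succ = sum(succeeded.values())
    observed = {p: succeeded[p] / attempted[p] for p in proteins}
    hits = {p: 0 for p in proteins}
    n_assign = 0
    for chosen in combinations(range(total), n_succ):
        n_assign += 1
        counts = {p: 0 for p in proteins}
        for i in chosen:
            counts[slots[i]] += 1
        for p in proteins:
            if counts[p] / attempted[p] <= observed[p] + 1e-12:
                hits[p] += 1
    return {p: hits[p] / n_assign for p in proteins}


def mcl_reference(adjacency: np.ndarray, inflation: float = 2.0,
                  expansion: int = 2, max_iter: int = 100) -> list[set[int]]:
    """Plain-loop Markov clustering with the same published update rules."""
    m = adjacency.astype(float).copy()
    np.fill_diagonal(m, 1.0)
    m = m / m.sum(axis=0)
    for _ in range(max_iter):
        prev = m.copy()
        m = np.linalg.matrix_power(m, expansion)
        m = np.power(m, inflation)
        m = m / m.sum(axis=0)
        if np.abs(m - prev).max() < 1e-8:
            break
    clusters = []
    for i in range(len(m)):
        if m[i, i] > 1e-6:
            members = set(np.nonzero(m[i] > 1e-6)[0]) | {i}
            if members not in clusters:
                clusters.append(members)
    return clusters
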