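import networkx as nx
import numpy as np
import pandas as pd
import pytest

from oracles import (exact_failure_pvalues, mcl_reference,
                     union_find_components)
from ppimodes import (build_graph, connected_components, degree_stats,
                      exclude_nodes, failure_randomness_test, mcl_cluster,
                      n_singletons)


def _summaries(rows):
    return pd.DataFrame([{"protein_a": a, "protein_b": b, "pdockq": q}
                         for a, b, q in rows])


class TestBuildGraph:
    def test_threshold(self):
        g = build_graph(_summaries([("a", "b", 0.6), ("c", "d", 0.4),
                                    ("e", "f", 0.55)]))
        assert g.number_of_edges() == 2
        assert set(g.nodes) == {"a", "b", "e", "f"}

    def test_duplicates_collapse_keeping_max(self):
        g = build_graph(_summaries([("a", "b", 0.6), ("b", "a", 0.8)]))
        assert g.number_of_edges() == 1
        assert g["a"]["b"]["pdockq"] == 0.8

    def test_missing_ids_rejected(self):
        df = _summaries([("a", "b", 0.6)])
        df.loc[0, "protein_b"] = None
        with pytest.raises(ValueError, match="missing"):
            build_graph(df)


class TestComponents:
    def test_triangle_plus_edge(self):
        g = build_graph(_summaries([("a", "b", 0.9), ("b", "c", 0.9),
                                    ("a", "c", 0.9), ("x", "y", 0.9)]))
        comps = connected_components(g)
        assert [(c.n_edges, c.n_nodes) for c in comps] == [(3, 3), (1, 2)]
        assert n_singletons(comps) == 1

    def test_empty_graph(self):
        assert connected_components(nx.Graph()) == []

    def test_matches_union_find_on_random_graphs(self):
        rng = np.random.default_rng(51)
        for _ in range(30):
            n = int(rng.integers(2, 200))
            edges = {(int(a), int(b))
                     for a, b in rng.integers(0, n, (n, 2)) if a != b}
            g = nx.Graph()
            g.add_edges_from(edges)
            got = sorted((c.members for c in connected_components(g)),
                         key=lambda s: (-len(s), sorted(s)))
            assert got == union_find_components(edges)

    def test_component_edges_partition_edge_set(self):
        rng = np.random.default_rng(53)
        g = nx.gnp_random_graph(60, 0.03, seed=7)
        comps = connected_components(g)
        assert sum(c.n_edges for c in comps) == g.number_of_edges()
        all_nodes = [n for c in comps for n in c.members]
        assert sorted(all_nodes) == sorted(g.nodes)


class TestDegrees:
    def test_path(self):
        g = nx.path_graph(3)
        mean, hist = degree_stats(g)
        assert mean == pytest.approx(4 / 3)
        assert hist == {1: 2, 2: 1}

    def test_triangle(self):
        assert degree_stats(nx.complete_graph(3))[0] == 2.0

    def test_handshake_identity(self):
        for seed in range(10):
            g = nx.gnp_random_graph(50, 0.08, seed=seed)
            if g.number_of_nodes() == 0:
                continue
            mean, hist = degree_stats(g)
            assert sum(d * c for d, c in hist.items()) \
                == 2 * g.number_of_edges()
            assert mean == pytest.approx(2 * g.number_of_edges()
                                         / g.number_of_nodes())

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            degree_stats(nx.Graph())


class TestExcludeNodes:
    def test_drop_leaf(self):
        g = nx.path_graph(4)
        sub = exclude_nodes(g, [3])
        assert sub.number_of_edges() == 2

    def test_drop_absent_id_is_noop(self):
        g = nx.path_graph(4)
        sub = exclude_nodes(g, ["nope"])
        assert set(sub.edges) == set(g.edges)

    def test_drop_all(self):
        g = nx.path_graph(4)
        assert exclude_nodes(g, list(g.nodes)).number_of_nodes() == 0

    def test_dangling_endpoints_removed(self):
        g = nx.path_graph(3)
        sub = exclude_nodes(g, [1])  # middle node: 0 and 2 become isolated
        assert sub.number_of_nodes() == 0


def _two_triangles(bridge=False):
    g = nx.Graph()
    g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
    if bridge:
        g.add_edge(2, 3)
    return g


class TestMcl:
    def test_two_disjoint_triangles(self):
        result = mcl_cluster(_two_triangles())
        assert sorted(sorted(c) for c in result.clusters) == \
            [[0, 1, 2], [3, 4, 5]]
        assert result.converged

    def test_single_self_loop_node(self):
        g = nx.Graph()
        g.add_edge("a", "a")
        g.remove_edges_from(nx.selfloop_edges(g))
        g.add_node("a")
        result = mcl_cluster(g)
        assert result.clusters == [{"a"}]

    def test_bridged_triangles_still_split(self):
        result = mcl_cluster(_two_triangles(bridge=True), inflation=2.0)
        assert sorted(sorted(c) for c in result.clusters) == \
            [[0, 1, 2], [3, 4, 5]]

    def test_matches_reference_updates(self):
        # fixtures where pruning never activates, so the in-package
        # implementation and the plain-loop reference are step-identical
        for graph in (_two_triangles(), _two_triangles(bridge=True),
                      nx.path_graph(7), nx.cycle_graph(6)):
            nodes = sorted(graph.nodes)
            adj = nx.to_numpy_array(graph, nodelist=nodes)
            ref = mcl_reference(adj)
            got = mcl_cluster(graph)
            ref_named = sorted(sorted(nodes[i] for i in c) for c in ref)
            got_named = sorted(sorted(c) for c in got.clusters)
            # reference keeps overlapping attractor sets; compare after
            # the same largest-cluster resolution only when disjoint
            if sum(len(c) for c in ref) == len(nodes):
                assert got_named == ref_named

    def test_cluster_count_non_decreasing_in_inflation(self):
        g = _two_triangles(bridge=True)
        counts = [len(mcl_cluster(g, inflation=i).clusters)
                  for i in (1.5, 2.0, 4.0)]
        assert counts == sorted(counts)

    def test_clusters_partition_nodes(self):
        rng = np.random.default_rng(61)
        for seed in range(20):
            g = nx.gnp_random_graph(int(rng.integers(3, 40)), 0.15,
                                    seed=seed)
            if g.number_of_nodes() == 0:
                continue
            result = mcl_cluster(g)
            nodes = [n for c in result.clusters for n in c]
            assert sorted(nodes) == sorted(g.nodes)  # disjoint cover


class TestFailureRandomness:
    def test_uniform_success_no_outliers(self):
        out = failure_randomness_test({c: 5 for c in "abcd"},
                                      {c: 3 for c in "abcd"},
                                      n_perm=300, seed=1)
        assert (out["fdr"] > 0.5).all()

    def test_matches_exhaustive_enumeration(self):
        attempted = {"a": 3, "b": 3, "c": 3}
        succeeded = {"a": 0, "b": 3, "c": 3}
        n_perm = 4000
        out = failure_randomness_test(attempted, succeeded,
                                      n_perm=n_perm, seed=5)
        exact = exact_failure_pvalues(attempted, succeeded)
        for row in out.itertuples(index=False):
            p = exact[row.protein]
            se = np.sqrt(p * (1 - p) / n_perm) + 1e-9
            assert abs(row.p_value - p) <= 3 * se + 2 / n_perm

    def test_seed_determinism(self):
        args = ({"a": 6, "b": 4}, {"a": 2, "b": 4})
        out1 = failure_randomness_test(*args, n_perm=200, seed=42)
        out2 = failure_randomness_test(*args, n_perm=200, seed=42)
        pd.testing.assert_frame_equal(out1, out2)

    def test_bh_monotone_in_p(self):
        out = failure_randomness_test(
            {c: 4 for c in "abcdef"},
            {"a": 0, "b": 1, "c": 2, "d": 3, "e": 4, "f": 4},
            n_perm=500, seed=9)
        df = out.sort_values("p_value")
        assert (df["fdr"].diff().dropna() >= -1e-12).all()

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            failure_randomness_test({"a": 0}, {"a": 0}, n_perm=10)
        with pytest.raises(ValueError):
            failure_randomness_test({"a": 2}, {"a": 3}, n_perm=10)
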