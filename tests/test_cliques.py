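"""Dual-threshold adjacency, clique enumeration and module merging."""

import numpy as np
import pandas as pd
import pytest

from bicordiff import (
    GeneModule,
    drop_isolated_nodes,
    dual_threshold_adjacency,
    enumerate_cliques,
    merge_cliques,
    threshold_grid,
)

from conftest import random_correlation_pair, ref_maximal_cliques


def adjacency_from_edges(n, edges, ids=None):
    ids = ids or [f"g{i}" for i in range(n)]
    arr = np.zeros((n, n), dtype=int)
    for i, j in edges:
        arr[i, j] = arr[j, i] = 1
    return pd.DataFrame(arr, index=ids, columns=ids)


class TestDualThresholdAdjacency:
    @pytest.mark.parametrize(
        "c1, c2, t1, t2, edge",
        [
            (0.8, 0.1, 0.76, 0.2, 1),    # strong then lost -> edge
            (0.8, 0.5, 0.76, 0.2, 0),    # coexpression not lost
            (0.5, 0.1, 0.76, 0.2, 0),    # never strong
            (-0.8, -0.1, 0.76, 0.2, 1),  # absolute values on both sides
            (0.76, 0.2, 0.76, 0.2, 1),   # comparisons are inclusive
        ],
    )
    def test_lost_coexpression_edges(self, c1, c2, t1, t2, edge):
        ids = ["a", "b"]
        C1 = pd.DataFrame([[1, c1], [c1, 1]], index=ids, columns=ids, dtype=float)
        C2 = pd.DataFrame([[1, c2], [c2, 1]], index=ids, columns=ids, dtype=float)
        assert dual_threshold_adjacency(C1, C2, t1, t2).loc["a", "b"] == edge

    def test_agrees_with_elementwise_scan(self, rng):
        C1, C2 = random_correlation_pair(rng, n_genes=9)
        t1, t2 = 0.5, 0.3
        adj = dual_threshold_adjacency(C1, C2, t1, t2)
        for g in C1.index:
            for h in C1.index:
                expected = int(
                    g != h
                    and abs(C1.loc[g, h]) >= t1
                    and abs(C2.loc[g, h]) <= t2
                )
                assert adj.loc[g, h] == expected

    def test_diagonal_zero_and_symmetric(self, rng):
        C1, C2 = random_correlation_pair(rng, n_genes=6)
        adj = dual_threshold_adjacency(C1, C2, 0.3, 0.5).to_numpy()
        assert not adj.diagonal().any()
        np.testing.assert_array_equal(adj, adj.T)

    def test_edge_set_antitone_in_t1_monotone_in_t2(self, rng):
        C1, C2 = random_correlation_pair(rng, n_genes=10)
        e = lambda t1, t2: dual_threshold_adjacency(C1, C2, t1, t2).to_numpy()
        base = e(0.5, 0.3)
        assert np.all(base | ~e(0.7, 0.3))   # raising t1 shrinks
        assert np.all(e(0.5, 0.5) | ~base)   # raising t2 grows

    def test_invalid_threshold_rejected(self, rng):
        C1, C2 = random_correlation_pair(rng, n_genes=3)
        with pytest.raises(ValueError):
            dual_threshold_adjacency(C1, C2, 1.5, 0.2)


class TestDropIsolated:
    def test_path_plus_isolated_node(self):
        A = adjacency_from_edges(3, [(0, 1)], ids=["a", "b", "c"])
        kept = drop_isolated_nodes(A)
        assert list(kept.index) == ["a", "b"]

    def test_complete_graph_unchanged(self):
        A = adjacency_from_edges(4, [(i, j) for i in range(4) for j in range(i + 1, 4)])
        pd.testing.assert_frame_equal(drop_isolated_nodes(A), A)

    def test_all_isolated_returns_empty_with_warning(self, caplog):
        A = adjacency_from_edges(3, [])
        with caplog.at_level("WARNING"):
            kept = drop_isolated_nodes(A)
        assert kept.empty and "isolated" in caplog.text

    def test_matches_degree_scan(self, rng):
        arr = (rng.uniform(size=(12, 12)) < 0.15).astype(int)
        arr = np.triu(arr, 1)
        arr = arr + arr.T
        A = pd.DataFrame(arr, index=[f"g{i}" for i in range(12)],
                         columns=[f"g{i}" for i in range(12)])
        kept = drop_isolated_nodes(A)
        expected = [g for g in A.index if A.loc[g].sum() > 0]
        assert list(kept.index) == expected


class TestEnumerateCliques:
    def test_complete_graph_single_maximal_clique(self):
        A = adjacency_from_edges(4, [(i, j) for i in range(4) for j in range(i + 1, 4)])
        assert enumerate_cliques(A, min_size=4) == [("g0", "g1", "g2", "g3")]

    def test_triangle_below_minimum_size(self):
        A = adjacency_from_edges(3, [(0, 1), (1, 2), (0, 2)])
        assert enumerate_cliques(A, min_size=4) == []

    def test_matches_brute_force_on_random_graphs(self, rng):
        ids = [f"g{i}" for i in range(10)]
        for _ in range(25):
            arr = (rng.uniform(size=(10, 10)) < 0.45).astype(int)
            arr = np.triu(arr, 1)
            arr = arr + arr.T
            A = pd.DataFrame(arr, index=ids, columns=ids)
            got = [tuple(int(g[1:]) for g in c) for c in enumerate_cliques(A, 3)]
            assert sorted(got) == ref_maximal_cliques(arr, 3)

    def test_no_maximal_clique_contains_another(self, rng):
        arr = (rng.uniform(size=(12, 12)) < 0.5).astype(int)
        arr = np.triu(arr, 1)
        arr = arr + arr.T
        ids = [f"g{i}" for i in range(12)]
        A = pd.DataFrame(arr, index=ids, columns=ids)
        cliques = [set(c) for c in enumerate_cliques(A, 2)]
        for c in cliques:
            assert not any(c < other for other in cliques)

    def test_all_cliques_mode_includes_subcliques(self):
        A = adjacency_from_edges(4, [(i, j) for i in range(4) for j in range(i + 1, 4)])
        every = enumerate_cliques(A, min_size=2, maximal=False)
        assert len(every) == 6 + 4 + 1  # all pairs, triangles, the 4-clique

    def test_deterministic_lexicographic_order(self):
        A = adjacency_from_edges(5, [(0, 1), (1, 2), (0, 2), (3, 4)])
        assert enumerate_cliques(A, 2) == [("g0", "g1", "g2"), ("g3", "g4")]


class TestMergeCliques:
    def test_seven_overlapping_cliques_union(self):
        # the eight-gene module reported for the rat type-2-diabetes study:
        # seven overlapping 4-gene cliques over 8 distinct genes
        cliques = [
            ("Tsc2", "Smarca4", "Sirt2", "Prkaca"),
            ("Tsc2", "Smarca4", "Sirt2", "Ctsd"),
            ("Sirt2", "Tsc2", "Ctsd", "Prkaca"),
            ("Polr2f", "Rpl9", "Prkaca", "Tsc2"),
            ("Pxmp3", "Rpl9", "Prkaca", "Tsc2"),
            ("Pxmp3", "Tsc2", "Prkaca", "Polr2f"),
            ("Polr2f", "Prkaca", "Smarca4", "Tsc2"),
        ]
        genes = sorted({g for c in cliques for g in c})
        pos = {g: i for i, g in enumerate(genes)}
        edges = {
            (pos[a], pos[b]) for c in cliques
            for a in c for b in c if pos[a] < pos[b]
        }
        A = adjacency_from_edges(len(genes), edges, ids=genes)
        module = merge_cliques(cliques, A)
        assert len(module.nodes) == 8

    def test_single_clique_is_fully_dense(self):
        A = adjacency_from_edges(4, [(i, j) for i in range(4) for j in range(i + 1, 4)])
        module = merge_cliques([("g0", "g1", "g2", "g3")], A)
        assert module.density == 1.0 and len(module.edges) == 6

    def test_two_disjoint_triangles(self):
        edges = [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]
        A = adjacency_from_edges(6, edges)
        module = merge_cliques([("g0", "g1", "g2"), ("g3", "g4", "g5")], A)
        assert len(module.nodes) == 6
        assert len(module.edges) == 6
        assert module.density == pytest.approx(6 / 15)

    def test_clique_with_missing_edge_rejected(self):
        A = adjacency_from_edges(3, [(0, 1), (1, 2)])  # g0-g2 absent
        with pytest.raises(ValueError):
            merge_cliques([("g0", "g1", "g2")], A)

    def test_empty_clique_set_gives_empty_module(self):
        A = adjacency_from_edges(3, [(0, 1)])
        module = merge_cliques([], A)
        assert module.nodes == () and module.density == 0.0

    def test_module_edge_endpoints_validated(self):
        with pytest.raises(ValueError):
            GeneModule(nodes=("a",), edges=(("a", "b"),), density=1.0)


def test_threshold_grid_reports_density_and_isolation(rng):
    C1, C2 = random_correlation_pair(rng, n_genes=8)
    diag = threshold_grid(C1, C2, [0.3, 0.6], [0.2, 0.5])
    assert len(diag) == 4
    assert set(diag.columns) == {
        "t1", "t2", "n_edges", "graph_density", "isolated_fraction"
    }
    for _, row in diag.iterrows():
        adj = dual_threshold_adjacency(C1, C2, row.t1, row.t2).to_numpy()
        assert row.n_edges == np.triu(adj, 1).sum()
        assert row.isolated_fraction == pytest.approx((adj.sum(1) == 0).mean())
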