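import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from mstknn import (
    adjusted_rand_index,
    annotate_edges,
    build_qnn_graph,
    cluster,
    component_threshold,
    correlation_distance,
    ensure_connected,
    initial_q,
    minimum_spanning_tree,
    neighbor_ranking,
    partition_forest,
)
from mstknn.graph_clustering import DistanceMatrix

from conftest import random_positive_matrix


def distance_from_points(points: np.ndarray) -> DistanceMatrix:
    """Euclidean toy distance oracle (any metric works for the graph ops)."""
    n = len(points)
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    d = d / (d.max() or 1.0)
    return DistanceMatrix(ids=[f"n{i}" for i in range(n)], d=d)


def brute_force_mst_weight(G: nx.Graph) -> float:
    """Minimum spanning-tree weight by exhaustive edge-subset enumeration."""
    nodes = list(G.nodes)
    edges = list(G.edges(data="weight"))
    best = math.inf
    for subset in itertools.combinations(edges, len(nodes) - 1):
        uf = nx.utils.UnionFind(nodes)
        ok = True
        for u, v, _ in subset:
            if uf[u] == uf[v]:
                ok = False
                break
            uf.union(u, v)
        if ok:
            best = min(best, sum(w for _, _, w in subset))
    return best


class TestCorrelationDistance:
    def test_duplicated_feature_distance_zero(self):
        X = random_positive_matrix(3, 6, seed=0)
        X.loc["f000"] = X.loc["f001"]
        D = correlation_distance(X)
        i, j = D.ids.index("f000"), D.ids.index("f001")
        assert D.d[i, j] == pytest.approx(0.0, abs=1e-12)

    def test_antimonotone_feature_distance_zero(self):
        X = random_positive_matrix(3, 6, seed=1)
        X.loc["f000"] = 100.0 - X.loc["f001"]
        D = correlation_distance(X)
        i, j = D.ids.index("f000"), D.ids.index("f001")
        assert D.d[i, j] == pytest.approx(0.0, abs=1e-12)

    def test_matches_rank_based_oracle(self):
        X = random_positive_matrix(4, 5, seed=7)
        D = correlation_distance(X)
        for i, fi in enumerate(D.ids):
            for j, fj in enumerate(D.ids):
                ri = rankdata(X.loc[fi].to_numpy())
                rj = rankdata(X.loc[fj].to_numpy())
                rho = np.corrcoef(ri, rj)[0, 1]
                assert D.d[i, j] == pytest.approx(1 - abs(rho), abs=1e-12)
        assert np.allclose(D.d, D.d.T)
        assert np.all(np.diag(D.d) == 0)

    def test_too_few_samples_rejected(self):
        X = random_positive_matrix(4, 2, seed=0)
        with pytest.raises(ValueError, match="samples"):
            correlation_distance(X)

    def test_constant_features_dropped(self):
        X = random_positive_matrix(4, 5, seed=3)
        X.loc["f000"] = 1.0
        D = correlation_distance(X)
        assert "f000" not in D.ids
        assert D.n == 3


class TestInitialQ:
    @pytest.mark.parametrize("n, expected", [(10, 3), (1372, 8), (3, 2), (2, 1)])
    def test_floor_log_plus_one(self, n, expected):
        assert initial_q(n) == expected

    def test_rejects_tiny(self):
        with pytest.raises(ValueError):
            initial_q(1)


class TestQnnGraph:
    def test_q_max_gives_complete_graph(self):
        D = distance_from_points(np.random.default_rng(0).normal(size=(6, 2)))
        G = build_qnn_graph(D, q=5)
        assert G.number_of_edges() == 15

    def test_three_node_enumeration(self):
        # d(0,1) < d(0,2) < d(1,2): with q=1, 0 picks 1, 1 picks 0, 2 picks 0
        d = np.array([[0.0, 0.1, 0.2], [0.1, 0.0, 0.9], [0.2, 0.9, 0.0]])
        D = DistanceMatrix(ids=["a", "b", "c"], d=d)
        G = build_qnn_graph(D, q=1)
        assert set(map(frozenset, G.edges)) == {frozenset({0, 1}), frozenset({0, 2})}

    def test_two_tight_pairs_disconnect_at_q1(self):
        points = np.array([[0.0, 0], [0.1, 0], [10.0, 0], [10.1, 0]])
        D = distance_from_points(points)
        G = build_qnn_graph(D, q=1)
        assert nx.number_connected_components(G) == 2

    def test_edges_match_rank_definition(self):
        D = distance_from_points(np.random.default_rng(2).normal(size=(8, 3)))
        f = neighbor_ranking(D)
        for q in (1, 2, 4):
            G = build_qnn_graph(D, q)
            for a, b in itertools.combinations(range(8), 2):
                expected = f[a, b] <= q or f[b, a] <= q
                assert G.has_edge(a, b) == expected


class TestEnsureConnected:
    def test_connected_at_q0_unchanged(self):
        D = distance_from_points(np.random.default_rng(1).normal(size=(10, 2)))
        G0 = build_qnn_graph(D, initial_q(10))
        if nx.is_connected(G0):
            _, q_used = ensure_connected(D)
            assert q_used == initial_q(10)

    def test_disconnected_pairs_escalate_to_two(self):
        points = np.array([[0.0, 0], [0.1, 0], [10.0, 0], [10.1, 0]])
        D = distance_from_points(points)
        G, q_used = ensure_connected(D, q0=1)
        assert q_used == 2
        assert nx.is_connected(G)

    def test_two_nodes(self):
        D = DistanceMatrix(ids=["a", "b"], d=np.array([[0.0, 0.5], [0.5, 0.0]]))
        G, q_used = ensure_connected(D, q0=1)
        assert q_used == 1
        assert G.number_of_edges() == 1


class TestNeighborRanking:
    def test_each_rank_used_once_per_node(self):
        D = distance_from_points(np.random.default_rng(3).normal(size=(7, 2)))
        f = neighbor_ranking(D)
        for a in range(7):
            ranks = sorted(f[a, b] for b in range(7) if b != a)
            assert ranks == list(range(1, 7))

    def test_matches_sorted_list_oracle(self):
        rng = np.random.default_rng(4)
        D = distance_from_points(rng.normal(size=(6, 2)))
        f = neighbor_ranking(D)
        for a in range(6):
            order = sorted(
                (b for b in range(6) if b != a), key=lambda b: (D.d[a, b], b)
            )
            for rank, b in enumerate(order, start=1):
                assert f[a, b] == rank

    def test_ties_break_toward_smaller_index(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = 0.5
        d[0, 2] = d[2, 0] = 0.5
        d[1, 2] = d[2, 1] = 0.9
        D = DistanceMatrix(ids=["a", "b", "c"], d=d)
        f = neighbor_ranking(D)
        assert f[0, 1] == 1 and f[0, 2] == 2


class TestMST:
    def test_tree_input_returned_unchanged(self):
        G = nx.Graph()
        G.add_edge(0, 1, weight=0.3)
        G.add_edge(1, 2, weight=0.1)
        T = minimum_spanning_tree(G)
        assert set(map(frozenset, T.edges)) == set(map(frozenset, G.edges))

    def test_matches_exhaustive_search_on_four_nodes(self):
        rng = np.random.default_rng(5)
        G = nx.complete_graph(4)
        for u, v in G.edges:
            G.edges[u, v]["weight"] = float(rng.uniform())
        T = minimum_spanning_tree(G)
        weight = sum(d["weight"] for _, _, d in T.edges(data=True))
        assert weight == pytest.approx(brute_force_mst_weight(G), abs=1e-12)

    def test_equal_weights_pick_lexicographic_tree(self):
        G = nx.complete_graph(4)
        for u, v in G.edges:
            G.edges[u, v]["weight"] = 1.0
        T = minimum_spanning_tree(G)
        assert set(map(tuple, sorted(map(sorted, T.edges)))) == {
            (0, 1), (0, 2), (0, 3)
        }

    def test_disconnected_input_rejected(self):
        G = nx.Graph()
        G.add_edge(0, 1, weight=0.1)
        G.add_node(2)
        with pytest.raises(ValueError, match="disconnected"):
            minimum_spanning_tree(G)


class TestAnnotate:
    def test_mutual_nearest_neighbors_get_p1(self):
        points = np.array([[0.0, 0], [0.1, 0], [5.0, 0]])
        D = distance_from_points(points)
        G, _ = ensure_connected(D, q0=1)
        T = minimum_spanning_tree(G)
        annotate_edges(T, neighbor_ranking(D))
        assert T.edges[0, 1]["p"] == 1

    def test_min_of_directed_ranks(self):
        f = np.zeros((2, 2), dtype=int)
        f[0, 1], f[1, 0] = 4, 2
        T = nx.Graph()
        T.add_edge(0, 1)
        annotate_edges(T, f)
        assert T.edges[0, 1]["p"] == 2

    def test_matches_full_sorted_list_oracle(self):
        rng = np.random.default_rng(6)
        D = distance_from_points(rng.normal(size=(6, 2)))
        G, _ = ensure_connected(D)
        T = minimum_spanning_tree(G)
        f = neighbor_ranking(D)
        annotate_edges(T, f)
        for a, b in T.edges:
            rank_ab = 1 + sum(
                1 for c in range(6)
                if c not in (a,) and (D.d[a, c], c) < (D.d[a, b], b)
            )
            rank_ba = 1 + sum(
                1 for c in range(6)
                if c not in (b,) and (D.d[b, c], c) < (D.d[b, a], a)
            )
            assert T.edges[a, b]["p"] == min(rank_ab, rank_ba)


class TestComponentThreshold:
    @pytest.mark.parametrize("n_c, expected", [(10, 2), (1372, 7), (4, 1), (2, 0)])
    def test_floor_log(self, n_c, expected):
        assert component_threshold(n_c) == expected

    def test_rejects_singleton(self):
        with pytest.raises(ValueError):
            component_threshold(1)


def annotated_path(p_values: list[int]) -> nx.Graph:
    """A path tree with given p annotations (weights irrelevant here)."""
    T = nx.Graph()
    for i, p in enumerate(p_values):
        T.add_edge(i, i + 1, weight=0.1, p=p)
    return T


class TestPartition:
    def test_small_component_terminal_regardless_of_p(self):
        T = annotated_path([5, 9])  # 3 nodes
        components, log = partition_forest(T)
        assert components == [frozenset({0, 1, 2})]
        assert log == [(3, "MINSIZE", 0)]

    def test_ten_node_component_removes_high_p_edge(self):
        # n_c = 10 -> t = 2; one edge with p = 3 is eliminated (C1), and
        # the two 5-node halves (all remaining p = 1) are terminal via C3
        T = annotated_path([1, 1, 1, 1, 3, 1, 1, 1, 1])
        components, log = partition_forest(T)
        assert log[0] == (10, "C1", 1)
        assert frozenset({0, 1, 2, 3, 4}) in components
        assert frozenset({5, 6, 7, 8, 9}) in components

    def test_all_p1_component_is_terminal_via_c3(self):
        T = annotated_path([1] * 9)
        components, log = partition_forest(T)
        assert components == [frozenset(range(10))]
        assert log == [(10, "C3", 0)]

    def test_pmax_equal_threshold_terminal_via_c3(self):
        T = annotated_path([1, 2, 1, 2, 1, 1, 2, 1, 1])  # t=2, p_max=2
        components, log = partition_forest(T)
        assert log == [(10, "C3", 0)]

    def test_c2_removes_pmax_edges(self):
        # 60 nodes -> t = 4; p_max = 3 in (1, 4) -> C2 removes p == 3
        p_values = [1] * 59
        p_values[10] = 3
        p_values[40] = 2
        T = annotated_path(p_values)
        components, log = partition_forest(T)
        assert log[0] == (60, "C2", 1)
        sizes = sorted(len(c) for c in components)
        # the p=2 edge then splits the 49-node piece (t=3, p_max=2 -> C2)
        assert sum(sizes) == 60

    def test_c2_alternative_policy_switchable(self):
        p_values = [1] * 59
        p_values[10] = 3
        p_values[40] = 2
        T = annotated_path(p_values)
        comps_default, log_default = partition_forest(T, c2_policy="pmax")
        comps_alt, log_alt = partition_forest(annotated_path(p_values), c2_policy="pmax-1")
        assert log_default[0] == (60, "C2", 1)  # removes the p=3 edge at index 10
        assert log_alt[0] == (60, "C2", 1)      # removes the p=2 edge at index 40
        assert frozenset(range(11)) in comps_default
        assert frozenset(range(41, 60)) in comps_alt

    def test_partition_is_lossless(self):
        rng = np.random.default_rng(8)
        for trial in range(10):
            n = int(rng.integers(5, 40))
            tree = nx.random_labeled_tree(n, seed=int(rng.integers(1 << 30)))
            for u, v in tree.edges:
                tree.edges[u, v]["p"] = int(rng.integers(1, 6))
            components, log = partition_forest(tree)
            all_nodes = sorted(n for c in components for n in c)
            assert all_nodes == list(range(n))
            assert len(log) >= len(components)


class TestEliminationRuleEquivalence:
    def test_p_annotation_reproduces_mutual_knn_rule(self):
        """An edge has p > k exactly when neither endpoint is in the
        other's k nearest neighbours — the original elimination rule."""
        rng = np.random.default_rng(9)
        for trial in range(20):
            n = int(rng.integers(5, 12))
            D = distance_from_points(rng.normal(size=(n, 2)))
            f = neighbor_ranking(D)
            G, _ = ensure_connected(D)
            T = minimum_spanning_tree(G)
            annotate_edges(T, f)
            for k in range(1, n):
                knn = {
                    a: set(
                        sorted(
                            (b for b in range(n) if b != a),
                            key=lambda b: (D.d[a, b], b),
                        )[:k]
                    )
                    for a in range(n)
                }
                for a, b in T.edges:
                    eliminate = (b not in knn[a]) and (a not in knn[b])
                    assert (T.edges[a, b]["p"] > k) == eliminate


class TestCluster:
    def test_duplicated_features_form_one_cluster(self):
        rng = np.random.default_rng(10)
        base = rng.lognormal(size=6)
        X = pd.DataFrame(
            [base * s for s in (1.0, 2.0, 0.5, 3.0)],
            index=["fA", "fB", "fC", "fD"],
            columns=[f"S{i}" for i in range(6)],
        )
        result = cluster(X)
        assert result.n_clusters == 1

    def test_two_planted_blocks_recovered_exactly(self):
        from mstknn import planted_expression

        ds = planted_expression(n_blocks=2, features_per_block=12, seed=0)
        result = cluster(ds.X)
        assert adjusted_rand_index(result.assignment, ds.labels) == 1.0

    def test_repeated_runs_identical(self):
        X = random_positive_matrix(25, 10, seed=12)
        r1 = cluster(X)
        r2 = cluster(X)
        assert r1.assignment == r2.assignment
        assert r1.split_log == r2.split_log

    def test_final_clusters_partition_features(self):
        X = random_positive_matrix(40, 9, seed=13)
        result = cluster(X)
        assert sorted(result.assignment) == sorted(X.index)
        sizes = [len(result.members(c)) for c in range(result.n_clusters)]
        assert sum(sizes) == 40

    def test_monotone_relabeling_leaves_clustering_unchanged(self):
        X = random_positive_matrix(20, 8, seed=14)
        r1 = cluster(X)
        r2 = cluster(np.log(X) * 3 + 7)
        assert r1.assignment == r2.assignment
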