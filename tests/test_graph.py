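"""Binary networks and topology metrics against brute-force oracles and
closed forms."""

import itertools

import numpy as np
import pytest

from mibrain.graph import (
    BinaryNetwork,
    HemisphereMap,
    interhemispheric_edge_count,
    node_metrics,
    proportional_threshold,
    rank_order_edges,
    threshold_sweep,
)
from mibrain.mi import MIMatrix
from mibrain.recording import MONTAGE_16


def brute_clustering(adj):
    """C_i = (edges among neighbours of i) / C(k_i, 2), counting literally."""
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k <= 1:
            continue
        e = sum(1 for a, b in itertools.combinations(nbrs, 2) if adj[a, b])
        out[i] = 2.0 * e / (k * (k - 1))
    return out


def brute_betweenness(adj):
    """Sum over unordered pairs {j,k} of sigma_jk(i)/sigma_jk by explicit
    enumeration of all shortest paths (BFS path counting)."""
    n = adj.shape[0]
    out = np.zeros(n)

    def all_shortest_paths(s, t):
        # BFS from s, collect every shortest s-t path as a node list
        from collections import deque

        dist = {s: 0}
        preds = {s: []}
        q = deque([s])
        while q:
            u = q.popleft()
            for v in range(n):
                if not adj[u, v]:
                    continue
                if v not in dist:
                    dist[v] = dist[u] + 1
                    preds[v] = [u]
                    q.append(v)
                elif dist[v] == dist[u] + 1:
                    preds[v].append(u)
        if t not in dist:
            return []
        paths = []

        def walk(v, acc):
            if v == s:
                paths.append([s] + acc[::-1])
                return
            for p in preds[v]:
                walk(p, acc + [v])

        walk(t, [])
        return paths

    for j, k in itertools.combinations(range(n), 2):
        paths = all_shortest_paths(j, k)
        if not paths:
            continue
        for i in range(n):
            if i in (j, k):
                continue
            through = sum(1 for p in paths if i in p)
            out[i] += through / len(paths)
    return out


def net_from_adjacency(adj, labels=None):
    adj = np.asarray(adj, dtype=bool)
    n = adj.shape[0]
    labels = labels or tuple(f"n{i}" for i in range(n))
    k = int(adj.sum()) // 2
    return BinaryNetwork(adjacency=adj, threshold_fraction=1.0, retained_edges=k,
                         channel_labels=labels)


def random_mi_matrix(n, seed, labels=None):
    rng = np.random.default_rng(seed)
    v = rng.random((n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    labels = labels or tuple(f"n{i:02d}" for i in range(n))
    return MIMatrix(values=v, per_epoch=v[None], channel_labels=labels)


class TestProportionalThreshold:
    def test_full_fraction_gives_complete_graph(self):
        net = proportional_threshold(random_mi_matrix(16, 0, MONTAGE_16), 1.0)
        assert net.retained_edges == 120
        assert net.adjacency.sum() == 240  # both triangles

    def test_twenty_percent_of_16_channels_keeps_24_edges(self):
        net = proportional_threshold(random_mi_matrix(16, 1, MONTAGE_16), 0.20)
        assert net.retained_edges == 24
        assert net.adjacency.sum() // 2 == 24

    def test_round_half_up(self):
        # 0.129 * 120 = 15.48 -> 15; 0.1292 -> 15.504 -> 16
        mi = random_mi_matrix(16, 2)
        assert proportional_threshold(mi, 0.129).retained_edges == 15
        assert proportional_threshold(mi, 0.1292).retained_edges == 16

    def test_nesting_across_grid(self):
        mi = random_mi_matrix(16, 3)
        prev = None
        for f in np.arange(0.10, 0.31, 0.01):
            net = proportional_threshold(mi, round(float(f), 2))
            edges = set(net.edge_list())
            if prev is not None:
                assert prev <= edges
            prev = edges

    def test_handshake_lemma(self):
        mi = random_mi_matrix(16, 4)
        for f in (0.1, 0.2, 0.3, 0.7):
            net = proportional_threshold(mi, f)
            assert net.degrees.sum() == 2 * net.retained_edges

    def test_tie_determinism(self):
        v = np.ones((6, 6)); np.fill_diagonal(v, 0)
        mi = MIMatrix(values=v, per_epoch=v[None], channel_labels=tuple("abcdef"))
        nets = [proportional_threshold(mi, 0.4).edge_list() for _ in range(3)]
        assert nets[0] == nets[1] == nets[2]

    @pytest.mark.parametrize("fraction", [0.0, -0.1, 1.5])
    def test_invalid_fraction_rejected(self, fraction):
        with pytest.raises(ValueError):
            proportional_threshold(random_mi_matrix(4, 5), fraction)


class TestClustering:
    def test_triangle_all_ones(self):
        adj = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]])
        m = node_metrics(net_from_adjacency(adj))
        assert np.allclose(m.clustering, 1.0)
        assert m.mean_clustering == 1.0

    def test_star_all_zero(self):
        adj = np.zeros((5, 5), dtype=bool)
        adj[0, 1:] = adj[1:, 0] = True
        m = node_metrics(net_from_adjacency(adj))
        assert np.allclose(m.clustering, 0.0)

    def test_degree_le_one_gets_zero(self):
        # path of two nodes: both degree 1
        adj = np.array([[0, 1], [1, 0]])
        assert np.allclose(node_metrics(net_from_adjacency(adj)).clustering, 0.0)

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for trial in range(30):
            p = rng.choice([0.15, 0.3, 0.5])
            adj = rng.random((16, 16)) < p
            adj = np.triu(adj, 1)
            adj = adj | adj.T
            m = node_metrics(net_from_adjacency(adj))
            assert m.clustering == pytest.approx(brute_clustering(adj), abs=1e-12)


class TestBetweenness:
    def test_path_centre_is_one(self):
        adj = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        m = node_metrics(net_from_adjacency(adj))
        assert m.betweenness == pytest.approx([0.0, 1.0, 0.0], abs=1e-12)

    def test_complete_graph_all_zero(self):
        adj = ~np.eye(6, dtype=bool)
        m = node_metrics(net_from_adjacency(adj))
        assert np.allclose(m.betweenness, 0.0)

    def test_star_centre_counts_leaf_pairs(self):
        adj = np.zeros((6, 6), dtype=bool)
        adj[0, 1:] = adj[1:, 0] = True
        m = node_metrics(net_from_adjacency(adj))
        assert m.betweenness[0] == pytest.approx(10.0)  # C(5,2)

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(1234)
        for trial in range(30):
            p = [0.15, 0.3, 0.5][trial % 3]
            adj = rng.random((16, 16)) < p
            adj = np.triu(adj, 1)
            adj = adj | adj.T
            m = node_metrics(net_from_adjacency(adj))
            assert m.betweenness == pytest.approx(brute_betweenness(adj), abs=1e-9)

    def test_disconnected_pairs_contribute_zero(self):
        # two disjoint edges: nobody is interior to any path
        adj = np.zeros((4, 4), dtype=bool)
        adj[0, 1] = adj[1, 0] = adj[2, 3] = adj[3, 2] = True
        m = node_metrics(net_from_adjacency(adj))
        assert np.allclose(m.betweenness, 0.0)


class TestHemisphereEdges:
    def test_empty_network_counts_zero(self):
        adj = np.zeros((16, 16), dtype=bool)
        assert interhemispheric_edge_count(net_from_adjacency(adj, MONTAGE_16)) == 0

    def test_complete_montage_graph_counts_64(self):
        adj = ~np.eye(16, dtype=bool)
        assert interhemispheric_edge_count(net_from_adjacency(adj, MONTAGE_16)) == 64

    def test_single_edges_by_definition(self):
        labels = MONTAGE_16
        i, j = labels.index("Fp1"), labels.index("Fp2")
        adj = np.zeros((16, 16), dtype=bool)
        adj[i, j] = adj[j, i] = True
        assert interhemispheric_edge_count(net_from_adjacency(adj, labels)) == 1
        adj[:] = False
        k = labels.index("F3")
        adj[i, k] = adj[k, i] = True
        assert interhemispheric_edge_count(net_from_adjacency(adj, labels)) == 0

    def test_unassigned_label_rejected(self):
        adj = np.zeros((2, 2), dtype=bool)
        net = net_from_adjacency(adj, ("Fp1", "Cz"))
        with pytest.raises(KeyError):
            interhemispheric_edge_count(net)

    def test_partition_conservation(self):
        # cross + left-internal + right-internal = retained
        hemi = HemisphereMap()
        mi = random_mi_matrix(16, 77, MONTAGE_16)
        for f in (0.1, 0.2, 0.3):
            net = proportional_threshold(mi, f)
            sides = [hemi.side(l) for l in net.channel_labels]
            cross = same_l = same_r = 0
            for i, j in net.edge_list():
                if sides[i] != sides[j]:
                    cross += 1
                elif sides[i] == "left":
                    same_l += 1
                else:
                    same_r += 1
            assert cross + same_l + same_r == net.retained_edges
            assert cross == interhemispheric_edge_count(net)


class TestRankOrder:
    def test_length_and_monotone(self):
        mi = random_mi_matrix(16, 9)
        ranked = rank_order_edges(mi)
        assert len(ranked) == 120
        values = [v for _, v in ranked]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_unique_maximum_first(self):
        mi = random_mi_matrix(16, 10, MONTAGE_16)
        i, j = MONTAGE_16.index("C3"), MONTAGE_16.index("C4")
        mi.values[i, j] = mi.values[j, i] = 10.0
        assert set(rank_order_edges(mi)[0][0]) == {"C3", "C4"}

    def test_all_ties_deterministic(self):
        v = np.ones((5, 5)); np.fill_diagonal(v, 0)
        mi = MIMatrix(values=v, per_epoch=v[None], channel_labels=tuple("abcde"))
        assert rank_order_edges(mi) == rank_order_edges(mi)


class TestThresholdSweep:
    def test_default_grid_has_21_records(self):
        records = threshold_sweep(random_mi_matrix(16, 11, MONTAGE_16))
        assert len(records) == 21
        assert records[0]["fraction"] == pytest.approx(0.10)
        assert records[-1]["fraction"] == pytest.approx(0.30)

    def test_single_full_fraction_matches_complete_graph(self):
        records = threshold_sweep(random_mi_matrix(16, 12, MONTAGE_16), [1.0])
        assert records[0]["network"].retained_edges == 120
        assert records[0]["interhemispheric_edges"] == 64

    def test_sweep_composes_single_threshold_ops(self):
        mi = random_mi_matrix(16, 13, MONTAGE_16)
        records = threshold_sweep(mi, [0.1, 0.2])
        for rec in records:
            single = proportional_threshold(mi, rec["fraction"])
            assert np.array_equal(single.adjacency, rec["network"].adjacency)
            assert rec["interhemispheric_edges"] == interhemispheric_edge_count(single)
            assert rec["mean_clustering"] == pytest.approx(
                node_metrics(single).mean_clustering
            )

    def test_unsorted_fractions_rejected(self):
        with pytest.raises(ValueError):
            threshold_sweep(random_mi_matrix(16, 14, MONTAGE_16), [0.3, 0.1])

    def test_mean_clustering_rises_with_threshold_on_average(self):
        # denser proportional networks are more clustered as a trend
        lows, highs = [], []
        for seed in range(20):
            mi = random_mi_matrix(16, 100 + seed, MONTAGE_16)
            lows.append(node_metrics(proportional_threshold(mi, 0.10)).mean_clustering)
            highs.append(node_metrics(proportional_threshold(mi, 0.30)).mean_clustering)
        assert np.mean(highs) > np.mean(lows)
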