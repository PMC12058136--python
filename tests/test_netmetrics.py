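import networkx as nx
import numpy as np
import pytest

from morbnet.netmetrics import (
    compute_centralities,
    detect_communities,
    modularity,
    rank_bridges,
)
from morbnet.network import PairwiseNetwork

import _oracles


def net_from_edges(nodes, edges, weight=1.0):
    net = PairwiseNetwork(nodes=tuple(nodes))
    for e in edges:
        if len(e) == 3:
            net.add_edge(e[0], e[1], e[2])
        else:
            net.add_edge(e[0], e[1], weight)
    return net


@pytest.fixture
def two_triangles_bridge():
    return net_from_edges(
        "abcdef",
        [("a", "b"), ("a", "c"), ("b", "c"), ("d", "e"), ("d", "f"),
         ("e", "f"), ("c", "d")],
    )


class TestModularity:
    def test_two_triangles_value(self, two_triangles_bridge):
        part = {"a": 0, "b": 0, "c": 0, "d": 1, "e": 1, "f": 1}
        assert modularity(two_triangles_bridge, part) == pytest.approx(5 / 14, abs=1e-12)

    def test_single_community_zero(self, two_triangles_bridge):
        part = {n: 0 for n in "abcdef"}
        assert modularity(two_triangles_bridge, part) == pytest.approx(0.0, abs=1e-12)

    def test_weight_scale_invariance(self, two_triangles_bridge):
        part = {"a": 0, "b": 0, "c": 0, "d": 1, "e": 1, "f": 1}
        doubled = net_from_edges(
            "abcdef",
            [(u, v, 2 * w) for (u, v), (w, _) in two_triangles_bridge.edges.items()],
        )
        assert modularity(doubled, part) == pytest.approx(
            modularity(two_triangles_bridge, part), abs=1e-12
        )

    def test_matches_networkx_on_random_graphs(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            g = nx.gnp_random_graph(8, 0.4, seed=seed)
            net = PairwiseNetwork(nodes=tuple(str(v) for v in g.nodes))
            for u, v in g.edges:
                net.add_edge(str(u), str(v), float(rng.uniform(0.2, 2.0)))
            if net.n_edges == 0:
                continue
            part = detect_communities(net)
            groups = [set(c) for c in part.communities().values()]
            gg = nx.Graph()
            gg.add_nodes_from(net.nodes)
            for (u, v), (w, _) in net.edges.items():
                gg.add_edge(u, v, weight=abs(w))
            expected = nx.community.modularity(gg, groups, weight="weight")
            assert part.Q == pytest.approx(expected, abs=1e-12)


class TestDetectCommunities:
    def test_two_triangles_recovered(self, two_triangles_bridge):
        part = detect_communities(two_triangles_bridge)
        assert sorted(map(sorted, part.communities().values())) == [
            ["a", "b", "c"], ["d", "e", "f"]
        ]
        assert part.Q == pytest.approx(5 / 14, abs=1e-12)

    def test_two_triangles_is_global_optimum(self, two_triangles_bridge):
        # exhaustive search over all 203 partitions of 6 nodes
        edges = [((u, v), abs(w)) for (u, v), (w, _) in
                 two_triangles_bridge.edges.items()]
        best_q = max(
            _oracles.brute_modularity(edges, p)
            for p in _oracles.set_partitions(list("abcdef"))
        )
        assert detect_communities(two_triangles_bridge).Q == pytest.approx(
            best_q, abs=1e-12
        )

    def test_edgeless_graph_all_singletons(self):
        net = PairwiseNetwork(nodes=tuple("abcde"))
        part = detect_communities(net)
        assert part.n_communities == 5
        assert part.Q == 0.0
        assert part.merge_history == []

    def test_single_clique_one_community(self):
        net = net_from_edges("abcd", [(u, v) for u in "abcd" for v in "abcd" if u < v])
        part = detect_communities(net)
        assert part.n_communities == 1

    def test_never_below_singleton_partition(self):
        for seed in range(15):
            rng = np.random.default_rng(seed)
            g = nx.gnp_random_graph(9, 0.3, seed=100 + seed)
            net = PairwiseNetwork(nodes=tuple(str(v) for v in g.nodes))
            for u, v in g.edges:
                net.add_edge(str(u), str(v), float(rng.uniform(0.1, 1.0)))
            if net.n_edges == 0:
                continue
            part = detect_communities(net)
            singletons = {n: i for i, n in enumerate(net.nodes)}
            assert part.Q >= modularity(net, singletons) - 1e-12

    def test_deterministic(self, two_triangles_bridge):
        a = detect_communities(two_triangles_bridge)
        b = detect_communities(two_triangles_bridge)
        assert a.assignment == b.assignment and a.merge_history == b.merge_history

    def test_isolates_are_singletons(self):
        net = net_from_edges("abcd", [("a", "b")])
        part = detect_communities(net)
        comms = part.communities()
        assert {frozenset(c) for c in comms.values()} == {
            frozenset("ab"), frozenset("c"), frozenset("d")
        }


class TestCentralities:
    def test_star_hand_values(self):
        net = net_from_edges(["c", "l1", "l2", "l3", "l4"],
                             [("c", l) for l in ("l1", "l2", "l3", "l4")])
        t = compute_centralities(net)
        assert t.loc["c", "degree"] == 4
        assert t.loc["c", "betweenness"] == pytest.approx(6.0)
        assert t.loc["c", "closeness"] == pytest.approx(1.0)
        assert t.loc["l1", "closeness"] == pytest.approx(4 / 7)

    def test_cycle_pagerank_uniform(self):
        net = net_from_edges("abcd", [("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])
        t = compute_centralities(net)
        assert np.allclose(t["pagerank"], 0.25, atol=1e-9)
        assert t["pagerank"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_path_eigenvector(self):
        net = net_from_edges("abc", [("a", "b"), ("b", "c")])
        t = compute_centralities(net)
        assert np.allclose(t["eigenvector"], [0.7071, 1.0, 0.7071], atol=5e-5)

    def test_brute_force_betweenness_closeness_small_graphs(self):
        for seed in range(25):
            g = nx.gnp_random_graph(int(np.random.default_rng(seed).integers(3, 8)),
                                    0.5, seed=seed)
            nodes = tuple(str(v) for v in g.nodes)
            net = net_from_edges(nodes, [(str(u), str(v)) for u, v in g.edges])
            t = compute_centralities(net)
            adj = {n: set() for n in nodes}
            for u, v in g.edges:
                adj[str(u)].add(str(v))
                adj[str(v)].add(str(u))
            bt = _oracles.brute_betweenness(adj, nodes)
            cl = _oracles.brute_closeness(adj, nodes)
            for n in nodes:
                assert t.loc[n, "betweenness"] == pytest.approx(bt[n], abs=1e-9)
                assert t.loc[n, "closeness"] == pytest.approx(cl[n], abs=1e-9)

    def test_pagerank_defining_system(self):
        rng = np.random.default_rng(3)
        g = nx.gnp_random_graph(7, 0.4, seed=3)
        nodes = tuple(str(v) for v in g.nodes)
        net = net_from_edges(nodes, [(str(u), str(v), float(rng.uniform(0.2, 2)))
                                     for u, v in g.edges])
        t = compute_centralities(net)
        pr = t["pagerank"].to_dict()
        adj_w = {n: {} for n in nodes}
        for (u, v), (w, _) in net.edges.items():
            adj_w[u][v] = abs(w)
            adj_w[v][u] = abs(w)
        assert _oracles.pagerank_residual(pr, adj_w, nodes) < 1e-8

    def test_relabeling_equivariance(self):
        rng = np.random.default_rng(5)
        g = nx.gnp_random_graph(6, 0.5, seed=5)
        nodes = tuple(str(v) for v in g.nodes)
        edges = [(str(u), str(v), float(rng.uniform(0.2, 2))) for u, v in g.edges]
        mapping = {n: f"X{n}" for n in nodes}
        t1 = compute_centralities(net_from_edges(nodes, edges))
        t2 = compute_centralities(
            net_from_edges([mapping[n] for n in nodes],
                           [(mapping[u], mapping[v], w) for u, v, w in edges])
        )
        for n in nodes:
            assert np.allclose(t1.loc[n].to_numpy(), t2.loc[mapping[n]].to_numpy(),
                               atol=1e-9)

    def test_isolate_scores(self):
        net = net_from_edges("abc", [("a", "b")])
        t = compute_centralities(net)
        assert t.loc["c", "degree"] == 0
        assert t.loc["c", "closeness"] == 0.0
        assert t.loc["c", "betweenness"] == 0.0

    def test_weighted_distances_used(self):
        # strong direct edge beats a weak one: path lengths are 1/|w|
        net = net_from_edges("abc", [("a", "b", 2.0), ("b", "c", 2.0), ("a", "c", 0.25)])
        t = compute_centralities(net)
        # direct a-c has length 4, a-b-c has length 1: b lies between
        assert t.loc["b", "betweenness"] == pytest.approx(1.0)

    def test_harmonic_closeness_mode(self):
        net = net_from_edges("abc", [("a", "b")])
        t = compute_centralities(net, closeness_mode="harmonic")
        assert t.loc["a", "closeness"] == pytest.approx(0.5)  # (1+0)/2


class TestRankBridges:
    def test_star_center_first(self):
        net = net_from_edges(["c", "l1", "l2", "l3", "l4"],
                             [("c", l) for l in ("l1", "l2", "l3", "l4")])
        ranked = rank_bridges(compute_centralities(net), top_k=1)
        assert list(ranked.index) == ["c"]

    def test_clique_tie_break_is_catalog_order(self):
        net = net_from_edges("dcba", [(u, v) for u in "abcd" for v in "abcd" if u < v])
        ranked = rank_bridges(compute_centralities(net))
        assert list(ranked.index) == ["d", "c", "b", "a"]  # catalog order of the net

    def test_unknown_metric_rejected(self):
        net = net_from_edges("ab", [("a", "b")])
        with pytest.raises(ValueError, match="metric"):
            rank_bridges(compute_centralities(net), metric="flux")
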