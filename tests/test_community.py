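import itertools
import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rindom import (
    Method,
    WalktrapConfig,
    cut_dendrogram,
    edge_betweenness,
    girvan_newman,
    walktrap,
    walktrap_distances,
)

from conftest import clique_pair_network, make_network, random_network


def enumerated_edge_betweenness(network):
    """Independent oracle: enumerate all shortest paths between all pairs
    and split each pair's unit of flow equally among them."""
    g = nx.Graph()
    g.add_nodes_from(range(network.n_vertices))
    g.add_edges_from(network.edges)
    scores = {e: 0.0 for e in network.edges}
    for s, t in itertools.combinations(range(network.n_vertices), 2):
        if not nx.has_path(g, s, t):
            continue
        paths = list(nx.all_shortest_paths(g, s, t))
        share = 1.0 / len(paths)
        for path in paths:
            for u, v in zip(path, path[1:]):
                scores[(u, v) if u < v else (v, u)] += share
    return scores


def groups(partition):
    return {frozenset(c) for c in partition.communities() if c}


class TestEdgeBetweenness:
    def test_path_graph_counts_pairs(self):
        net = make_network(3, [(0, 1), (1, 2)])
        assert edge_betweenness(net) == {(0, 1): 2.0, (1, 2): 2.0}

    def test_bridge_between_triangles_is_strict_maximum(self):
        net = make_network(
            6, [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5), (2, 3)]
        )
        scores = edge_betweenness(net)
        oracle = enumerated_edge_betweenness(net)
        for e, s in scores.items():
            assert s == pytest.approx(oracle[e], abs=1e-9)
        bridge = scores.pop((2, 3))
        assert bridge == pytest.approx(9.0)  # 3x3 cross pairs counted via it
        assert all(bridge > s for s in scores.values())

    def test_equal_shortest_paths_split_flow(self):
        # 4-cycle: each pair of opposite vertices has two shortest paths
        net = make_network(4, [(0, 1), (1, 2), (2, 3), (0, 3)])
        scores = edge_betweenness(net)
        assert all(s == pytest.approx(2.0) for s in scores.values())

    def test_disconnected_components_scored_independently(self):
        net = make_network(5, [(0, 1), (1, 2), (3, 4)])
        scores = edge_betweenness(net)
        assert scores[(3, 4)] == pytest.approx(1.0)
        assert scores[(0, 1)] == pytest.approx(2.0)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_matches_enumeration_oracle_on_random_graphs(self, seed):
        net = random_network(np.random.default_rng(seed))
        scores = edge_betweenness(net)
        oracle = enumerated_edge_betweenness(net)
        assert set(scores) == set(oracle)
        for e in scores:
            assert scores[e] == pytest.approx(oracle[e], abs=1e-9)


class TestGirvanNewman:
    def test_bridge_removed_first_and_cliques_recovered(self, bridged_cliques):
        dendro = girvan_newman(bridged_cliques)
        assert dendro.removals[0] == (0, 8)
        part = cut_dendrogram(dendro, 2)
        assert groups(part) == {frozenset(range(8)), frozenset(range(8, 16))}

    def test_removal_history_covers_all_edges(self, bridged_cliques):
        dendro = girvan_newman(bridged_cliques)
        assert len(dendro.removals) == bridged_cliques.n_edges
        counts = [c for _, _, c in dendro.snapshots]
        assert counts == sorted(counts)  # components never decrease

    def test_edgeless_network_is_already_split(self):
        net = make_network(5, [])
        dendro = girvan_newman(net)
        assert dendro.removals == []
        assert cut_dendrogram(dendro, 5).n_communities == 5

    def test_early_stop_matches_full_run(self, bridged_cliques):
        full = girvan_newman(bridged_cliques)
        partial = girvan_newman(bridged_cliques, stop_at_components=2)
        assert not partial.complete
        assert np.array_equal(partial.cut(2).labels, full.cut(2).labels)
        with pytest.raises(ValueError):
            partial.cut(5)

    def test_deterministic(self, bridged_cliques):
        d1 = girvan_newman(bridged_cliques)
        d2 = girvan_newman(bridged_cliques)
        assert d1.removals == d2.removals

    def test_nested_partitions_along_cut_levels(self):
        rng = np.random.default_rng(3)
        net = random_network(rng, max_n=12, p=0.4)
        dendro = girvan_newman(net)
        for k in range(1, net.n_vertices):
            coarse = dendro.cut(k).labels
            fine = dendro.cut(k + 1).labels
            # each fine community maps into exactly one coarse community
            for c in np.unique(fine):
                assert len(np.unique(coarse[fine == c])) == 1


class TestWalktrapDistances:
    def test_disjoint_components_at_infinite_distance(self):
        net = make_network(4, [(0, 1), (2, 3)])
        prof = walktrap_distances(net, WalktrapConfig(steps=3))
        assert math.isinf(prof.distance(0, 2))
        assert prof.distance(0, 1) < math.inf

    def test_single_edge_two_step_profiles_have_strict_parity(self):
        # with t-step powers of the degree-normalised adjacency (no
        # self-loops) the walk alternates endpoints, so the two profiles are
        # orthogonal: r^2 = 1^2/1 + 1^2/1 = 2
        net = make_network(2, [(0, 1)])
        prof = walktrap_distances(net, WalktrapConfig(steps=2))
        assert np.allclose(prof.profiles, [[1, 0], [0, 1]])
        assert prof.distance(0, 1) == pytest.approx(math.sqrt(2.0))
        # the pair is still the only possible merge
        assert walktrap(net, WalktrapConfig(steps=2)).cut(1).n_communities == 1

    def test_planted_cliques_separate_in_walk_distance(self):
        net = clique_pair_network(10)
        prof = walktrap_distances(net, WalktrapConfig(steps=4))
        intra = [
            prof.distance(i, j)
            for base in (0, 10)
            for i, j in itertools.combinations(range(base, base + 10), 2)
        ]
        inter = [
            prof.distance(i, j) for i in range(10) for j in range(10, 20)
        ]
        assert max(intra) < min(inter)


class TestWalktrap:
    @pytest.mark.parametrize("steps", range(3, 11))
    def test_recovers_bridged_cliques(self, bridged_cliques, steps):
        dendro = walktrap(bridged_cliques, WalktrapConfig(steps=steps))
        part = cut_dendrogram(dendro, 2)
        assert groups(part) == {frozenset(range(8)), frozenset(range(8, 16))}

    def test_complete_graph_cut_at_n_gives_singletons(self):
        net = make_network(5, itertools.combinations(range(5), 2))
        dendro = walktrap(net, WalktrapConfig(steps=4))
        assert cut_dendrogram(dendro, 5).n_communities == 5
        assert cut_dendrogram(dendro, 1).n_communities == 1

    def test_components_never_merge(self):
        net = make_network(6, [(0, 1), (1, 2), (3, 4), (4, 5)])
        dendro = walktrap(net, WalktrapConfig(steps=3))
        part = cut_dendrogram(dendro, 1)  # 1 unreachable: floor is 2
        assert part.n_communities == 2
        assert groups(part) == {frozenset({0, 1, 2}), frozenset({3, 4, 5})}

    def test_isolated_vertices_stay_singletons(self):
        net = make_network(4, [(0, 1)])
        dendro = walktrap(net, WalktrapConfig(steps=2))
        part = cut_dendrogram(dendro, 1)
        assert part.n_communities == 3  # merged pair + two isolated singletons

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_nested_partitions_along_cut_levels(self, seed):
        net = random_network(np.random.default_rng(seed))
        dendro = walktrap(net, WalktrapConfig(steps=4))
        for k in range(1, net.n_vertices):
            coarse = dendro.cut(k).labels
            fine = dendro.cut(k + 1).labels
            for c in np.unique(fine):
                assert len(np.unique(coarse[fine == c])) == 1

    def test_deterministic(self, bridged_cliques):
        d1 = walktrap(bridged_cliques, WalktrapConfig(steps=5))
        d2 = walktrap(bridged_cliques, WalktrapConfig(steps=5))
        assert d1.merges == d2.merges


class TestCuts:
    def test_k_out_of_range_rejected(self, bridged_cliques):
        dendro = girvan_newman(bridged_cliques)
        with pytest.raises(ValueError):
            dendro.cut(0)
        with pytest.raises(ValueError):
            dendro.cut(17)

    def test_methods_tagged(self, bridged_cliques):
        assert girvan_newman(bridged_cliques).method is Method.EDGE_BETWEENNESS
        assert (
            walktrap(bridged_cliques, WalktrapConfig(steps=3)).method
            is Method.RANDOM_WALK
        )

    def test_walktrap_config_validation(self):
        with pytest.raises(ValueError):
            WalktrapConfig(steps=0)
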