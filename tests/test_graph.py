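import numpy as np
import pytest

from netcontrast.graph import (
    CommunityPartition,
    WeightedGraph,
    betweenness_centrality,
    global_efficiency,
    modularity,
    newman_communities,
    participation_coefficient,
    prepare_adjacency,
)

from _oracles import (
    oracle_best_partition,
    oracle_betweenness,
    oracle_global_efficiency,
    oracle_modularity,
    random_graph,
)


def graph_from_edges(n, edges):
    a = np.zeros((n, n))
    for i, j, w in edges:
        a[i, j] = a[j, i] = w
    return WeightedGraph(a)


TRIANGLES = graph_from_edges(6, [(0, 1, 1), (1, 2, 1), (0, 2, 1),
                                 (3, 4, 1), (4, 5, 1), (3, 5, 1)])


class TestPrepareAdjacency:
    def test_cost_one_is_absolute_value_identity(self):
        m = np.array([[0, -0.8, 0.5], [-0.8, 0, 0.1], [0.5, 0.1, 0]])
        g = prepare_adjacency(m, 1.0)
        np.testing.assert_array_equal(g.adjacency, np.abs(m))

    def test_negative_edge_preserved_by_absolute_value(self):
        m = np.array([[0, -0.8, 0.5], [-0.8, 0, 0.1], [0.5, 0.1, 0]])
        g = prepare_adjacency(m, 1.0)
        assert g.adjacency[0, 1] == 0.8

    def test_half_cost_keeps_top_half(self):
        w = [0.9, 0.8, 0.7, 0.3, 0.2, 0.1]
        m = np.zeros((4, 4))
        m[np.triu_indices(4, 1)] = w
        m = m + m.T
        g = prepare_adjacency(m, 0.5)
        kept = sorted(g.adjacency[np.triu_indices(4, 1)], reverse=True)
        assert kept[:3] == [0.9, 0.8, 0.7]
        assert kept[3:] == [0.0, 0.0, 0.0]

    @pytest.mark.parametrize("cost", [0.0, -0.1, 1.5])
    def test_invalid_cost_rejected(self, cost):
        with pytest.raises(ValueError, match="cost"):
            prepare_adjacency(np.zeros((3, 3)), cost)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(5)
        m = rng.normal(size=(20, 20))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        previous = None
        for cost in (0.1, 0.3, 0.5, 0.8, 1.0):
            edges = prepare_adjacency(m, cost).n_edges
            if previous is not None:
                assert edges >= previous
            previous = edges

    def test_tie_break_is_deterministic(self):
        m = np.zeros((4, 4))
        m[np.triu_indices(4, 1)] = 0.5  # all-tied weights
        m = m + m.T
        a1 = prepare_adjacency(m, 0.5).adjacency
        a2 = prepare_adjacency(m, 0.5).adjacency
        np.testing.assert_array_equal(a1, a2)
        # lexicographically earliest pairs survive
        assert a1[0, 1] == 0.5 and a1[0, 2] == 0.5 and a1[0, 3] == 0.5
        assert a1[1, 2] == 0.0


class TestParticipationCoefficient:
    def test_within_community_node_is_zero(self):
        g = graph_from_edges(3, [(0, 1, 1), (1, 2, 1)])
        pc = participation_coefficient(g, CommunityPartition([0, 0, 0]))
        np.testing.assert_allclose(pc, 0.0)

    def test_equal_two_community_split_is_half(self):
        g = graph_from_edges(4, [(0, 1, 1), (0, 2, 1)])
        pc = participation_coefficient(g, CommunityPartition([0, 0, 1, 1]))
        assert pc[0] == pytest.approx(0.5)

    def test_direct_sum_evaluation(self):
        # strengths (2, 1, 1) into 3 communities, k = 4
        g = graph_from_edges(5, [(0, 1, 2), (0, 2, 1), (0, 3, 1)])
        pc = participation_coefficient(
            g, CommunityPartition([0, 0, 1, 2, 2]))
        assert pc[0] == pytest.approx(1 - (0.25 + 0.0625 + 0.0625))

    def test_isolated_node_is_zero(self):
        g = graph_from_edges(3, [(0, 1, 1)])
        pc = participation_coefficient(g, CommunityPartition([0, 1, 1]))
        assert pc[2] == 0.0

    def test_bounds_on_random_graphs(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            n = int(rng.integers(4, 12))
            adj = random_graph(rng, n)
            labels = rng.integers(0, 3, size=n)
            m_comms = len(np.unique(labels))
            pc = participation_coefficient(
                WeightedGraph(adj), CommunityPartition(labels))
            assert np.all(pc >= -1e-12)
            assert np.all(pc <= 1 - 1 / m_comms + 1e-12)


class TestBetweenness:
    def test_path_center(self):
        g = graph_from_edges(3, [(0, 1, 1), (1, 2, 1)])
        np.testing.assert_allclose(betweenness_centrality(g), [0, 1, 0])

    def test_star_center(self):
        g = graph_from_edges(4, [(0, 1, 1), (0, 2, 1), (0, 3, 1)])
        np.testing.assert_allclose(betweenness_centrality(g), [3, 0, 0, 0])

    def test_four_cycle_split_paths(self):
        g = graph_from_edges(4, [(0, 1, 1), (1, 2, 1), (2, 3, 1), (3, 0, 1)])
        np.testing.assert_allclose(betweenness_centrality(g), [0.5] * 4)

    def test_edgeless_graph(self):
        g = WeightedGraph(np.zeros((4, 4)))
        np.testing.assert_array_equal(betweenness_centrality(g), np.zeros(4))


class TestGlobalEfficiency:
    def test_complete_unit_graph(self):
        g = WeightedGraph(np.ones((5, 5)) - np.eye(5))
        assert global_efficiency(g) == pytest.approx(1.0)

    def test_edgeless_graph(self):
        assert global_efficiency(WeightedGraph(np.zeros((4, 4)))) == 0.0

    def test_three_node_path(self):
        g = graph_from_edges(3, [(0, 1, 1), (1, 2, 1)])
        assert global_efficiency(g) == pytest.approx(5 / 6)

    def test_single_node_rejected(self):
        with pytest.raises(ValueError):
            global_efficiency(WeightedGraph(np.zeros((1, 1))))


class TestModularity:
    def test_single_community_is_zero(self):
        rng = np.random.default_rng(2)
        adj = random_graph(rng, 6)
        g = WeightedGraph(adj)
        q = modularity(g, CommunityPartition(np.zeros(6, dtype=int)))
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_disconnected_triangles_optimum(self):
        q = modularity(TRIANGLES, CommunityPartition([0, 0, 0, 1, 1, 1]))
        assert q == pytest.approx(0.5)

    def test_misassigned_partition_is_worse(self):
        q_bad = modularity(TRIANGLES, CommunityPartition([0, 0, 1, 1, 1, 1]))
        assert q_bad < 0.5

    def test_edgeless_graph_rejected(self):
        with pytest.raises(ValueError):
            modularity(WeightedGraph(np.zeros((3, 3))),
                       CommunityPartition([0, 0, 0]))


class TestNewmanCommunities:
    def test_disconnected_triangles_recovered(self):
        part = newman_communities(TRIANGLES)
        assert part.n_communities == 2
        labels = part.labels
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_complete_graph_single_community(self):
        g = WeightedGraph(np.ones((4, 4)) - np.eye(4))
        assert newman_communities(g).n_communities == 1

    def test_two_cliques_with_bridge(self):
        a = np.zeros((8, 8))
        for block in (range(4), range(4, 8)):
            for i in block:
                for j in block:
                    if i < j:
                        a[i, j] = a[j, i] = 1
        a[3, 4] = a[4, 3] = 1
        part = newman_communities(WeightedGraph(a))
        labels = part.labels
        assert part.n_communities == 2
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1

    def test_edgeless_graph_single_community_with_warning(self):
        g = WeightedGraph(np.zeros((5, 5)))
        with pytest.warns(UserWarning, match="no edges"):
            part = newman_communities(g)
        assert part.n_communities == 1

    def test_deterministic(self):
        rng = np.random.default_rng(9)
        adj = random_graph(rng, 10)
        g = WeightedGraph(adj)
        l1 = newman_communities(g).labels
        l2 = newman_communities(g).labels
        np.testing.assert_array_equal(l1, l2)


class TestPermutationEquivariance:
    def test_relabeling_permutes_metrics(self):
        rng = np.random.default_rng(17)
        adj = random_graph(rng, 8)
        perm = rng.permutation(8)
        adj_p = adj[np.ix_(perm, perm)]
        labels = rng.integers(0, 3, size=8)
        g, gp = WeightedGraph(adj), WeightedGraph(adj_p)
        part = CommunityPartition(labels)
        part_p = CommunityPartition(labels[perm])

        np.testing.assert_allclose(
            participation_coefficient(g, part)[perm],
            participation_coefficient(gp, part_p), atol=1e-12)
        np.testing.assert_allclose(
            betweenness_centrality(g)[perm],
            betweenness_centrality(gp), atol=1e-9)
        assert global_efficiency(g) == pytest.approx(global_efficiency(gp))
        q1 = modularity(g, newman_communities(g))
        q2 = modularity(gp, newman_communities(gp))
        assert q1 == pytest.approx(q2, abs=1e-9)


class TestOracleSpotChecks:
    """Light-weight oracle agreement; the full suite runs in acceptance."""

    def test_random_graphs_match_oracles(self):
        rng = np.random.default_rng(23)
        for _ in range(25):
            n = int(rng.integers(4, 8))
            adj = random_graph(rng, n, density=0.6)
            if adj.sum() == 0:
                continue
            g = WeightedGraph(adj)
            np.testing.assert_allclose(
                betweenness_centrality(g), oracle_betweenness(adj), atol=1e-9)
            assert global_efficiency(g) == pytest.approx(
                oracle_global_efficiency(adj), abs=1e-9)
            part = newman_communities(g)
            q = modularity(g, part)
            assert q == pytest.approx(
                oracle_modularity(adj, part.labels), abs=1e-9)
            q_best, _ = oracle_best_partition(adj)
            assert q == pytest.approx(q_best, abs=1e-9)
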