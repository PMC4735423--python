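"""Graph metrics against closed forms and independent oracles.

Oracles: networkx for clustering and efficiencies, a hand-written
Floyd-Warshall for distances, a direct double-sum for the modularity of
a given partition, and exhaustive partition enumeration for the optimum.
"""

import networkx as nx
import numpy as np
import pytest

from structconn import (
    clustering,
    density_grid,
    global_efficiency,
    local_efficiency,
    modularity,
    quality_of,
    shortest_path_matrix,
    threshold_to_density,
    topology_profile,
)
from structconn.metrics import (
    ModularityError,
    Partition,
    exhaustive_modularity,
)

from conftest import graph_from_edges, random_graph


def to_nx(g):
    return nx.from_numpy_array(np.asarray(g.adjacency))


def floyd_warshall_oracle(A):
    n = A.shape[0]
    d = np.where(A > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def modularity_double_sum(g, labels):
    """Direct elementwise evaluation of Q = 1/2m sum_ij (A_ij - k_i k_j/2m) d(g_i,g_j)."""
    A = np.asarray(g.adjacency, dtype=float)
    k = A.sum(axis=1)
    m2 = A.sum()
    q = 0.0
    n = A.shape[0]
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += A[i, j] - k[i] * k[j] / m2
    return q / m2


class TestClosedForms:
    def test_complete_graph_limits(self, complete5):
        """Fully connected network: all distances are one, so both
        efficiencies and every clustering coefficient are exactly 1, and
        no partition beats the trivial one (optimal Q = 0)."""
        assert global_efficiency(complete5) == pytest.approx(1.0)
        assert local_efficiency(complete5) == pytest.approx(1.0)
        c_node, c_mean = clustering(complete5)
        assert np.allclose(c_node, 1.0)
        q, _ = modularity(complete5)
        assert q == pytest.approx(0.0, abs=1e-12)
        q_opt, _ = exhaustive_modularity(complete5)
        assert q_opt == pytest.approx(0.0, abs=1e-12)

    def test_path3(self, path3):
        # E_glob(P3) = (1/6)(1+1+1+1+1/2+1/2) = 5/6
        assert global_efficiency(path3) == pytest.approx(5 / 6)
        assert local_efficiency(path3) == 0.0
        d = shortest_path_matrix(path3)
        assert d[0, 2] == 2

    def test_star_graph_has_no_triangles(self):
        g = graph_from_edges(5, [(0, i) for i in range(1, 5)])
        c_node, c_mean = clustering(g)
        assert np.all(c_node == 0)

    def test_chorded_square_clustering(self):
        # edges 12,23,34,41,13 -> C = (2/3, 1, 2/3, 1), mean 5/6
        g = graph_from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0), (0, 2)])
        c_node, c_mean = clustering(g)
        assert np.allclose(c_node, [2 / 3, 1.0, 2 / 3, 1.0])
        assert c_mean == pytest.approx(5 / 6)

    def test_two_triangles_modularity_and_efficiency(self, two_triangles):
        q, part = modularity(two_triangles)
        assert q == pytest.approx(0.5)
        assert part.n_communities == 2
        q_opt, _ = exhaustive_modularity(two_triangles)
        assert q_opt == pytest.approx(0.5)
        assert local_efficiency(two_triangles) == pytest.approx(1.0)

    def test_all_in_one_partition_scores_zero(self, rng):
        for _ in range(5):
            g = random_graph(7, 0.4, rng)
            assert quality_of(g, np.zeros(7, dtype=int)) == pytest.approx(0.0, abs=1e-12)

    def test_disconnected_pair_infinite_distance(self):
        g = graph_from_edges(4, [(0, 1), (2, 3)])
        d = shortest_path_matrix(g)
        assert np.isinf(d[0, 2])

    def test_edgeless_graph_contracts(self):
        g = graph_from_edges(4, [])
        assert global_efficiency(g) == 0.0
        assert local_efficiency(g) == 0.0
        with pytest.raises(ModularityError):
            modularity(g)


class TestOracles:
    def test_clustering_matches_networkx(self, rng):
        for _ in range(60):
            g = random_graph(rng.integers(4, 13), rng.uniform(0.2, 0.7), rng)
            ours, _ = clustering(g)
            theirs = nx.clustering(to_nx(g))
            assert np.allclose(ours, [theirs[i] for i in range(g.n_nodes)])

    def test_distances_match_floyd_warshall(self, rng):
        for _ in range(40):
            g = random_graph(12, rng.uniform(0.1, 0.5), rng)
            assert np.array_equal(
                shortest_path_matrix(g), floyd_warshall_oracle(g.adjacency)
            )

    def test_efficiencies_match_networkx(self, rng):
        for _ in range(60):
            g = random_graph(rng.integers(4, 13), rng.uniform(0.2, 0.7), rng)
            G = to_nx(g)
            assert global_efficiency(g) == pytest.approx(nx.global_efficiency(G), abs=1e-12)
            assert local_efficiency(g) == pytest.approx(nx.local_efficiency(G), abs=1e-12)

    def test_quality_of_matches_double_sum(self, rng):
        for _ in range(40):
            n = int(rng.integers(4, 11))
            g = random_graph(n, 0.4, rng)
            labels = rng.integers(0, 3, size=n)
            assert quality_of(g, labels) == pytest.approx(
                modularity_double_sum(g, labels), abs=1e-12
            )

    def test_greedy_near_optimal_on_small_graphs(self, rng):
        """Greedy agglomeration reaches >= 90% of the exhaustive optimum
        on random graphs with up to 8 nodes (and never exceeds it)."""
        for _ in range(25):
            g = random_graph(int(rng.integers(4, 9)), rng.uniform(0.25, 0.6), rng)
            q_greedy, part = modularity(g)
            q_opt, _ = exhaustive_modularity(g)
            assert q_greedy <= q_opt + 1e-12
            assert q_greedy >= 0.9 * q_opt - 1e-12
            # the returned Q must be the score of the returned partition
            assert q_greedy == pytest.approx(quality_of(g, part), abs=1e-12)

    def test_greedy_exact_on_two_cliques(self):
        for k in (3, 4, 5):
            edges = [(i, j) for i in range(k) for j in range(i + 1, k)]
            edges += [(k + i, k + j) for i, j in edges]
            g = graph_from_edges(2 * k, edges)
            q_greedy, _ = modularity(g)
            q_opt, _ = exhaustive_modularity(g)
            assert q_greedy == pytest.approx(q_opt, abs=1e-12)
            assert q_greedy == pytest.approx(0.5)


class TestProperties:
    def test_adding_edge_never_decreases_global_efficiency(self, rng):
        for _ in range(20):
            g = random_graph(10, 0.3, rng)
            A = np.asarray(g.adjacency).copy()
            missing = np.argwhere(np.triu(A == 0, 1))
            if not missing.size:
                continue
            i, j = missing[rng.integers(len(missing))]
            A2 = A.copy()
            A2[i, j] = A2[j, i] = 1
            g2 = graph_from_edges(10, list(zip(*np.nonzero(np.triu(A2, 1)))))
            assert global_efficiency(g2) >= global_efficiency(g) - 1e-12

    def test_metrics_invariant_under_relabeling(self, rng):
        g = random_graph(10, 0.4, rng)
        perm = rng.permutation(10)
        A2 = np.asarray(g.adjacency)[np.ix_(perm, perm)]
        g2 = graph_from_edges(10, list(zip(*np.nonzero(np.triu(A2, 1)))))
        assert modularity(g)[0] == pytest.approx(modularity(g2)[0], abs=1e-12)
        assert global_efficiency(g) == pytest.approx(global_efficiency(g2))
        assert local_efficiency(g) == pytest.approx(local_efficiency(g2))
        c1 = np.sort(clustering(g)[0])
        c2 = np.sort(clustering(g2)[0])
        assert np.allclose(c1, c2)

    def test_greedy_nonnegative_with_components(self, rng):
        for _ in range(10):
            # two disjoint random blobs -> >= 2 components -> Q >= 0
            g1 = random_graph(5, 0.5, rng)
            A = np.zeros((10, 10), dtype=np.int8)
            A[:5, :5] = g1.adjacency
            g2 = random_graph(5, 0.5, rng)
            A[5:, 5:] = g2.adjacency
            g = graph_from_edges(10, list(zip(*np.nonzero(np.triu(A, 1)))))
            assert modularity(g)[0] >= 0


class TestTopologyProfile:
    def test_default_profile_has_twenty_points(self, rng):
        w = rng.random((20, 20))
        w = (w + w.T) / 2
        p = topology_profile(w, density_grid(), which=("Q", "C_mean"))
        assert p.densities.size == 20
        assert p["Q"].size == 20

    def test_deterministic_on_constant_weights(self):
        w = np.ones((12, 12))
        p1 = topology_profile(w, [0.2, 0.4], which=("Q", "C_mean", "E_glob"))
        p2 = topology_profile(w, [0.2, 0.4], which=("Q", "C_mean", "E_glob"))
        for met in p1.metrics:
            assert np.array_equal(p1[met], p2[met])

    def test_planted_blocks_beat_shuffled_labels(self, rng):
        """On a planted 2-block weight matrix thresholded at d=0.2, the
        found Q exceeds the quality of a shuffled block assignment and
        the planted partition outscores shuffled ones, 20/20 paired."""
        n = 20
        blocks = np.repeat([0, 1], n // 2)
        wins = 0
        for _ in range(20):
            noise = rng.normal(0, 0.3, (n, n))
            w = np.where(blocks[:, None] == blocks[None, :], 1.0, 0.0) + (noise + noise.T) / 2
            np.fill_diagonal(w, 0)
            g = threshold_to_density(w, 0.2)
            q_found = topology_profile(w, [0.2], which=("Q",))["Q"][0]
            q_shuffled = quality_of(g, rng.permutation(blocks))
            wins += (q_found > q_shuffled) and (
                quality_of(g, blocks) > q_shuffled
            )
        assert wins == 20
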