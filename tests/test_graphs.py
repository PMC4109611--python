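import itertools

import networkx as nx
import numpy as np
import pytest

import brainmi as bm
from brainmi import graphs
from tests.conftest import make_roi_table


class TestEuclidean:
    def test_three_four_five(self):
        rois = make_roi_table([(0, 0, 0), (3, 4, 0)], ["L", "L"])
        d = graphs.euclidean_distances(rois)
        assert d.d[0, 1] == pytest.approx(5.0)
        assert d.d[0, 0] == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 50, size=(10, 3))
        rois = make_roi_table(pts, ["L"] * 10)
        d = graphs.euclidean_distances(rois)
        for i in range(10):
            for j in range(10):
                expected = np.sqrt(((pts[i] - pts[j]) ** 2).sum())
                assert d.d[i, j] == pytest.approx(expected)


class TestDissimilarity:
    def test_reciprocal_and_missing_edges(self):
        w = np.array([[0, 4, 0], [4, 0, 2], [0, 2, 0]], dtype=float)
        conn = bm.StructuralConnectome(w, [0, 1, 2])
        lengths = graphs.dissimilarity_from_nof(conn)
        assert lengths[0, 1] == pytest.approx(0.25)
        assert lengths[1, 2] == pytest.approx(0.5)
        assert lengths[0, 2] == 0.0  # no edge, not an infinite-length edge

    def test_monotone_in_nof(self):
        for low, high in [(1, 2), (3, 10), (5, 100)]:
            assert 1 / high < 1 / low


class TestShortestPaths:
    def test_two_hop_beats_direct(self):
        # A-B 0.5, B-C 0.25, A-C 1.0 -> d(A,C) = 0.75 via B
        lengths = np.array([[0, 0.5, 1.0], [0.5, 0, 0.25], [1.0, 0.25, 0]])
        d = graphs.shortest_path_distances(lengths, np.arange(3))
        assert d.d[0, 2] == pytest.approx(0.75)

    def test_single_edge(self):
        lengths = np.array([[0, 0.3], [0.3, 0]])
        d = graphs.shortest_path_distances(lengths, np.arange(2))
        assert d.d[0, 1] == pytest.approx(0.3)

    def test_unreachable_is_infinite(self):
        lengths = np.zeros((3, 3))
        lengths[0, 1] = lengths[1, 0] = 1.0
        d = graphs.shortest_path_distances(lengths, np.arange(3))
        assert np.isinf(d.d[0, 2])

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(3)
        n = 8
        g = nx.gnp_random_graph(n, 0.5, seed=4)
        lengths = np.zeros((n, n))
        for a, b in g.edges:
            lengths[a, b] = lengths[b, a] = rng.uniform(0.1, 2.0)
        d = graphs.shortest_path_distances(lengths, np.arange(n))
        for a, b in itertools.combinations(range(n), 2):
            best = np.inf
            for path in nx.all_simple_paths(g, a, b):
                best = min(best, sum(lengths[u, v] for u, v in zip(path, path[1:])))
            assert d.d[a, b] == pytest.approx(best)

    def test_triangle_inequality(self):
        rois = bm.generate_roi_geometry(6, extent=80, rng_seed=5)
        conn = bm.generate_connectome(rois, density=0.5, rng_seed=5)
        d = graphs.connectome_distances(conn).d
        finite = np.where(np.isfinite(d), d, 1e9)
        n = d.shape[0]
        for a, b, c in itertools.permutations(range(n), 3):
            assert finite[a, c] <= finite[a, b] + finite[b, c] + 1e-12


@pytest.fixture(scope="module")
def world():
    rois = bm.generate_roi_geometry(12, extent=100, rng_seed=6)
    conn = bm.generate_connectome(rois, density=0.3, rng_seed=7)
    return rois, conn


class TestRewiring:

    def test_degree_sequence_and_weights_preserved(self, world):
        rois, conn = world
        rewired = graphs.rewire_connectome(conn, rois, n_swap_multiple=10, rng_seed=1)
        assert np.array_equal(
            (conn.weights > 0).sum(axis=0), (rewired.weights > 0).sum(axis=0)
        )
        for mat in (conn, rewired):
            mat.validate_hemispheres(rois)
        triu = np.triu_indices_from(conn.weights, 1)
        w_before = np.sort(conn.weights[triu][conn.weights[triu] > 0])
        w_after = np.sort(rewired.weights[triu][rewired.weights[triu] > 0])
        assert np.array_equal(w_before, w_after)

    def test_actually_rewires(self, world):
        rois, conn = world
        rewired = graphs.rewire_connectome(conn, rois, n_swap_multiple=10, rng_seed=1)
        assert not np.array_equal(conn.weights, rewired.weights)

    def test_zero_budget_is_identity(self, world):
        rois, conn = world
        rewired = graphs.rewire_connectome(conn, rois, n_swap_multiple=0, rng_seed=1)
        assert np.array_equal(conn.weights, rewired.weights)

    def test_star_graph_unchanged(self):
        # every double-edge swap in a star creates a multi-edge or self-loop
        pts = [(10, 0, 0), (20, 0, 0), (30, 0, 0), (40, 0, 0)]
        rois = make_roi_table(pts, ["L"] * 4)
        w = np.zeros((4, 4))
        for leaf, nof in zip((1, 2, 3), (2.0, 3.0, 4.0)):
            w[0, leaf] = w[leaf, 0] = nof
        conn = bm.StructuralConnectome(w, rois.roi_ids)
        rewired = graphs.rewire_connectome(conn, rois, n_swap_multiple=50, rng_seed=2)
        assert np.array_equal(rewired.weights, w)

    def test_deterministic_per_seed(self, world):
        rois, conn = world
        a = graphs.rewire_connectome(conn, rois, 10, rng_seed=9)
        b = graphs.rewire_connectome(conn, rois, 10, rng_seed=9)
        assert np.array_equal(a.weights, b.weights)


class TestRanking:
    def test_collinear_ordering(self):
        rois = make_roi_table([(10, 0, 0), (11, 0, 0), (12, 0, 0)], ["L"] * 3)
        ranking = graphs.rank_neighbors(graphs.euclidean_distances(rois), rois)
        assert list(ranking.order[0]) == [1, 2]
        assert list(ranking.order[1]) in ([0, 2], [0, 2])
        assert ranking.neighbor(0, 1) == 1

    def test_tie_broken_by_roi_id(self):
        rois = make_roi_table([(10, 0, 0), (10, 1, 0), (10, -1, 0)], ["L"] * 3)
        ranking = graphs.rank_neighbors(graphs.euclidean_distances(rois), rois)
        assert list(ranking.order[0]) == [1, 2]  # equidistant; lower id first

    def test_only_same_hemisphere(self, small_world, small_rankings):
        rois = small_world["rois"]
        for seed, order in small_rankings["euclidean"].order.items():
            hemi = rois.table.set_index("roi_id").loc[seed, "hemisphere"]
            assert set(order) == set(rois.hemisphere_ids(hemi)) - {seed}

    def test_distances_nondecreasing(self, small_rankings):
        for ranking in small_rankings.values():
            for seed, dists in ranking.distances.items():
                finite = dists[np.isfinite(dists)]
                assert (np.diff(finite) >= 0).all()

    def test_disconnected_roi_ranked_last(self):
        # ROI 2 has no fibers: infinite connectome distance from everyone
        rois = make_roi_table([(10, 0, 0), (20, 0, 0), (30, 0, 0)], ["L"] * 3)
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 5.0
        # rank via raw shortest paths (skip the connectivity guarantee of
        # the generator on purpose)
        d = graphs.shortest_path_distances(
            graphs.dissimilarity_from_nof(bm.StructuralConnectome(w, rois.roi_ids)),
            rois.roi_ids,
        )
        ranking = graphs.rank_neighbors(d, rois)
        assert ranking.order[0][-1] == 2
        assert ranking.order[1][-1] == 2


class TestSubsystem:
    def test_k1_and_full_hemisphere(self, small_world, small_rankings):
        rois = small_world["rois"]
        ranking = small_rankings["euclidean"]
        seed = int(rois.hemisphere_ids("L")[0])
        hemi = set(rois.hemisphere_ids("L"))
        sub1 = graphs.build_subsystem(ranking, seed, 1)
        assert sub1.members == (seed,)
        assert set(sub1.environment) == hemi - {seed}
        full = graphs.build_subsystem(ranking, seed, len(hemi))
        assert set(full.members) == hemi
        assert full.environment == ()

    def test_members_plus_environment_partition_hemisphere(
        self, small_world, small_rankings
    ):
        rois = small_world["rois"]
        ranking = small_rankings["euclidean"]
        hemi = set(rois.hemisphere_ids("L"))
        for seed in rois.hemisphere_ids("L"):
            for k in range(1, len(hemi) + 1):
                sub = graphs.build_subsystem(ranking, int(seed), k)
                assert len(sub.members) == k
                assert set(sub.members) | set(sub.environment) == hemi
                assert not set(sub.members) & set(sub.environment)

    def test_k_out_of_range(self, small_rankings):
        ranking = small_rankings["euclidean"]
        seed = next(iter(ranking.order))
        with pytest.raises(ValueError):
            graphs.build_subsystem(ranking, seed, 0)
        with pytest.raises(ValueError):
            graphs.build_subsystem(ranking, seed, len(ranking.order[seed]) + 2)


class TestEfficiency:
    def test_reciprocal_of_path_distance(self):
        lengths = np.array([[0, 0.5, 1.0], [0.5, 0, 0.25], [1.0, 0.25, 0]])
        d = graphs.shortest_path_distances(lengths, np.arange(3))
        assert graphs.long_range_efficiency(0, [2], d) == pytest.approx(1 / 0.75)

    def test_mean_of_inverse_distances(self):
        d = graphs.DistanceMatrix(
            "connectome",
            np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float),
            np.arange(3),
        )
        assert graphs.long_range_efficiency(0, [1, 2], d) == pytest.approx(0.75)

    def test_unreachable_contributes_zero(self):
        d = graphs.DistanceMatrix(
            "connectome",
            np.array([[0, np.inf], [np.inf, 0]]),
            np.arange(2),
        )
        assert graphs.long_range_efficiency(0, [1], d) == 0.0

    def test_empty_environment_fails(self):
        d = graphs.DistanceMatrix("euclidean", np.zeros((1, 1)), np.arange(1))
        with pytest.raises(ValueError):
            graphs.long_range_efficiency(0, [], d)
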