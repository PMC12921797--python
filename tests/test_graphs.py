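import numpy as np
import pytest

from ddnet.graphs import (NullModels, build_null_models, char_path_length,
                          detect_hubs, edge_betweenness, edge_importance,
                          lattice_surrogate, node_strength_bc,
                          random_surrogate, small_world_propensity,
                          threshold_proportional, weighted_clustering)

from conftest import random_weighted_graph


# ---------------------------------------------------------------- oracles

def onnela_clustering_oracle(adj):
    """Exhaustive triangle enumeration of the Onnela coefficient."""
    n = adj.shape[0]
    w = adj / adj.max()
    c = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(adj[i] > 0)
        k = len(nbrs)
        if k < 2:
            continue
        s = 0.0
        for j in nbrs:
            for h in nbrs:
                if j != h:
                    s += (w[i, j] * w[i, h] * w[j, h]) ** (1 / 3)
        c[i] = s / (k * (k - 1))
    return c


def floyd_path_oracle(adj):
    """All-pairs shortest paths on 1/w costs by Floyd–Warshall loops."""
    n = adj.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and adj[i, j] > 0:
                d[i, j] = 1.0 / adj[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def brute_betweenness_oracle(adj):
    """Node and edge betweenness by exhaustive simple-path enumeration."""
    n = adj.shape[0]
    node_bc = np.zeros(n)
    edge_bc = np.zeros((n, n))

    def all_paths(s, t):
        paths, stack = [], [(s, [s], 0.0)]
        while stack:
            u, path, cost = stack.pop()
            if u == t:
                paths.append((path, cost))
                continue
            for v in range(n):
                if adj[u, v] > 0 and v not in path:
                    stack.append((v, path + [v], cost + 1.0 / adj[u, v]))
        return paths

    for s in range(n):
        for t in range(s + 1, n):
            paths = all_paths(s, t)
            if not paths:
                continue
            best = min(c for _, c in paths)
            shortest = [p for p, c in paths if np.isclose(c, best)]
            sigma = len(shortest)
            for p in shortest:
                for v in p[1:-1]:
                    node_bc[v] += 1.0 / sigma
                for a, b in zip(p[:-1], p[1:]):
                    edge_bc[a, b] += 1.0 / sigma
                    edge_bc[b, a] += 1.0 / sigma
    node_bc /= (n - 1) * (n - 2) / 2
    edge_bc /= n * (n - 1) / 2
    return node_bc, edge_bc


# ----------------------------------------------------------- clustering

class TestClustering:
    def test_triangle_is_fully_clustered(self):
        adj = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        c, mean = weighted_clustering(adj)
        assert np.allclose(c, 1.0) and mean == pytest.approx(1.0)

    def test_star_has_no_triangles(self):
        adj = np.zeros((5, 5))
        adj[0, 1:] = adj[1:, 0] = 1.0
        c, mean = weighted_clustering(adj)
        assert np.allclose(c, 0.0) and mean == 0.0

    def test_four_node_graph_matches_enumeration_oracle(self):
        adj = np.zeros((4, 4))
        for (i, j), w in {(0, 1): 1.0, (0, 2): 0.5, (1, 2): 0.25,
                          (2, 3): 1.0}.items():
            adj[i, j] = adj[j, i] = w
        c, _ = weighted_clustering(adj)
        assert np.allclose(c, onnela_clustering_oracle(adj))

    def test_negative_weights_rejected(self):
        adj = np.array([[0, -1.0], [-1.0, 0]])
        with pytest.raises(ValueError, match="nonnegative"):
            weighted_clustering(adj)


class TestPathLength:
    def test_single_edge(self):
        adj = np.array([[0, 1.0], [1.0, 0]])
        l, unreachable = char_path_length(adj)
        assert l == pytest.approx(1.0) and unreachable == 0

    def test_three_node_path_hand_enumeration(self):
        adj = np.zeros((3, 3))
        adj[0, 1] = adj[1, 0] = 1.0
        adj[1, 2] = adj[2, 1] = 1.0
        l, _ = char_path_length(adj)
        assert l == pytest.approx(4 / 3)

    def test_complete_graph_equal_weights(self):
        w = 0.4
        adj = np.full((6, 6), w)
        np.fill_diagonal(adj, 0.0)
        l, _ = char_path_length(adj)
        assert l == pytest.approx(1 / w)

    def test_mostly_disconnected_raises(self):
        adj = np.zeros((6, 6))
        adj[0, 1] = adj[1, 0] = 1.0
        with pytest.raises(ValueError, match="unreachable"):
            char_path_length(adj)


# ---------------------------------------------------------- null models

class TestNullModels:
    def test_lattice_construction_is_idempotent(self, rng):
        adj = random_weighted_graph(rng, 12, density=0.5)
        latt = lattice_surrogate(adj)
        assert np.allclose(lattice_surrogate(latt), latt)

    def test_lattice_is_fixed_point_in_clustering(self, rng):
        adj = random_weighted_graph(rng, 14, density=0.6)
        latt = lattice_surrogate(adj)
        nulls = build_null_models(latt, n_random=5, seed=0)
        _, c_obs = weighted_clustering(latt)
        assert nulls.c_latt == pytest.approx(c_obs)

    def test_complete_equal_weight_graph_invariant(self):
        adj = np.full((8, 8), 0.5)
        np.fill_diagonal(adj, 0.0)
        nulls = build_null_models(adj, n_random=5, seed=1)
        _, c_obs = weighted_clustering(adj)
        l_obs, _ = char_path_length(adj)
        assert nulls.c_rand == pytest.approx(c_obs)
        assert nulls.l_rand == pytest.approx(l_obs)

    def test_surrogates_preserve_degree_and_weights(self, rng):
        adj = random_weighted_graph(rng, 12, density=0.4)
        surr = random_surrogate(adj, rng)
        assert np.allclose(np.sort((surr > 0).sum(0)),
                           np.sort((adj > 0).sum(0)))
        assert np.allclose(np.sort(surr[np.triu_indices(12, 1)]),
                           np.sort(adj[np.triu_indices(12, 1)]))

    def test_watts_strogatz_ordering_over_seeds(self):
        """C_latt ≥ C_obs ≥ C_rand should hold in ≥ 95 % of runs."""
        import networkx as nx
        ok = 0
        runs = 40
        for s in range(runs):
            g = nx.watts_strogatz_graph(30, 4, 0.1, seed=s)
            adj = nx.to_numpy_array(g) * np.random.default_rng(s).uniform(
                0.5, 1.0, (30, 30))
            adj = np.triu(adj, 1)
            adj = adj + adj.T
            nulls = build_null_models(adj, n_random=8, seed=s)
            _, c_obs = weighted_clustering(adj)
            ok += nulls.c_latt >= c_obs >= nulls.c_rand
        assert ok / runs >= 0.95

    def test_too_small_graph_rejected(self, rng):
        adj = np.array([[0, 1.0], [1.0, 0]])
        with pytest.raises(ValueError, match="4 nodes"):
            random_surrogate(adj, rng)


class TestSmallWorldPropensity:
    def test_ideal_small_world(self, rng):
        adj = random_weighted_graph(rng, 10, density=0.6)
        _, c_obs = weighted_clustering(adj)
        l_obs, _ = char_path_length(adj)
        nulls = NullModels(c_latt=c_obs, l_latt=l_obs + 1.0,
                           c_rand=c_obs - 0.2, l_rand=l_obs, n_nulls=0)
        res = small_world_propensity(adj, nulls=nulls)
        assert res.phi == pytest.approx(1.0)
        assert res.delta_c == 0.0 and res.delta_l == 0.0

    def test_maximal_deviation(self, rng):
        adj = random_weighted_graph(rng, 10, density=0.6)
        _, c_obs = weighted_clustering(adj)
        l_obs, _ = char_path_length(adj)
        nulls = NullModels(c_latt=c_obs + 0.2, l_latt=l_obs,
                           c_rand=c_obs, l_rand=l_obs - 1.0, n_nulls=0)
        res = small_world_propensity(adj, nulls=nulls)
        assert res.phi == pytest.approx(0.0)
        assert res.delta_c == 1.0 and res.delta_l == 1.0

    def test_phi_recomputable_from_deviations(self, rng):
        adj = random_weighted_graph(rng, 16, density=0.4)
        res = small_world_propensity(adj, n_random=10, seed=3)
        assert res.phi == pytest.approx(
            1 - np.sqrt((res.delta_c ** 2 + res.delta_l ** 2) / 2))
        assert 0 <= res.delta_c <= 1 and 0 <= res.delta_l <= 1

    def test_uniform_weight_scaling_leaves_swp_unchanged(self, rng):
        adj = random_weighted_graph(rng, 14, density=0.5)
        r1 = small_world_propensity(adj, n_random=10, seed=5)
        r2 = small_world_propensity(3.7 * adj, n_random=10, seed=5)
        assert r1.phi == pytest.approx(r2.phi)
        assert r1.delta_c == pytest.approx(r2.delta_c)
        assert r1.delta_l == pytest.approx(r2.delta_l)


class TestThresholdProportional:
    def test_density_is_respected(self, rng):
        adj = random_weighted_graph(rng, 10, density=1.0)
        out = threshold_proportional(adj, 0.3)
        iu = np.triu_indices(10, 1)
        assert (out[iu] > 0).mean() == pytest.approx(0.3, abs=0.05)
        assert np.all(out[out > 0] >= np.quantile(adj[iu], 0.7) - 1e-12)

    def test_full_density_is_identity(self, rng):
        adj = random_weighted_graph(rng, 8)
        assert np.allclose(threshold_proportional(adj, 1.0), adj)


# ------------------------------------------------- strength / betweenness

class TestNodeMetrics:
    def test_star_center_carries_all_paths(self):
        adj = np.zeros((5, 5))
        adj[0, 1:] = adj[1:, 0] = 1.0
        df = node_strength_bc(adj)
        assert df.bc_raw[0] == pytest.approx(1.0)
        assert np.allclose(df.bc_raw[1:], 0.0)

    def test_complete_graph_normalised_strength_is_one(self):
        adj = np.full((6, 6), 0.8)
        np.fill_diagonal(adj, 0.0)
        df = node_strength_bc(adj)
        assert np.allclose(df.strength_norm, 1.0)
        assert df.strength_norm.mean() == pytest.approx(1.0)

    def test_five_node_graph_matches_brute_force(self, rng):
        adj = random_weighted_graph(rng, 5, density=0.8)
        while (adj.sum(0) == 0).any():
            adj = random_weighted_graph(rng, 5, density=0.8)
        df = node_strength_bc(adj)
        bc_oracle, ebc_oracle = brute_betweenness_oracle(adj)
        assert np.allclose(df.bc_raw, bc_oracle)
        assert np.allclose(edge_betweenness(adj), ebc_oracle)

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ValueError, match="fewer than 3"):
            node_strength_bc(np.array([[0, 1.0], [1.0, 0]]))


class TestHubDetection:
    def test_single_outlier_node_is_the_only_hub(self):
        metric = np.tile([1.0, 1, 1, 1, 3], (3, 1))
        df = detect_hubs(metric)
        assert df.threshold[0] == pytest.approx(1.4 + np.sqrt(0.8))
        assert list(df.hub) == [False, False, False, False, True]

    def test_flat_profile_has_no_hubs(self):
        with pytest.warns(UserWarning, match="no hubs"):
            df = detect_hubs(np.ones((4, 6)))
        assert not df.hub.any()

    def test_translation_invariance(self, rng):
        m = rng.normal(size=(5, 8))
        h1 = detect_hubs(m).hub
        h2 = detect_hubs(m + 100.0).hub
        assert list(h1) == list(h2)


class TestEdgeImportance:
    def test_equal_edge_bc_yields_none(self):
        adj = np.zeros((3, 3))
        adj[0, 1] = adj[1, 0] = adj[1, 2] = adj[2, 1] = 1.0
        ebc = edge_betweenness(adj)
        df = edge_importance(np.stack([ebc, ebc]))
        assert not df.important.any()

    def test_bridge_between_cliques_is_flagged(self):
        n = 8
        adj = np.zeros((n, n))
        for grp in (range(4), range(4, 8)):
            for i in grp:
                for j in grp:
                    if i != j:
                        adj[i, j] = 1.0
        adj[3, 4] = adj[4, 3] = 1.0  # the bridge
        ebc = edge_betweenness(adj)
        df = edge_importance(np.stack([ebc, ebc]))
        flagged = df[df.important]
        assert len(flagged) == 1
        assert {flagged.iloc[0].node_a, flagged.iloc[0].node_b} == {"3", "4"}

    def test_subject_permutation_invariance(self, rng):
        stacks = np.stack([edge_betweenness(random_weighted_graph(rng, 6))
                           for _ in range(4)])
        df1 = edge_importance(stacks)
        df2 = edge_importance(stacks[::-1])
        assert np.allclose(df1.bc_edge_mean, df2.bc_edge_mean)
        assert list(df1.important) == list(df2.important)
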