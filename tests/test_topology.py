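import itertools

import networkx as nx
import numpy as np
import pytest

from klsnet.atlases import AAL116, DK68
from klsnet.topology import (
    BinaryGraph,
    binarize_at_sparsity,
    compute_topology_profile,
    density_curve,
    global_metrics,
    metric_auc,
    nodal_metrics,
    random_null_ensemble,
    smallworld_normalize,
    sparsity_grid,
)

from conftest import random_similarity


def graph_from_edges(n, edges):
    adj = np.zeros((n, n), dtype=np.uint8)
    for u, v in edges:
        adj[u, v] = adj[v, u] = 1
    labels = tuple(f"n{i}" for i in range(n))
    return BinaryGraph(labels=labels, adjacency=adj)


# --------------------------------------------------------------------------
# brute-force oracles (independent of the implementation under test)
# --------------------------------------------------------------------------

def floyd_warshall(adj):
    n = adj.shape[0]
    d = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def brute_metrics(adj):
    n = adj.shape[0]
    d = floyd_warshall(adj)
    # clustering
    cs = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k < 2:
            cs.append(0.0)
            continue
        links = sum(
            adj[u, v] for u, v in itertools.combinations(nbrs, 2)
        )
        cs.append(2.0 * links / (k * (k - 1)))
    cp = float(np.mean(cs))
    finite = [
        d[i, j] for i in range(n) for j in range(n)
        if i != j and np.isfinite(d[i, j])
    ]
    lp = float(np.mean(finite)) if finite else float("nan")
    eg = sum(
        1.0 / d[i, j] for i in range(n) for j in range(n)
        if i != j and np.isfinite(d[i, j])
    ) / (n * (n - 1))
    return cp, lp, eg, d


def brute_betweenness(adj):
    """Normalized betweenness by explicit enumeration of shortest paths."""
    n = adj.shape[0]
    d = floyd_warshall(adj)
    bc = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        if not np.isfinite(d[s, t]):
            continue
        # enumerate all shortest s-t paths by DFS limited to distance d
        paths = []

        def extend(path):
            u = path[-1]
            if u == t:
                paths.append(path)
                return
            if len(path) - 1 >= d[s, t]:
                return
            for v in range(n):
                if adj[u, v] and v not in path and d[s, v] == len(path):
                    extend(path + [v])

        extend([s])
        for p in paths:
            for v in p[1:-1]:
                bc[v] += 1.0 / len(paths)
    return bc / ((n - 1) * (n - 2) / 2.0)


# --------------------------------------------------------------------------


class TestSparsityGrid:
    def test_aal_grid(self):
        grid = sparsity_grid(AAL116)
        assert len(grid) == 26
        assert grid[0] == 0.05 and grid[-1] == 0.30

    def test_dk_grid(self):
        grid = sparsity_grid(DK68)
        assert len(grid) == 24
        assert grid[0] == 0.07

    def test_constant_step(self):
        for atlas in (AAL116, DK68):
            steps = np.diff(sparsity_grid(atlas))
            assert np.all(steps > 0)
            np.testing.assert_allclose(steps, 0.01, atol=1e-12)


class TestBinarize:
    def test_keeps_largest(self):
        mat = random_similarity(5, seed=1)
        g = binarize_at_sparsity(mat, 0.3)
        assert g.n_edges == 3
        iu = np.triu_indices(5, 1)
        w = mat.values[iu]
        top3 = set(np.argsort(-w)[:3])
        kept = {k for k in range(len(w)) if g.adjacency[iu[0][k], iu[1][k]]}
        assert kept == top3

    def test_complete_at_one(self):
        g = binarize_at_sparsity(random_similarity(5, seed=2), 1.0)
        assert g.n_edges == 10

    def test_edge_count_contract_across_grid(self):
        mat = random_similarity(116, seed=3)
        n_pairs = 116 * 115 / 2
        for s in sparsity_grid(AAL116):
            g = binarize_at_sparsity(mat, float(s))
            # round-half-up tie rule (documented deterministic choice)
            assert g.n_edges == int(np.floor(s * n_pairs + 0.5))

    def test_tie_determinism(self):
        v = np.full((4, 4), 0.5)
        np.fill_diagonal(v, 1.0)
        mat_cls = random_similarity(4, seed=0)
        mat_cls.values = v  # all weights tie
        runs = [binarize_at_sparsity(mat_cls, 0.5).adjacency for _ in range(3)]
        assert all(np.array_equal(runs[0], r) for r in runs)

    def test_empty_graph_warning(self):
        mat = random_similarity(5, seed=4)
        with pytest.warns(UserWarning):
            g = binarize_at_sparsity(mat, 0.01)
        assert g.n_edges == 0

    def test_invalid_sparsity(self):
        with pytest.raises(ValueError):
            binarize_at_sparsity(random_similarity(5, seed=5), 0.0)


class TestGlobalMetrics:
    def test_complete_k5(self):
        g = graph_from_edges(5, itertools.combinations(range(5), 2))
        m = global_metrics(g)
        assert m["Cp"] == 1.0 and m["Lp"] == 1.0
        assert m["Eg"] == 1.0 and m["Eloc"] == 1.0

    def test_path_p3(self):
        g = graph_from_edges(3, [(0, 1), (1, 2)])
        m = global_metrics(g)
        assert m["Lp"] == pytest.approx(4.0 / 3.0)
        assert m["Cp"] == 0.0

    def test_empty_graph(self):
        g = graph_from_edges(5, [])
        assert global_metrics(g)["Eg"] == 0.0

    def test_too_small(self):
        with pytest.raises(ValueError):
            global_metrics(graph_from_edges(2, [(0, 1)]))

    def test_eg_monotone_in_sparsity(self):
        mat = random_similarity(30, seed=6)
        egs = [
            global_metrics(binarize_at_sparsity(mat, s))["Eg"]
            for s in (0.1, 0.2, 0.3, 0.5)
        ]
        assert all(a <= b + 1e-12 for a, b in zip(egs, egs[1:]))


class TestNodalMetrics:
    def test_star_center(self):
        g = graph_from_edges(5, [(0, i) for i in range(1, 5)])
        nm = nodal_metrics(g)
        assert nm.loc["n0", "degree"] == 4
        assert nm.loc["n0", "bc"] == pytest.approx(1.0)

    def test_p3_betweenness(self):
        g = graph_from_edges(3, [(0, 1), (1, 2)])
        nm = nodal_metrics(g)
        assert nm.loc["n1", "bc"] == pytest.approx(1.0)
        assert nm.loc["n0", "bc"] == 0.0 and nm.loc["n2", "bc"] == 0.0

    def test_isolated_node(self):
        g = graph_from_edges(4, [(0, 1), (1, 2), (0, 2)])
        nm = nodal_metrics(g)
        assert nm.loc["n3", "degree"] == 0
        assert nm.loc["n3", "ne"] == 0.0
        assert nm.loc["n3", "nle"] == 0.0


class TestBruteForceOracle:
    """Exhaustive check over every isomorphism class with 3..6 nodes."""

    @pytest.fixture(scope="class")
    def atlas_graphs(self):
        graphs = [
            g for g in nx.graph_atlas_g()
            if 3 <= g.number_of_nodes() <= 6
        ]
        assert len(graphs) > 200
        return graphs

    def test_global_metrics_match(self, atlas_graphs):
        for ag in atlas_graphs:
            adj = nx.to_numpy_array(ag, dtype=np.uint8)
            g = graph_from_edges(adj.shape[0], [])
            g.adjacency = adj
            m = global_metrics(BinaryGraph(g.labels, adj))
            cp, lp, eg, _ = brute_metrics(adj)
            assert m["Cp"] == pytest.approx(cp, abs=1e-10)
            if np.isnan(lp):
                assert np.isnan(m["Lp"])
            else:
                assert m["Lp"] == pytest.approx(lp, abs=1e-10)
            assert m["Eg"] == pytest.approx(eg, abs=1e-10)

    def test_betweenness_matches(self, atlas_graphs):
        for ag in atlas_graphs:
            adj = nx.to_numpy_array(ag, dtype=np.uint8)
            nm = nodal_metrics(BinaryGraph(
                tuple(f"n{i}" for i in range(adj.shape[0])), adj
            ))
            expected = brute_betweenness(adj)
            np.testing.assert_allclose(nm["bc"].to_numpy(), expected, atol=1e-10)


class TestNullEnsemble:
    def test_k5_null_is_k5(self):
        g = graph_from_edges(5, itertools.combinations(range(5), 2))
        nulls = random_null_ensemble(g, 5, seed=0)
        for h in nulls:
            assert np.array_equal(h.adjacency, g.adjacency)

    def test_degree_sequence_preserved(self):
        mat = random_similarity(40, seed=7)
        g = binarize_at_sparsity(mat, 0.15)
        for h in random_null_ensemble(g, 10, seed=1):
            np.testing.assert_array_equal(
                h.adjacency.sum(0), g.adjacency.sum(0)
            )

    def test_ring_lattice_cp_drops(self):
        # C10 with 2 neighbors each side: Cp = 0.5; rewiring destroys it
        edges = []
        for i in range(10):
            edges.append((i, (i + 1) % 10))
            edges.append((i, (i + 2) % 10))
        g = graph_from_edges(10, edges)
        assert global_metrics(g)["Cp"] == pytest.approx(0.5)
        nulls = random_null_ensemble(g, 50, seed=2)
        mean_cp = np.mean([global_metrics(h)["Cp"] for h in nulls])
        assert mean_cp < 0.5

    def test_reproducible(self):
        g = binarize_at_sparsity(random_similarity(20, seed=8), 0.2)
        a = random_null_ensemble(g, 3, seed=5)
        b = random_null_ensemble(g, 3, seed=5)
        for x, y in zip(a, b):
            assert np.array_equal(x.adjacency, y.adjacency)

    def test_tiny_graph_copies(self):
        g = graph_from_edges(4, [(0, 1)])
        with pytest.warns(UserWarning):
            nulls = random_null_ensemble(g, 3, seed=0)
        assert all(np.array_equal(h.adjacency, g.adjacency) for h in nulls)


class TestSmallWorld:
    def test_identical_nulls_unity(self):
        g = binarize_at_sparsity(random_similarity(20, seed=9), 0.3)
        nulls = [BinaryGraph(g.labels, g.adjacency.copy()) for _ in range(5)]
        gamma, lam, sigma = smallworld_normalize(g, nulls)
        assert gamma == pytest.approx(1.0) and lam == pytest.approx(1.0)
        assert sigma == pytest.approx(1.0)

    def test_sigma_identity(self):
        g = binarize_at_sparsity(random_similarity(25, seed=10), 0.2)
        nulls = random_null_ensemble(g, 10, seed=3)
        gamma, lam, sigma = smallworld_normalize(g, nulls)
        assert sigma * lam == pytest.approx(gamma, abs=1e-12)

    def test_lattice_gamma_above_one(self):
        edges = []
        for i in range(20):
            for k in (1, 2, 3):
                edges.append((i, (i + k) % 20))
        g = graph_from_edges(20, edges)
        nulls = random_null_ensemble(g, 30, seed=4)
        gamma, _, _ = smallworld_normalize(g, nulls)
        assert gamma > 1.0


class TestMetricAuc:
    def test_constant_one(self):
        t = sparsity_grid(AAL116)
        assert metric_auc(np.ones(26), t) == pytest.approx(0.25)

    def test_trapezoid_pair(self):
        assert metric_auc(np.array([0.0, 2.0]), np.array([0.05, 0.06])) == (
            pytest.approx(0.01)
        )

    def test_linearity(self, rng):
        t = sparsity_grid(DK68)
        a = rng.random(24)
        b = rng.random(24)
        assert metric_auc(a + b, t) == pytest.approx(
            metric_auc(a, t) + metric_auc(b, t), abs=1e-12
        )

    def test_nan_dropped_with_warning(self):
        v = np.array([1.0, np.nan, 1.0])
        t = np.array([0.1, 0.2, 0.3])
        with pytest.warns(UserWarning):
            out = metric_auc(v, t)
        assert out == pytest.approx(0.2)

    def test_too_short(self):
        with pytest.raises(ValueError):
            metric_auc(np.array([1.0]), np.array([0.1]))


class TestDensityCurve:
    def test_extremes(self):
        mat = random_similarity(10, seed=11)
        lo = mat.offdiag_values().min()
        hi = mat.offdiag_values().max()
        assert density_curve(mat, np.array([lo / 2]))[0] == 1.0
        assert density_curve(mat, np.array([(1 + hi) / 2]))[0] == 0.0

    def test_count(self):
        mat = random_similarity(5, seed=12)
        w = mat.offdiag_values()
        frac = (w > 0.5).mean()
        assert density_curve(mat, np.array([0.5]))[0] == frac


class TestProfile:
    def test_profile_structure(self):
        mat = random_similarity(30, seed=13, labels=None)
        th = np.array([0.1, 0.2, 0.3])
        prof = compute_topology_profile(mat, thresholds=th, n_nulls=3, seed=0)
        assert list(prof.global_table.index) == [0.1, 0.2, 0.3]
        assert set(prof.auc) == {"Cp", "Lp", "Eg", "Eloc", "gamma", "lambda", "sigma"}
        assert len(prof.nodal_table) == 3 * 30
        # stored component identity: sigma = gamma / lambda
        gt = prof.global_table
        np.testing.assert_allclose(
            gt["sigma"], gt["gamma"] / gt["lambda"], atol=1e-12
        )
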