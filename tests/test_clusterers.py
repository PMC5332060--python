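import itertools

import numpy as np
import pytest

from srsc.clusterers import (
    NeighborGraph,
    build_neighbor_graph,
    constrained_gmm_fit,
    fcm_fit,
    fcm_memberships,
    gmm_fit,
    kmeans_fit,
    make_init,
    neighbor_average,
)


def _full_coords(shape):
    return np.argwhere(np.ones(shape, dtype=bool))


class TestNeighborGraph:
    def test_interior_voxel_has_26_neighbors(self):
        g = build_neighbor_graph(_full_coords((3, 3, 3)), (3, 3, 3))
        center = 13  # raster index of (1,1,1)
        assert len(g.neighbors(center)) == 26

    def test_corner_voxel_has_7_neighbors(self):
        g = build_neighbor_graph(_full_coords((3, 3, 3)), (3, 3, 3))
        assert len(g.neighbors(0)) == 7

    def test_matches_brute_force_chebyshev(self):
        rng = np.random.default_rng(0)
        mask = rng.uniform(size=(5, 5, 2)) > 0.4  # holes
        mask[0, 0, 0] = True  # keep nonempty
        coords = np.argwhere(mask)
        g = build_neighbor_graph(coords, (5, 5, 2))
        for i in range(len(coords)):
            expect = sorted(
                j
                for j in range(len(coords))
                if j != i and np.abs(coords[i] - coords[j]).max() == 1
            )
            assert sorted(g.neighbors(i).tolist()) == expect

    def test_symmetric_no_self_links(self):
        rng = np.random.default_rng(1)
        mask = rng.uniform(size=(4, 4, 3)) > 0.3
        mask[1, 1, 1] = True
        coords = np.argwhere(mask)
        g = build_neighbor_graph(coords, (4, 4, 3))
        adj = g.adjacency.toarray()
        assert np.array_equal(adj, adj.T)
        assert np.all(np.diag(adj) == 0)
        assert g.degrees.max() <= 26

    def test_duplicate_coords_rejected(self):
        coords = np.array([[0, 0, 0], [0, 0, 0]])
        with pytest.raises(ValueError, match="unique"):
            build_neighbor_graph(coords, (2, 2, 2))


class TestNeighborAverage:
    def test_constant_rows_unchanged(self):
        g = build_neighbor_graph(_full_coords((3, 3, 1)), (3, 3, 1))
        R = np.tile([0.3, 0.7], (9, 1))
        S = neighbor_average(R, g)
        assert np.allclose(S, R, atol=1e-12)

    def test_isolated_voxel_uniform(self):
        coords = np.array([[0, 0, 0], [5, 5, 5]])
        g = build_neighbor_graph(coords, (6, 6, 6))
        R = np.array([[1.0, 0.0], [0.0, 1.0]])
        S = neighbor_average(R, g)
        assert np.allclose(S, 0.5)

    def test_single_neighbor_swap(self):
        coords = np.array([[0, 0, 0], [1, 0, 0]])
        g = build_neighbor_graph(coords, (2, 1, 1))
        R = np.array([[1.0, 0.0], [0.2, 0.8]])
        S = neighbor_average(R, g)
        assert np.allclose(S, [[0.2, 0.8], [1.0, 0.0]], atol=1e-12)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(2)
        mask = rng.uniform(size=(4, 4, 4)) > 0.3
        mask[2, 2, 2] = True
        coords = np.argwhere(mask)
        g = build_neighbor_graph(coords, (4, 4, 4))
        R = rng.dirichlet(np.ones(3), size=len(coords))
        S = neighbor_average(R, g)
        assert np.abs(S.sum(axis=1) - 1.0).max() < 1e-9


class TestKMeans:
    def test_k_equals_n_zero_inertia(self):
        rng = np.random.default_rng(3)
        Y = rng.normal(0, 1, (6, 2))
        res = kmeans_fit(Y, K=6, n_restarts=3, seed=0)
        assert res.inertia == pytest.approx(0.0, abs=1e-20)
        assert len(np.unique(res.labels)) == 6

    def test_square_corners_matches_exhaustive(self):
        Y = np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 0.0], [10.0, 1.0]])
        res = kmeans_fit(Y, K=2, n_restarts=5, seed=0)
        best = min(
            _partition_cost(Y, labels)
            for labels in itertools.product(range(2), repeat=4)
            if len(set(labels)) == 2
        )
        assert res.inertia == pytest.approx(best, abs=1e-12)

    def test_duplicated_dataset_same_centroids(self):
        rng = np.random.default_rng(4)
        centers = np.array([[0.0, 0.0], [8.0, 0.0], [0.0, 8.0]])
        Y = np.vstack([c + rng.normal(0, 0.3, (10, 2)) for c in centers])
        a = kmeans_fit(Y, K=3, n_restarts=5, seed=1)
        b = kmeans_fit(np.vstack([Y, Y]), K=3, n_restarts=5, seed=1)
        assert np.allclose(
            np.sort(a.centroids, axis=0), np.sort(b.centroids, axis=0), atol=1e-9
        )

    @pytest.mark.parametrize("seed", range(6))
    def test_exhaustive_partition_optimum_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n, K = 10, 3
        Y = rng.normal(0, 1, (n, 2))
        res = kmeans_fit(Y, K=K, n_restarts=20, seed=seed)
        best = min(
            _partition_cost(Y, labels)
            for labels in itertools.product(range(K), repeat=n)
            if len(set(labels)) == K
        )
        assert res.inertia == pytest.approx(best, rel=1e-10)

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        Y = rng.normal(0, 1, (30, 3))
        a = kmeans_fit(Y, K=3, seed=7)
        b = kmeans_fit(Y, K=3, seed=7)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.centroids, b.centroids)


def _partition_cost(Y, labels):
    labels = np.asarray(labels)
    cost = 0.0
    for k in np.unique(labels):
        pts = Y[labels == k]
        cost += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return cost


class TestFCM:
    def test_point_at_centroid_crisp(self):
        cent = np.array([[0.0, 0.0], [5.0, 5.0]])
        U = fcm_memberships(np.array([[0.0, 0.0]]), cent, m=2.0)
        assert U[0].tolist() == [1.0, 0.0]

    @pytest.mark.parametrize("m", [1.5, 2.0, 3.0])
    def test_equidistant_point_half_half(self, m):
        cent = np.array([[-1.0, 0.0], [1.0, 0.0]])
        U = fcm_memberships(np.array([[0.0, 2.0]]), cent, m=m)
        assert np.allclose(U[0], [0.5, 0.5], atol=1e-12)

    def test_one_cycle_matches_formula(self):
        rng = np.random.default_rng(6)
        Y = rng.normal(0, 1, (6, 2))
        m = 2.0
        res = fcm_fit(Y, K=2, m=m, max_iter=500, seed=0)
        # brute-force evaluation of the membership formula at the returned
        # centroids
        U_expect = np.zeros((6, 2))
        for i in range(6):
            d = [np.linalg.norm(Y[i] - res.centroids[k]) ** 2 for k in range(2)]
            for k in range(2):
                U_expect[i, k] = 1.0 / sum(
                    (d[k] / d[j]) ** (1.0 / (m - 1.0)) for j in range(2)
                )
        assert np.abs(res.U - U_expect).max() < 1e-10

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(7)
        res = fcm_fit(rng.normal(0, 1, (40, 3)), K=3, seed=1)
        assert np.abs(res.U.sum(axis=1) - 1.0).max() < 1e-9

    def test_objective_nonincreasing(self):
        rng = np.random.default_rng(8)
        res = fcm_fit(rng.normal(0, 1, (60, 2)), K=3, seed=2)
        obj = np.array(res.objective)
        assert np.all(np.diff(obj) <= 1e-8)

    def test_m_must_exceed_one(self):
        with pytest.raises(ValueError, match="m must exceed 1"):
            fcm_fit(np.zeros((5, 1)), K=2, m=1.0)


class TestMakeInit:
    def test_deterministic(self):
        rng = np.random.default_rng(9)
        Y = rng.normal(0, 1, (40, 2))
        a = make_init(Y, 3, seed=5)
        b = make_init(Y, 3, seed=5)
        assert np.array_equal(a.means, b.means)
        assert np.array_equal(a.covariances, b.covariances)

    def test_k1_mean_is_global_mean(self):
        rng = np.random.default_rng(10)
        Y = rng.normal(3, 1, (25, 2))
        init = make_init(Y, 1, seed=0)
        assert np.allclose(init.means[0], Y.mean(axis=0), atol=1e-12)

    def test_separable_init_means_in_hulls(self):
        rng = np.random.default_rng(11)
        centers = np.array([[0.0, 0.0], [20.0, 0.0], [0.0, 20.0]])
        Y = np.vstack([c + rng.normal(0, 0.5, (20, 2)) for c in centers])
        init = make_init(Y, 3, seed=0)
        for mu in init.means:
            assert np.min(np.linalg.norm(centers - mu, axis=1)) < 2.0

    def test_random_strategy(self):
        rng = np.random.default_rng(12)
        Y = rng.normal(0, 1, (30, 2))
        init = make_init(Y, 2, strategy="random", seed=3)
        assert init.weights.sum() == pytest.approx(1.0, abs=1e-12)


class TestGMM:
    def test_separable_recovery(self):
        rng = np.random.default_rng(13)
        pts = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        Y = np.vstack([p + rng.normal(0, 0.01, (20, 2)) for p in pts])
        params, resp = gmm_fit(Y, 3, seed=0)
        # match each true center to its nearest recovered mean
        for p in pts:
            assert np.min(np.linalg.norm(params.means - p, axis=1)) < 0.05

    def test_loglik_nondecreasing(self):
        rng = np.random.default_rng(14)
        Y = np.vstack(
            [rng.normal(0, 1, (60, 2)), rng.normal(4, 1, (60, 2))]
        )
        _, resp = gmm_fit(Y, 2, seed=1)
        trace = np.array(resp.trace)
        assert np.all(np.diff(trace) >= -1e-8)

    def test_1d_mixture_recovery_with_grid_mle(self):
        rng = np.random.default_rng(15)
        n = 2000
        comp = rng.uniform(size=n) < 0.5
        x = np.where(comp, rng.normal(0, 1, n), rng.normal(6, 1, n))
        params, _ = gmm_fit(x[:, None], 2, seed=0)
        means = np.sort(params.means.ravel())
        assert abs(means[0] - 0.0) < 0.15
        assert abs(means[1] - 6.0) < 0.15
        # independent brute-force grid-search MLE (known unit SDs, 0.5 weight)
        grid = np.arange(-0.5, 0.51, 0.05)
        best, best_ll = None, -np.inf
        for m1 in grid:
            for m2 in grid + 6.0:
                ll = np.log(
                    0.5 * np.exp(-0.5 * (x - m1) ** 2)
                    + 0.5 * np.exp(-0.5 * (x - m2) ** 2)
                ).sum()
                if ll > best_ll:
                    best, best_ll = (m1, m2), ll
        assert abs(means[0] - best[0]) < 0.1
        assert abs(means[1] - best[1]) < 0.1

    def test_responsibilities_normalized(self):
        rng = np.random.default_rng(16)
        _, resp = gmm_fit(rng.normal(0, 1, (50, 2)), 3, seed=2)
        assert np.abs(resp.R.sum(axis=1) - 1.0).max() < 1e-9
        assert resp.R.min() >= 0.0


class TestConstrainedGMM:
    def test_empty_graph_reduces_to_gmm(self):
        rng = np.random.default_rng(17)
        Y = np.vstack([rng.normal(0, 1, (40, 2)), rng.normal(3, 1, (40, 2))])
        coords = _full_coords((80, 1, 1))
        init = make_init(Y, 2, seed=0)
        _, rc = constrained_gmm_fit(
            Y, NeighborGraph.empty(coords), 2, init=init, tol=1e-12, max_iter=60
        )
        _, rg = gmm_fit(Y, 2, init=init, tol=1e-12, max_iter=60)
        assert np.abs(rc.R - rg.R).max() < 1e-8

    def test_two_block_recovery(self):
        shape = (8, 2, 2)
        coords = _full_coords(shape)
        truth = (coords[:, 0] >= 4).astype(int)
        rng = np.random.default_rng(18)
        x = np.where(truth == 1, 5.0, 0.0) + rng.normal(0, 0.1, len(truth))
        g = build_neighbor_graph(coords, shape)
        params, resp = constrained_gmm_fit(x[:, None], g, 2, seed=0)
        labels = np.argmax(resp.R, axis=1)
        agree = max((labels == truth).mean(), (labels != truth).mean())
        assert agree == 1.0
        means = np.sort(params.means.ravel())
        assert abs(means[0] - 0.0) < 0.1
        assert abs(means[1] - 5.0) < 0.1

    def test_single_flip_smoothed_majority_of_seeds(self):
        shape = (8, 4, 4)
        coords = _full_coords(shape)
        truth = (coords[:, 0] >= 4).astype(int)
        flip = np.flatnonzero(
            (coords[:, 0] == 2) & (coords[:, 1] == 2) & (coords[:, 2] == 2)
        )[0]
        ref = np.flatnonzero(
            (coords[:, 0] == 1) & (coords[:, 1] == 2) & (coords[:, 2] == 2)
        )[0]
        g = build_neighbor_graph(coords, shape)
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = np.where(truth == 1, 5.0, 0.0) + rng.normal(0, 0.1, len(truth))
            x[flip] = 5.0 + rng.normal(0, 0.1)  # drawn from the other class
            init = make_init(x[:, None], 2, seed=seed)
            _, rc = constrained_gmm_fit(x[:, None], g, 2, init=init, seed=seed)
            _, rg = gmm_fit(x[:, None], 2, init=init, seed=seed)
            lc = np.argmax(rc.R, axis=1)
            lg = np.argmax(rg.R, axis=1)
            if lc[flip] == lc[ref] and lg[flip] != lg[ref]:
                wins += 1
        assert wins > 5

    def test_responsibilities_normalized(self):
        shape = (6, 4, 4)
        coords = _full_coords(shape)
        rng = np.random.default_rng(19)
        block = np.minimum(coords[:, 0] // 2, 2)
        Y = 3.0 * np.eye(3)[block][:, :2] + rng.normal(0, 0.4, (len(coords), 2))
        g = build_neighbor_graph(coords, shape)
        _, resp = constrained_gmm_fit(Y, g, 3, seed=3)
        assert np.abs(resp.R.sum(axis=1) - 1.0).max() < 1e-9

    def test_permutation_equivariance(self):
        shape = (6, 3, 2)
        coords = _full_coords(shape)
        rng = np.random.default_rng(20)
        Y = np.vstack(
            [rng.normal(0, 0.5, (18, 2)), rng.normal(4, 0.5, (18, 2))]
        )
        init = make_init(Y, 2, seed=0)
        g = build_neighbor_graph(coords, shape)
        _, base = constrained_gmm_fit(Y, g, 2, init=init, tol=1e-10, max_iter=40)

        perm = rng.permutation(len(coords))
        g_perm = build_neighbor_graph(coords[perm], shape)
        _, permuted = constrained_gmm_fit(
            Y[perm], g_perm, 2, init=init, tol=1e-10, max_iter=40
        )
        assert np.abs(permuted.R - base.R[perm]).max() < 1e-8

    def test_requires_graph(self):
        with pytest.raises(ValueError, match="NeighborGraph"):
            constrained_gmm_fit(np.zeros((10, 2)), None, 2)

    def test_objective_trace_recorded(self):
        shape = (6, 5, 2)
        coords = _full_coords(shape)
        rng = np.random.default_rng(21)
        truth = (coords[:, 0] >= 3).astype(int)
        Y = np.where(truth[:, None] == 1, 3.0, 0.0) + rng.normal(
            0, 0.5, (len(coords), 2)
        )
        g = build_neighbor_graph(coords, shape)
        _, resp = constrained_gmm_fit(Y, g, 2, seed=0)
        assert len(resp.trace) == resp.n_iter
        assert resp.n_iter >= 2
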