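import numpy as np
import pytest

import stdomain.agc as agc_mod
from stdomain import (
    AGCPreClusterer,
    FixtureSpec,
    ari,
    build_spot_graph,
    intra_cluster_distance,
    kmeans_assign,
    run_agc,
    simulate_counts,
    smooth,
    spectral_embed,
)
class TestSmooth:
    def test_t_zero_is_identity(self):
        rng = np.random.default_rng(0)
        F = rng.normal(size=(5, 3))
        L = np.eye(5) * 0.5
        np.testing.assert_array_equal(smooth(F, L, 1.5, 0), F)

    def test_isolated_self_looped_node_unchanged(self):
        F = np.array([[2.0, -1.0]])
        np.testing.assert_array_equal(smooth(F, np.zeros((1, 1)), 1.5, 7), F)

    def test_matches_explicit_matrix_power(self):
        # 3-node path graph Laplacian, t = 2
        A = np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 1.0], [0.0, 1.0, 1.0]])
        from stdomain import normalized_laplacian

        L = normalized_laplacian(A)
        rng = np.random.default_rng(1)
        F = rng.normal(size=(3, 4))
        M = np.eye(3) - L / 1.5
        np.testing.assert_allclose(
            smooth(F, L, 1.5, 2), np.linalg.matrix_power(M, 2) @ F, atol=1e-12
        )

    def test_large_lambda_limit_approaches_identity(self):
        rng = np.random.default_rng(2)
        F = rng.normal(size=(6, 3))
        L = np.diag(rng.random(6))
        np.testing.assert_allclose(smooth(F, L, 1e9, 5), F, atol=1e-6)


class TestSpectralEmbed:
    def test_matches_direct_eigendecomposition(self):
        rng = np.random.default_rng(3)
        H = rng.normal(size=(8, 5))
        R = spectral_embed(H, 3)
        evals, evecs = np.linalg.eigh(H @ H.T)
        top = np.argsort(evals)[::-1][:3]
        expected = evecs[:, top] * np.sqrt(np.maximum(evals[top], 0.0))
        for j in range(3):  # match the deterministic sign convention
            col = expected[:, j]
            if col[np.argmax(np.abs(col))] < 0:
                expected[:, j] = -col
        np.testing.assert_allclose(R, expected, atol=1e-8)

    def test_full_rank_embedding_reconstructs_similarity(self):
        rng = np.random.default_rng(4)
        H = rng.normal(size=(6, 4))
        R = spectral_embed(H, 4)
        np.testing.assert_allclose(R @ R.T, H @ H.T, atol=1e-8)

    def test_orthogonal_rows_give_axis_aligned_embedding(self):
        H = np.diag([3.0, 2.0, 1.0])
        R = spectral_embed(H, 3)
        np.testing.assert_allclose(np.abs(R), np.diag([3.0, 2.0, 1.0]), atol=1e-12)

    def test_dim_above_rank_errors(self):
        with pytest.raises(ValueError):
            spectral_embed(np.ones((4, 3)), 4)


class TestKmeansAssign:
    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(5)
        R = np.vstack(
            [rng.normal(0, 0.1, (20, 2)), rng.normal(5, 0.1, (20, 2))]
        )
        truth = np.repeat([0, 1], 20)
        assert ari(truth, kmeans_assign(R, 2, seed=0)) == 1.0

    def test_single_cluster_and_determinism(self):
        rng = np.random.default_rng(6)
        R = rng.normal(size=(10, 2))
        np.testing.assert_array_equal(kmeans_assign(R, 1, 0), np.zeros(10, dtype=int))
        np.testing.assert_array_equal(
            kmeans_assign(R, 3, 9), kmeans_assign(R, 3, 9)
        )

    def test_first_occurrence_relabeling(self):
        rng = np.random.default_rng(7)
        R = np.vstack([rng.normal(i * 10, 0.1, (5, 2)) for i in range(3)])
        labels = kmeans_assign(R, 3, seed=1)
        # first occurrences appear in increasing order
        firsts = [np.flatnonzero(labels == k)[0] for k in range(3)]
        assert firsts == sorted(firsts)

    def test_more_clusters_than_points_errors(self):
        with pytest.raises(ValueError):
            kmeans_assign(np.zeros((3, 2)), 4, 0)


class TestIntraClusterDistance:
    def test_identical_embeddings_give_zero(self):
        H = np.ones((6, 3))
        assert intra_cluster_distance(H, np.repeat([0, 1], 3)) == 0.0

    def test_single_pair_cluster_returns_distance(self):
        H = np.array([[0.0, 0.0], [0.0, 1.5]])
        assert intra_cluster_distance(H, np.array([0, 0])) == 1.5

    def test_two_pair_clusters_average(self):
        H = np.array([[0.0, 0.0], [0.0, 1.5], [10.0, 0.0], [10.0, 2.5]])
        C = np.array([0, 0, 1, 1])
        assert intra_cluster_distance(H, C) == 2.0

    def test_singletons_contribute_zero(self):
        H = np.array([[0.0, 0.0], [0.0, 2.0], [50.0, 50.0]])
        # cluster 1 is a singleton: mean over 2 clusters of (2, 0)
        assert intra_cluster_distance(H, np.array([0, 0, 1])) == 1.0

    def test_empty_assignment_errors(self):
        with pytest.raises(ValueError):
            intra_cluster_distance(np.ones((2, 2)), np.array([0]))


class TestRunAgc:
    def test_stops_at_first_intra_increase(self, monkeypatch):
        trace_values = iter([5.0, 4.0, 3.0, 6.0])
        calls = []

        def fake_intra(H, C):
            return next(trace_values)

        def fake_kmeans(R, n, seed):
            calls.append(seed)
            return np.full(R.shape[0], len(calls), dtype=int)

        monkeypatch.setattr(agc_mod, "intra_cluster_distance", fake_intra)
        monkeypatch.setattr(agc_mod, "kmeans_assign", fake_kmeans)
        rng = np.random.default_rng(8)
        F = rng.normal(size=(6, 4))
        L = np.diag(rng.random(6))
        res = agc_mod.run_agc(F, L, n=2, seed=0, max_t=10)
        assert res.stop_t == 3
        assert res.intra_trace == [5.0, 4.0, 3.0, 6.0]
        np.testing.assert_array_equal(res.labels, np.full(6, 3))

    def test_recovers_planted_stripes(self, stripe_preprocessed):
        pp = stripe_preprocessed
        res = run_agc(pp["p50"].scores, pp["graph"].L, 3, seed=0)
        assert ari(pp["labels"], res.labels) >= 0.9

    def test_single_cluster_trivial(self):
        rng = np.random.default_rng(9)
        F = rng.normal(size=(5, 3))
        L = np.diag(rng.random(5))
        res = run_agc(F, L, n=1, seed=0)
        assert res.stop_t == 1
        np.testing.assert_array_equal(res.labels, 0)

    def test_disconnected_cliques_recovered_exactly(self):
        from stdomain import normalized_laplacian

        blocks = 3
        A = np.kron(np.eye(blocks), np.ones((4, 4)))
        L = normalized_laplacian(A)
        rng = np.random.default_rng(10)
        centers = rng.normal(size=(blocks, 6)) * 10
        F = np.repeat(centers, 4, axis=0) + rng.normal(scale=0.05, size=(12, 6))
        res = run_agc(F, L, n=blocks, seed=0, embed_dim=6)
        assert ari(np.repeat(np.arange(blocks), 4), res.labels) == 1.0

    def test_invariant_to_spot_permutation(self):
        from stdomain import normalized_laplacian

        rng = np.random.default_rng(11)
        A = np.kron(np.eye(2), np.ones((5, 5)))
        L = normalized_laplacian(A)
        F = np.vstack(
            [rng.normal(0, 0.1, (5, 4)), rng.normal(8, 0.1, (5, 4))]
        )
        res = run_agc(F, L, n=2, seed=0, embed_dim=4)
        perm = rng.permutation(10)
        res_p = run_agc(F[perm], L[np.ix_(perm, perm)], n=2, seed=0, embed_dim=4)
        assert ari(res.labels[perm], res_p.labels) == 1.0


def test_estimator_front_end(stripe_preprocessed):
    pp = stripe_preprocessed
    model = AGCPreClusterer(n_clusters=3, random_state=0)
    labels = model.fit_predict(pp["p50"].scores, coords=pp["d"].pixel_xy)
    assert ari(pp["labels"], labels) >= 0.9
    assert model.sigma_ > 0
    assert len(model.intra_trace_) >= model.stop_t_
    params = model.get_params()
    assert params["n_clusters"] == 3 and params["lam"] == 1.5
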