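import numpy as np
import pytest
import scipy.sparse as sp

from vesseltopo.gcn import (
    ChebParams,
    GCNParams,
    GCNTrainConfig,
    cheb_layer,
    first_order_identity_check,
    forward,
    gcn_layer,
    init_params,
    laplacian,
    learning_rate_at,
    load_params,
    predict,
    save_params,
    train_gcn,
)
from vesseltopo.graph import VesselGraph, build_edges, normalize

from conftest import random_adjacency, random_connected_adjacency


def spectral_cheb_oracle(X, A, params: ChebParams) -> np.ndarray:
    """Explicit eigendecomposition route: sum_k U T_k(Lam) U^T X theta_k."""
    L = laplacian(A).toarray()
    n = L.shape[0]
    L_hat = (2.0 / params.lambda_max) * L - np.eye(n)
    lam, U = np.linalg.eigh(L_hat)
    t_prev = np.ones_like(lam)
    t_curr = lam.copy()
    Y = (U @ np.diag(t_prev) @ U.T) @ X @ params.theta_k[0]
    if params.K >= 1:
        Y += (U @ np.diag(t_curr) @ U.T) @ X @ params.theta_k[1]
        for k in range(2, params.K + 1):
            t_next = 2.0 * lam * t_curr - t_prev
            Y += (U @ np.diag(t_next) @ U.T) @ X @ params.theta_k[k]
            t_prev, t_curr = t_curr, t_next
    return Y


class TestGcnLayer:
    def test_isolated_node_passes_through_theta(self, rng):
        S = normalize(sp.csr_matrix((1, 1))).S
        x = rng.normal(size=(1, 3))
        theta = rng.normal(size=(3, 2))
        assert np.allclose(gcn_layer(x, S, theta), x @ theta)

    def test_two_node_complete_graph_averages(self, rng):
        A = sp.csr_matrix(np.array([[0.0, 1.0], [1.0, 0.0]]))
        S = normalize(A).S
        x = rng.normal(size=(2, 4))
        y = gcn_layer(x, S, np.eye(4))
        mean = x.mean(axis=0)
        assert np.allclose(y[0], mean) and np.allclose(y[1], mean)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_oracle(self, seed):
        rng = np.random.default_rng(seed)
        A = random_adjacency(rng, 10)
        S = normalize(A).S
        X = rng.normal(size=(10, 6))
        Theta = rng.normal(size=(6, 3))
        dense = S.toarray() @ X @ Theta
        assert np.max(np.abs(gcn_layer(X, S, Theta) - dense)) < 1e-10

    def test_shape_mismatch_rejected(self, rng):
        S = normalize(random_adjacency(rng, 5)).S
        with pytest.raises(ValueError):
            gcn_layer(rng.normal(size=(4, 3)), S, rng.normal(size=(3, 2)))
        with pytest.raises(ValueError):
            gcn_layer(rng.normal(size=(5, 3)), S, rng.normal(size=(4, 2)))


class TestChebLayer:
    def test_k0_is_feature_transform_only(self, rng):
        A = random_adjacency(rng, 8)
        X = rng.normal(size=(8, 4))
        theta0 = rng.normal(size=(4, 2))
        Y = cheb_layer(X, A, ChebParams(K=0, theta_k=[theta0]))
        assert np.allclose(Y, X @ theta0)

    def test_k1_matches_first_order_expansion(self, rng):
        # K=1, lambda_max=2: Y = X theta0 + (L - I) X theta1
        A = random_adjacency(rng, 9)
        X = rng.normal(size=(9, 5))
        t0, t1 = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
        Y = cheb_layer(X, A, ChebParams(K=1, theta_k=[t0, t1], lambda_max=2.0))
        L = laplacian(A).toarray()
        expected = X @ t0 + (L - np.eye(9)) @ X @ t1
        assert np.max(np.abs(Y - expected)) < 1e-12

    @pytest.mark.parametrize("K", [0, 1, 2, 3])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_eigendecomposition_oracle(self, K, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        A = random_adjacency(rng, n)
        X = rng.normal(size=(n, 4))
        params = ChebParams(K=K, theta_k=[rng.normal(size=(4, 3)) for _ in range(K + 1)])
        Y = cheb_layer(X, A, params)
        assert np.max(np.abs(Y - spectral_cheb_oracle(X, A, params))) < 1e-8

    def test_isolated_nodes_act_as_identity_in_L(self, rng):
        # zero-degree convention: D^(-1/2) entry 0, so L row = identity row
        A = sp.csr_matrix((3, 3))
        L = laplacian(A).toarray()
        assert np.allclose(L, np.eye(3))

    def test_invalid_order_rejected(self):
        with pytest.raises(ValueError):
            ChebParams(K=-1, theta_k=[])
        with pytest.raises(ValueError):
            ChebParams(K=2, theta_k=[np.eye(2)])


class TestFirstOrderIdentity:
    @pytest.mark.parametrize("seed", range(5))
    def test_holds_on_connected_graphs(self, seed):
        rng = np.random.default_rng(seed)
        A = random_connected_adjacency(rng, int(rng.integers(2, 15)))
        x = rng.normal(size=(A.shape[0], 3))
        theta = rng.normal(size=(3, 2))
        assert first_order_identity_check(A, x, theta)

    def test_zero_theta_trivially_true(self, rng):
        A = random_connected_adjacency(rng, 6)
        assert first_order_identity_check(A, rng.normal(size=(6, 2)), np.zeros((2, 2)))

    def test_sign_flip_breaks_identity(self, rng):
        # with theta1 = +theta the off-diagonal term changes sign
        A = sp.csr_matrix(np.array([[0.0, 1.0], [1.0, 0.0]]))
        x = rng.normal(size=(2, 1))
        theta = np.array([[1.0]])
        deg = np.asarray(A.sum(axis=1)).ravel()
        Dinv = sp.diags(1.0 / np.sqrt(deg))
        SA = (Dinv @ A @ Dinv).toarray()
        lhs_flipped = x @ theta - SA @ x @ (+theta)  # theta1 = +theta
        rhs = (x + SA @ x) @ theta
        assert not np.allclose(lhs_flipped, rhs)

    def test_isolated_node_rejected(self, rng):
        A = sp.csr_matrix((3, 3))
        with pytest.raises(ValueError, match="isolated"):
            first_order_identity_check(A, rng.normal(size=(3, 2)), np.eye(2))


class TestForward:
    def _setup(self, rng, n=10, c=6, h=4):
        A = random_adjacency(rng, n)
        S = normalize(A).S
        X = rng.normal(size=(n, c))
        params = GCNParams(
            Theta1=rng.normal(size=(c, h)), Theta2=rng.normal(size=(h, 4))
        )
        return X, S, params

    def test_zero_parameters_give_uniform_probabilities(self, rng):
        X, S, _ = self._setup(rng)
        params = GCNParams(Theta1=np.zeros((6, 4)), Theta2=np.zeros((4, 4)))
        probs = forward(X, S, params)
        assert np.allclose(probs, 0.25)

    def test_inference_is_deterministic(self, rng):
        X, S, params = self._setup(rng)
        assert np.array_equal(forward(X, S, params), forward(X, S, params))

    def test_default_channel_progression_67_32_4(self, rng):
        X = rng.normal(size=(12, 67))
        S = normalize(random_adjacency(rng, 12)).S
        cfg = GCNTrainConfig()
        params = init_params(67, cfg)
        assert params.Theta1.shape == (67, 32)
        assert params.Theta2.shape == (32, 4)
        assert forward(X, S, params).shape == (12, 4)

    def test_rows_sum_to_one(self, rng):
        X, S, params = self._setup(rng)
        assert np.allclose(forward(X, S, params).sum(axis=1), 1.0)

    def test_permutation_equivariance(self, rng):
        X, S, params = self._setup(rng, n=14)
        probs = forward(X, S, params)
        perm = rng.permutation(14)
        Sp = S.toarray()[np.ix_(perm, perm)]
        probs_p = forward(X[perm], sp.csr_matrix(Sp), params)
        assert np.max(np.abs(probs_p - probs[perm])) < 1e-8

    def test_training_mode_requires_rng(self, rng):
        X, S, params = self._setup(rng)
        with pytest.raises(ValueError):
            forward(X, S, params, training=True)

    def test_dropout_expectation_matches_inference(self, rng):
        # constant features, many training-mode passes ~ inference pass
        n = 8
        A = random_connected_adjacency(rng, n)
        S = normalize(A).S
        X = np.ones((n, 5))
        params = GCNParams(
            Theta1=rng.normal(size=(5, 6)) * 0.3,
            Theta2=rng.normal(size=(6, 4)) * 0.3,
            dropout_rate=0.5,
        )
        draws = np.mean(
            [forward(X, S, params, training=True, rng=rng) for _ in range(2000)],
            axis=0,
        )
        ref = forward(X, S, params)
        assert np.max(np.abs(draws - ref)) < 0.05


class TestTraining:
    def _planted_graph(self, seed=0, noise=0.05):
        # two 5x5 blobs, artery left / vein right, separable node features
        rng = np.random.default_rng(seed)
        mask = np.zeros((7, 12), dtype=bool)
        mask[1:6, 1:6] = True
        mask[1:6, 7:12] = True
        labels = np.zeros((7, 12), dtype=np.int64)
        labels[1:6, 1:6] = 1
        labels[1:6, 7:12] = 3
        _, A = build_edges(mask)
        means = {0: [0.0, 0.0, 1.0], 1: [1.0, 0.0, 0.0], 3: [0.0, 1.0, 0.0]}
        X = np.zeros((mask.size, 3))
        for node, lab in enumerate(labels.reshape(-1)):
            X[node] = means[lab] + rng.normal(0, noise, size=3)
        return VesselGraph(
            shape=mask.shape, X=X, edges=np.zeros((0, 2), dtype=int), A=A,
            y=labels.reshape(-1),
        )

    def test_zero_epochs_returns_initial_params(self):
        g = self._planted_graph()
        cfg = GCNTrainConfig(total_epochs=0, standardize_features=False, seed=5)
        params, history = train_gcn([g], cfg)
        init = init_params(3, cfg)
        assert history == []
        assert np.array_equal(params.Theta1, init.Theta1)
        assert np.array_equal(params.Theta2, init.Theta2)

    def test_planted_two_class_graph_reaches_99pct(self):
        g = self._planted_graph(seed=1)
        cfg = GCNTrainConfig(total_epochs=200, lr_decay_factor=0.1, seed=0)
        params, history = train_gcn([g], cfg)
        probs = predict(g, params)
        acc = float(np.mean(probs.argmax(axis=1) == g.y))
        assert acc >= 0.99
        assert history[-1]["loss"] < history[0]["loss"]

    def test_learning_rate_decay_schedule(self):
        cfg = GCNTrainConfig(
            learning_rate=0.003, lr_decay_factor=0.01, lr_decay_interval=30
        )
        assert learning_rate_at(cfg, 0) == 0.003
        # first epoch after the decay interval runs at factor * initial
        assert np.isclose(learning_rate_at(cfg, 30), 0.003 * 0.01)
        g = self._planted_graph()
        cfg2 = GCNTrainConfig(total_epochs=3, lr_decay_interval=2, lr_decay_factor=0.5)
        _, history = train_gcn([g], cfg2)
        assert [h["lr"] for h in history] == [0.003, 0.003, 0.0015]

    def test_seed_determinism(self):
        g = self._planted_graph()
        cfg = GCNTrainConfig(total_epochs=10, seed=3)
        p1, h1 = train_gcn([g], cfg)
        p2, h2 = train_gcn([g], cfg)
        assert h1 == h2
        assert np.array_equal(p1.Theta1, p2.Theta1)

    def test_unlabeled_graph_rejected(self):
        g = self._planted_graph()
        g.y = None
        with pytest.raises(ValueError):
            train_gcn([g], GCNTrainConfig(total_epochs=1))

    def test_vessel_only_loss_flag(self):
        g = self._planted_graph()
        cfg = GCNTrainConfig(total_epochs=5, loss_on_vessel_nodes_only=True)
        params, history = train_gcn([g], cfg)
        assert np.all(np.isfinite(params.Theta1))

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            GCNTrainConfig(lr_decay_factor=0.0)
        with pytest.raises(ValueError):
            GCNTrainConfig(total_epochs=-1)


class TestSerialization:
    def test_params_roundtrip(self, tmp_path, rng):
        cfg = GCNTrainConfig(total_epochs=4, seed=1)
        g_rng = np.random.default_rng(0)
        A = random_adjacency(g_rng, 12)
        g = VesselGraph(
            shape=(3, 4),
            X=g_rng.normal(size=(12, 5)),
            edges=np.zeros((0, 2), dtype=int),
            A=A,
            y=g_rng.integers(0, 4, size=12),
        )
        params, _ = train_gcn([g], cfg)
        path = tmp_path / "gcn.npz"
        save_params(params, cfg, path)
        loaded, loaded_cfg = load_params(path)
        assert loaded_cfg == cfg
        assert np.allclose(predict(g, loaded), predict(g, params))
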