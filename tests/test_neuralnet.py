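"""Shallow regressor: gradients, adaptive-rate rule, early stopping, splits."""

import numpy as np
import pandas as pd
import pytest

from coupledraw import neuralnet as nn
from coupledraw.core import substream


def _tiny_net():
    return nn.ShallowNet(
        W1=np.array([[0.5, -0.3, 0.2], [0.1, 0.4, -0.6], [-0.2, 0.7, 0.05]]),
        b1=np.array([0.1, -0.2, 0.3]),
        W2=np.array([[1.0, -0.5, 0.25]]),
        b2=np.array([0.4]),
    )


class TestForward:
    def test_zero_weights_output_bias(self, rng):
        net = nn.ShallowNet(W1=np.zeros((4, 6)), b1=np.zeros(4),
                            W2=np.zeros((1, 4)), b2=np.array([2.5]))
        X = rng.standard_normal((10, 6))
        assert np.allclose(nn.forward(net, X), 2.5)
        # scaling inputs cannot change the output when the readout is zero
        assert np.allclose(nn.forward(net, 100 * X), 2.5)

    def test_tiny_instance_matches_hand_computation(self):
        net = _tiny_net()
        x = np.array([1.0, 2.0, -1.0])
        h = np.tanh(net.W1 @ x + net.b1)       # manual matrix arithmetic
        expected = (net.W2 @ h + net.b2)[0]
        assert nn.forward(net, x)[0] == pytest.approx(expected, abs=1e-15)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="input dim"):
            nn.forward(_tiny_net(), np.ones((2, 5)))


class TestInit:
    def test_seeded_reproducibility_and_variation(self):
        a = nn.init_network(20, 5, np.random.default_rng(3))
        b = nn.init_network(20, 5, np.random.default_rng(3))
        c = nn.init_network(20, 5, np.random.default_rng(4))
        assert np.array_equal(a.W1, b.W1) and np.array_equal(a.b2, b.b2)
        assert not np.array_equal(a.W1, c.W1)

    def test_magnitudes_within_declared_ranges(self):
        net = nn.init_network(100, 30, np.random.default_rng(0))
        assert np.allclose(np.linalg.norm(net.W1, axis=1), nn.INIT_BETA)
        assert np.all(np.abs(net.b1) <= nn.INIT_BETA)
        assert np.all(np.abs(net.W2) <= 1 / np.sqrt(30))


class TestGradients:
    def test_analytic_matches_central_differences(self, rng):
        """6-4-1 finite-difference oracle, relative error < 1e-5."""
        net = nn.init_network(6, 4, rng)
        X = rng.standard_normal((12, 6))
        y = rng.standard_normal(12)
        _, grads = nn.loss_and_grads(net, X, y)
        eps = 1e-6
        for name in ("W1", "b1", "W2", "b2"):
            P = getattr(net, name)
            num = np.zeros_like(P)
            for idx in np.ndindex(P.shape):
                P[idx] += eps
                up, _ = nn.loss_and_grads(net, X, y)
                P[idx] -= 2 * eps
                dn, _ = nn.loss_and_grads(net, X, y)
                P[idx] += eps
                num[idx] = (up - dn) / (2 * eps)
            scale = np.maximum(np.abs(num), 1e-8)
            assert np.max(np.abs(grads[name] - num) / scale) < 1e-5

    def test_zero_gradient_leaves_parameters(self):
        # with zero readout and zero targets the loss is exactly flat in W2
        net = nn.ShallowNet(W1=np.zeros((3, 2)), b1=np.zeros(3),
                            W2=np.zeros((1, 3)), b2=np.zeros(1))
        X = np.zeros((5, 2))
        y = np.zeros(5)
        state = nn._OptState(lr=0.1, velocity={
            "W1": np.zeros((3, 2)), "b1": np.zeros(3),
            "W2": np.zeros((1, 3)), "b2": np.zeros(1)})
        net2, _, mse = nn.backprop_step(net, X, y, state, nn.TrainConfig())
        assert mse == 0.0
        assert np.array_equal(net2.W1, net.W1) and np.array_equal(net2.b2, net.b2)


class TestAdaptiveRate:
    def test_rate_drops_and_step_rejected_on_loss_blowup(self, rng):
        net = nn.init_network(3, 2, rng)
        X = rng.standard_normal((8, 3))
        y = rng.standard_normal(8)
        cfg = nn.TrainConfig(lr0=1e6)  # guaranteed overshoot
        state = nn._OptState(lr=cfg.lr0, velocity={
            k: np.zeros_like(getattr(net, k)) for k in ("W1", "b1", "W2", "b2")})
        net2, state2, _ = nn.backprop_step(net, X, y, state, cfg)
        assert state2.lr == pytest.approx(cfg.lr0 * cfg.lr_dec)
        assert np.array_equal(net2.W1, net.W1)          # step rejected
        assert all(np.all(v == 0) for v in state2.velocity.values())

    def test_rate_grows_after_improvement(self, rng):
        net = nn.init_network(3, 2, rng)
        X = rng.standard_normal((8, 3))
        y = nn.forward(net, X) + 0.5   # nonzero residual, smooth landscape
        cfg = nn.TrainConfig(lr0=0.01)
        state = nn._OptState(lr=cfg.lr0, velocity={
            k: np.zeros_like(getattr(net, k)) for k in ("W1", "b1", "W2", "b2")})
        _, state2, _ = nn.backprop_step(net, X, y, state, cfg)
        assert state2.lr == pytest.approx(cfg.lr0 * cfg.lr_inc)


class TestTraining:
    def test_learns_noiseless_linear_target(self, rng):
        w = rng.standard_normal(5)
        X = rng.uniform(-1, 1, (120, 5))
        y = X @ w
        net = nn.init_network(5, 8, rng)
        cfg = nn.TrainConfig(max_epochs=2000, patience=50)
        net2, trace = nn.train(net, X[:90], y[:90], X[90:105], y[90:105], cfg)
        pred = nn.forward(net2, X[105:])
        assert np.corrcoef(pred, y[105:])[0, 1] > 0.99

    def test_patience_one_stops_on_first_failure(self, rng):
        net = nn.init_network(4, 3, rng)
        X = rng.standard_normal((10, 4))
        y = rng.standard_normal(10)
        # validation drawn from a different distribution: degrades quickly
        Xv = rng.standard_normal((4, 4)) * 50
        yv = rng.standard_normal(4) * 50
        cfg = nn.TrainConfig(patience=1, max_epochs=200)
        _, trace = nn.train(net, X, y, Xv, yv, cfg)
        assert trace.stop_reason == "early_stopping"
        assert trace.epochs_run == trace.best_epoch + 2

    def test_returns_best_validation_parameters(self, rng):
        net = nn.init_network(4, 3, rng)
        X = rng.standard_normal((30, 4))
        y = rng.standard_normal(30)
        net2, trace = nn.train(net, X[:20], y[:20], X[20:], y[20:],
                               nn.TrainConfig(max_epochs=60, patience=5))
        val = float(np.mean((nn.forward(net2, X[20:]) - y[20:]) ** 2))
        assert val == pytest.approx(min(trace.val_mse), rel=1e-12)
        assert val <= trace.val_mse[-1] + 1e-15

    def test_empty_sets_rejected(self, rng):
        net = nn.init_network(4, 3, rng)
        with pytest.raises(ValueError):
            nn.train(net, np.empty((0, 4)), np.empty(0), np.ones((2, 4)),
                     np.ones(2), nn.TrainConfig())


class TestScaler:
    def test_midpoint_maps_to_zero(self):
        sc = nn.FeatureScaler().fit(np.array([[0.0], [10.0]]))
        assert sc.transform(np.array([[5.0]]))[0, 0] == 0.0

    def test_no_clipping_outside_training_range(self):
        sc = nn.FeatureScaler().fit(np.array([[0.0], [10.0]]))
        assert sc.transform(np.array([[20.0]]))[0, 0] == pytest.approx(3.0)

    def test_roundtrip_and_constant_features(self, rng):
        X = rng.standard_normal((40, 6))
        X[:, 2] = 4.2
        sc = nn.FeatureScaler().fit(X)
        Z = sc.transform(X)
        assert np.allclose(Z[:, 2], 0.0)
        assert np.allclose(sc.inverse_transform(Z), X)


class TestSplits:
    def test_240_split_sizes_exact(self, rng):
        s = nn.make_split(240, (0.85, 0.05, 0.10), rng)
        assert (len(s.train_idx), len(s.val_idx), len(s.test_idx)) == (204, 12, 24)
        allidx = np.concatenate([s.train_idx, s.val_idx, s.test_idx])
        assert len(np.unique(allidx)) == 240

    def test_disjointness_enforced(self):
        with pytest.raises(ValueError, match="disjoint"):
            nn.SplitScheme(np.array([0, 1]), np.array([1]), np.array([2]))


def _linear_problem(n=240, d=12, seed=0):
    r = np.random.default_rng(seed)
    X = pd.DataFrame(r.uniform(-1, 1, (n, d)),
                     index=pd.Index(np.arange(n), name="trial_id"))
    y = pd.Series(X.to_numpy() @ r.standard_normal(d), index=X.index, name="ci")
    return X, y


FAST = nn.TrainConfig(max_epochs=15, patience=3)


class TestIterateSplits:
    def test_coverage_counts_and_determinism(self):
        X, y = _linear_problem()
        res1 = nn.iterate_splits(X, y, n_iter=200, hidden_dim=6, cfg=FAST, seed=5)
        res2 = nn.iterate_splits(X, y, n_iter=200, hidden_dim=6, cfg=FAST, seed=5)
        assert res1.predictions.n_test_appearances.sum() == res1.n_iterations * 24
        assert res1.predictions.n_test_appearances.min() >= 5
        pd.testing.assert_frame_equal(res1.predictions, res2.predictions)
        pd.testing.assert_frame_equal(res1.iterations, res2.iterations)

    def test_predictions_only_from_test_appearances(self):
        """Leakage check: appearance counts must equal the number of times a
        trial lands in the regenerated test sets of the same substreams."""
        X, y = _linear_problem(seed=1)
        res = nn.iterate_splits(X, y, n_iter=60, hidden_dim=6, cfg=FAST, seed=9,
                                min_appearances=1)
        counts = np.zeros(len(X), dtype=int)
        for k in range(res.n_iterations):
            split = nn.make_split(len(X), (0.85, 0.05, 0.10),
                                  substream(9, "ann-iteration", k))
            counts[split.test_idx] += 1
        assert np.array_equal(res.predictions.n_test_appearances.to_numpy(), counts)

    def test_insufficient_coverage_fails_hard(self):
        X, y = _linear_problem()
        with pytest.raises(RuntimeError, match="fewer than"):
            nn.iterate_splits(X, y, n_iter=3, hidden_dim=6, cfg=FAST, seed=0,
                              min_appearances=5, max_extra_iter=2)

    def test_mean_r_high_on_learnable_problem(self):
        X, y = _linear_problem(seed=2)
        res = nn.iterate_splits(X, y, n_iter=20, hidden_dim=8,
                                cfg=nn.TrainConfig(max_epochs=400, patience=20),
                                seed=3, min_appearances=0)
        assert res.mean_r > 0.9
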