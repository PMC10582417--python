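"""Metabolic LSTM: dataset assembly, gradients, learnability, evaluation."""

import numpy as np
import pytest

import thermogait as tg
from thermogait.metabolic import (NetConfig, _backward, _forward, init_weights,
                                  make_dataset, train)


class TestMakeDataset:
    def test_default_windowing(self, sessions6):
        X, y, sid = make_dataset(sessions6[0], NetConfig())
        # 180 s session -> 90 non-overlapping 2 s windows of 10 steps x 4 channels
        assert X.shape == (90, 10, 4)
        assert y.shape == (90,)
        assert np.all(sid == 0)

    def test_step_count_follows_rate(self):
        assert NetConfig(input_rate=5.0, window=2.0).steps == 10
        assert NetConfig(input_rate=10.0, window=2.0).steps == 20

    def test_non_divisor_rate_rejected(self, sessions6):
        with pytest.raises(ValueError, match="integer multiple"):
            make_dataset(sessions6[0], NetConfig(input_rate=7.0, window=2.0))

    def test_standardized_channels_zero_mean_unit_sd(self, sessions6):
        cfg = NetConfig()
        X, y, _ = make_dataset(sessions6[:2], cfg)
        norm = tg.Normalizer.fit(X, y)
        Xn = norm.transform_x(X)
        assert np.allclose(Xn.mean(axis=(0, 1)), 0.0, atol=1e-9)
        assert np.allclose(Xn.std(axis=(0, 1)), 1.0, atol=1e-6)


def test_bptt_gradients_match_finite_differences():
    """Handwritten backpropagation through time agrees with numerical
    differentiation of the full-batch MSE loss."""
    cfg = NetConfig(cells=3, input_rate=5.0, window=1.0, seed=0)
    rng = np.random.default_rng(1)
    X = rng.normal(size=(7, cfg.steps, 4))
    y = rng.normal(size=7)
    w = init_weights(cfg, rng)

    def loss(weights):
        pred = _forward(weights, X)
        return float(np.mean((pred - y) ** 2))

    y_hat, h_T, steps = _forward(w, X, cache=True)
    grads = _backward(w, X, y, y_hat, h_T, steps)
    eps = 1e-6
    for key in ("Wx", "Wh", "b", "w_out"):
        flat = np.asarray(w[key], dtype=float)
        idx = [tuple(rng.integers(0, s) for s in flat.shape) for _ in range(5)]
        for ij in idx:
            w_plus = {k: (v.copy() if isinstance(v, np.ndarray) else v) for k, v in w.items()}
            w_plus[key][ij] += eps
            w_minus = {k: (v.copy() if isinstance(v, np.ndarray) else v) for k, v in w.items()}
            w_minus[key][ij] -= eps
            num = (loss(w_plus) - loss(w_minus)) / (2 * eps)
            assert grads[key][ij] == pytest.approx(num, rel=1e-4, abs=1e-7)


def test_constant_target_learned_exactly():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(60, 10, 4))
    y = np.full(60, 7.5)
    model = train((X, y), NetConfig(epochs=50))
    assert tg.mape(model.predict(X), y) < 1.0


def test_speed_linked_target_learnable_out_of_sample():
    """With a deterministic speed -> metabolic map the network recovers
    held-out targets to within a few percent."""
    quiet = tg.MetabolicConfig(ar_sd=0.0)
    recs = [tg.generate_session(tg.ProtocolConfig(seed=11), metabolic=quiet,
                                session_index=k) for k in range(3)]
    cfg = NetConfig(seed=0)
    X, y, sid = make_dataset(recs, cfg)
    train_mask = sid < 2
    model = train((X[train_mask], y[train_mask]), cfg)
    held_out = tg.mape(model.predict(X[~train_mask]), y[~train_mask])
    assert held_out < 5.0


def test_training_is_deterministic():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(40, 10, 4))
    y = rng.normal(size=40) + 5.0
    cfg = NetConfig(epochs=30, seed=9)
    a = train((X, y), cfg).predict(X)
    b = train((X, y), cfg).predict(X)
    np.testing.assert_array_equal(a, b)


def test_divergent_loss_aborts_with_diagnostics():
    X = np.full((10, 10, 4), np.inf)
    y = np.ones(10)
    with pytest.raises(RuntimeError, match="epoch"):
        train((X, y), NetConfig(epochs=5))


def test_single_cell_network_runs(sessions6):
    cfg = NetConfig(cells=1, epochs=60, seed=0)
    X, y, sid = make_dataset(sessions6[:3], cfg)
    model = train((X[sid < 2], y[sid < 2]), cfg)
    err = tg.mape(model.predict(X[sid == 2]), y[sid == 2])
    assert np.isfinite(err)


def test_loo_partition_covers_each_session_once(sessions6):
    report = tg.evaluate_loo(sessions6[:3], NetConfig(epochs=40, seed=0))
    assert len(report.per_fold) == 3
    counts = np.bincount(report.fold_assignments)
    assert (counts > 0).all() and len(counts) == 3
    assert sum(f["n_test"] for f in report.per_fold) == len(report.fold_assignments)


def test_loo_requires_three_sessions(sessions6):
    with pytest.raises(ValueError):
        tg.evaluate_loo(sessions6[:2], NetConfig())


def test_model_serialization_round_trip(tmp_path):
    rng = np.random.default_rng(5)
    X = rng.normal(size=(30, 10, 4))
    y = rng.normal(size=30) + 6.0
    model = train((X, y), NetConfig(epochs=20, seed=1))
    path = tmp_path / "model.json"
    model.save(path)
    back = tg.MetabolicModel.load(path)
    np.testing.assert_allclose(back.predict(X), model.predict(X), rtol=1e-12)
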