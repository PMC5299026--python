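"""Tests for the recurrent response models: cells, unrolling, training."""

import copy

import numpy as np
import pytest

from voxencode.rnn import (
    GateParams,
    RNNDivergenceError,
    RNNLayer,
    TrainConfig,
    forward,
    gru_step,
    init_model,
    lstm_step,
    train,
)


def _zero_layer(cell, size, input_dim):
    names = ("o", "f", "i", "c") if cell == "LSTM" else ("z", "r", "h")
    gates = {
        n: GateParams(np.zeros((size, size)), np.zeros((size, input_dim)), np.zeros(size))
        for n in names
    }
    return RNNLayer(cell, size, input_dim, gates)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _reference_lstm_step(layer, h_prev, c_prev, x):
    """Independent scalar-loop LSTM step used as an oracle."""
    size = layer.size
    h, c = np.empty(size), np.empty(size)
    for u in range(size):
        acts = {}
        for name in ("o", "f", "i", "c"):
            g = layer.gates[name]
            a = g.b[u]
            for j in range(size):
                a += g.U[u, j] * h_prev[j]
            for j in range(layer.input_dim):
                a += g.W[u, j] * x[j]
            acts[name] = np.tanh(a) if (name == "c" and layer.candidate_tanh) else _sigmoid(a)
        c[u] = acts["f"] * c_prev[u] + acts["i"] * acts["c"]
        h[u] = acts["o"] * np.tanh(c[u])
    return h, c


def _reference_gru_step(layer, h_prev, x):
    size = layer.size
    h = np.empty(size)
    for u in range(size):
        a = {}
        for name in ("z", "r"):
            g = layer.gates[name]
            s = g.b[u] + sum(g.U[u, j] * h_prev[j] for j in range(size))
            s += sum(g.W[u, j] * x[j] for j in range(layer.input_dim))
            a[name] = _sigmoid(s)
        g = layer.gates["h"]
        s = g.b[u]
        for j in range(size):
            # reset gate of unit j gates its contribution to unit u
            gz = layer.gates["r"]
            rj = _sigmoid(
                gz.b[j]
                + sum(gz.U[j, k] * h_prev[k] for k in range(size))
                + sum(gz.W[j, k] * x[k] for k in range(layer.input_dim))
            )
            s += g.U[u, j] * (rj * h_prev[j])
        s += sum(g.W[u, j] * x[j] for j in range(layer.input_dim))
        h[u] = (1 - a["z"]) * h_prev[u] + a["z"] * np.tanh(s)
    return h


class TestCells:
    def test_lstm_all_zero_params_fixed_point(self, rng):
        """With zero parameters every gate is 1/2, so c = 1/4, h = tanh(1/4)/2."""
        layer = _zero_layer("LSTM", 3, 2)
        h, c = lstm_step(layer, np.zeros(3), np.zeros(3), rng.standard_normal(2))
        np.testing.assert_allclose(c, 0.25, atol=1e-12)
        np.testing.assert_allclose(h, 0.5 * np.tanh(0.25), atol=1e-12)

    def test_lstm_memory_preservation_limit(self, rng):
        layer = _zero_layer("LSTM", 3, 2)
        layer.gates["f"].b[:] = 50.0  # forget gate ~ 1
        layer.gates["i"].b[:] = -50.0  # input gate ~ 0
        c0 = rng.standard_normal(3)
        _, c = lstm_step(layer, np.zeros(3), c0, rng.standard_normal(2))
        assert np.max(np.abs(c - c0)) < 1e-6

    def test_lstm_matches_reference_oracle(self, rng):
        for candidate_tanh in (False, True):
            layer = _zero_layer("LSTM", 4, 3)
            layer.candidate_tanh = candidate_tanh
            for g in layer.gates.values():
                g.U[:] = rng.standard_normal(g.U.shape)
                g.W[:] = rng.standard_normal(g.W.shape)
                g.b[:] = rng.standard_normal(g.b.shape)
            h_prev, c_prev = rng.standard_normal(4), rng.standard_normal(4)
            x = rng.standard_normal(3)
            h, c = lstm_step(layer, h_prev, c_prev, x)
            h_ref, c_ref = _reference_lstm_step(layer, h_prev, c_prev, x)
            np.testing.assert_allclose(h, h_ref, atol=1e-12)
            np.testing.assert_allclose(c, c_ref, atol=1e-12)

    def test_gru_all_zero_params_halves_state(self, rng):
        layer = _zero_layer("GRU", 3, 2)
        v = rng.standard_normal(3)
        h = gru_step(layer, v, np.zeros(2))
        np.testing.assert_allclose(h, 0.5 * v, atol=1e-12)

    def test_gru_closed_update_gate_freezes_state(self, rng):
        layer = _zero_layer("GRU", 3, 2)
        layer.gates["z"].b[:] = -50.0
        v = rng.standard_normal(3)
        h = gru_step(layer, v, rng.standard_normal(2))
        np.testing.assert_allclose(h, v, atol=1e-6)

    def test_gru_matches_reference_oracle(self, rng):
        layer = _zero_layer("GRU", 4, 3)
        for g in layer.gates.values():
            g.U[:] = rng.standard_normal(g.U.shape)
            g.W[:] = rng.standard_normal(g.W.shape)
            g.b[:] = rng.standard_normal(g.b.shape)
        h_prev, x = rng.standard_normal(4), rng.standard_normal(3)
        np.testing.assert_allclose(
            gru_step(layer, h_prev, x), _reference_gru_step(layer, h_prev, x), atol=1e-12
        )

    def test_nan_input_raises_with_gate_name(self):
        layer = _zero_layer("GRU", 2, 2)
        with pytest.raises(RNNDivergenceError, match="gate"):
            gru_step(layer, np.array([np.nan, 0.0]), np.zeros(2))


class TestForward:
    def test_zero_readout_predicts_zero(self, rng):
        model = init_model("GRU", 5, 3, 2, seed=0)
        model.W_out[:] = 0.0
        pred, _, _ = forward(model, rng.standard_normal((10, 3)))
        np.testing.assert_array_equal(pred, 0)

    def test_state_reset_makes_identical_blocks_identical(self, rng):
        model = init_model("LSTM", 4, 3, 2, seed=1)
        X = rng.standard_normal((15, 3))
        p1, h1a, h2a = forward(model, X)
        p2, h1b, h2b = forward(model, X)
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_array_equal(h1a, h1b)

    def test_unroll_equals_manual_step_composition(self, rng):
        for cell in ("GRU", "LSTM"):
            model = init_model(cell, 4, 3, 2, seed=2)
            X = rng.standard_normal((6, 3))
            _, h1, h2 = forward(model, X)
            h = np.zeros(4)
            c = np.zeros(4)
            for t in range(6):
                if cell == "LSTM":
                    h, c = lstm_step(model.layer1, h, c, X[t])
                else:
                    h = gru_step(model.layer1, h, X[t])
                np.testing.assert_allclose(h1[t], h, atol=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        model = init_model("GRU", 4, 3, 2, seed=0)
        with pytest.raises(ValueError, match="features"):
            forward(model, rng.standard_normal((10, 5)))


class TestGradients:
    def test_backprop_matches_finite_differences(self, rng):
        """Hand-written BPTT gradients agree with central finite differences."""
        from voxencode.rnn import _layer_backward, _layer_forward, _named_params

        for cell in ("GRU", "LSTM"):
            model = init_model(cell, 3, 2, 2, seed=3)
            X = rng.standard_normal((4, 2, 2))
            Y = rng.standard_normal((4, 2, 2))

            def loss_grads():
                z = lambda: np.zeros((2, 3))
                c0 = z() if cell == "LSTM" else None
                H1, _, c1 = _layer_forward(model.layer1, X, z(), c0)
                H2, _, c2 = _layer_forward(model.layer2, H1, z(), z() if cell == "LSTM" else None)
                pred = H2 @ model.W_out.T
                resid = pred - Y
                L = float(np.mean(resid**2))
                dpred = 2 * resid / resid.size
                dW = dpred.reshape(-1, 2).T @ H2.reshape(-1, 3)
                g2, dH1 = _layer_backward(model.layer2, dpred @ model.W_out, c2)
                g1, _ = _layer_backward(model.layer1, dH1, c1)
                gm = {"out.W": dW}
                for li, gs in ((1, g1), (2, g2)):
                    for n, gp in gs.items():
                        gm[f"l{li}.{n}.U"] = gp.U
                        gm[f"l{li}.{n}.W"] = gp.W
                        gm[f"l{li}.{n}.b"] = gp.b
                return L, gm

            _, gm = loss_grads()
            eps = 1e-6
            for key, param in _named_params(model):
                idx = tuple(rng.integers(s) for s in param.shape)
                old = param[idx]
                param[idx] = old + eps
                Lp, _ = loss_grads()
                param[idx] = old - eps
                Lm, _ = loss_grads()
                param[idx] = old
                num = (Lp - Lm) / (2 * eps)
                assert gm[key][idx] == pytest.approx(num, abs=2e-7, rel=1e-4)


def _toy_blocks(rng, T=50, p=2, m=2, n=2, noise=0.0):
    blocks = []
    W = np.abs(rng.standard_normal((m, p)))
    kernel = np.array([0.0, 0.3, 1.0, 0.6, 0.2])
    for _ in range(n):
        X = rng.standard_normal((T, p))
        drive = X @ W.T
        Y = np.zeros_like(drive)
        for v in range(m):
            Y[:, v] = np.convolve(drive[:, v], kernel)[:T]
        Y += noise * rng.standard_normal(Y.shape)
        blocks.append((X, Y))
    return blocks


class TestTraining:
    def test_zero_epochs_returns_initialisation(self, rng):
        model = init_model("GRU", 3, 2, 2, seed=4)
        before = copy.deepcopy(model)
        out, history = train(model, _toy_blocks(rng), _toy_blocks(rng), TrainConfig(max_epochs=0))
        assert history == []
        np.testing.assert_array_equal(out.W_out, before.W_out)

    def test_fixed_seed_reproducible_bitwise(self, rng):
        tr, va = _toy_blocks(rng), _toy_blocks(rng)
        cfg = TrainConfig(max_epochs=3)
        m1, h1 = train(init_model("GRU", 3, 2, 2, seed=5), tr, va, cfg, seed=9)
        m2, h2 = train(init_model("GRU", 3, 2, 2, seed=5), tr, va, cfg, seed=9)
        assert h1 == h2
        np.testing.assert_array_equal(m1.W_out, m2.W_out)
        np.testing.assert_array_equal(m1.layer1.gates["z"].U, m2.layer1.gates["z"].U)

    def test_early_stopping_returns_best_epoch(self, rng):
        from voxencode.rnn import _validation_median_r

        tr, va = _toy_blocks(rng, noise=0.3), _toy_blocks(rng, noise=0.3)
        model, history = train(
            init_model("GRU", 3, 2, 2, seed=6), tr, va, TrainConfig(max_epochs=8), seed=6
        )
        best_recorded = max(h["val_median_r"] for h in history)
        assert _validation_median_r(model, va) == pytest.approx(best_recorded, abs=1e-12)

    def test_planted_linear_hrf_model_is_learned(self, rng):
        """Noiseless linear-kernel data: G-10 reaches high validation r."""
        tr = _toy_blocks(rng, T=120, n=4)
        va = _toy_blocks(rng, T=60, n=1)
        model, history = train(
            init_model("GRU", 10, 2, 2, seed=7), tr, va, TrainConfig(max_epochs=150), seed=7
        )
        assert max(h["val_median_r"] for h in history) > 0.8

    def test_pure_noise_gives_near_zero_validation_r(self, rng):
        meds = []
        for seed in range(3):
            r = np.random.default_rng(seed)
            tr = [(r.standard_normal((60, 2)), r.standard_normal((60, 2))) for _ in range(2)]
            va = [(r.standard_normal((40, 2)), r.standard_normal((40, 2)))]
            _, history = train(
                init_model("GRU", 3, 2, 2, seed=seed), tr, va, TrainConfig(max_epochs=10), seed=seed
            )
            meds.append(max(h["val_median_r"] for h in history))
        assert abs(np.median(meds)) < 0.35  # small-sample r fluctuates; no real signal

    def test_readout_rows_are_independent_given_frozen_trunk(self, rng):
        model = init_model("GRU", 4, 3, 3, seed=8)
        X = rng.standard_normal((20, 3))
        pred_full, _, h2 = forward(model, X)
        submodel = copy.deepcopy(model)
        submodel.W_out = model.W_out[:2]
        pred_sub, _, _ = forward(submodel, X)
        np.testing.assert_array_equal(pred_full[:, :2], pred_sub)

    def test_divergence_raises_with_epoch(self, rng):
        model = init_model("GRU", 3, 2, 2, seed=9)
        model.W_out[:] = 1e300
        bad = [(np.full((10, 2), 1.0), np.full((10, 2), 1e300))]
        with pytest.raises(RNNDivergenceError, match="epoch"):
            train(model, bad, bad, TrainConfig(max_epochs=2, grad_clip=None), seed=0)
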