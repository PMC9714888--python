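"""Temporal convolutional classifier: primitives, geometry, training."""

import numpy as np
import pytest

from myofuse.preprocess import normalize_length
from myofuse.states import STATES
from myofuse.tcn import (
    ConvParams,
    NetConfig,
    ResidualBlock,
    build_model,
    causal_conv,
    predict_proba,
    receptive_field,
    train,
)

# small architecture used by most structural tests
SMALL = dict(input_len=64, filters_per_stage=[4], dilations=[1, 2],
             kernel_size=2, dropout_rate=0.0, seed=0)


def brute_force_causal_conv(x, W, b, d):
    """Direct double-loop evaluation of the causal convolution sum."""
    x = np.atleast_2d(np.asarray(x, float).T).T
    L, cin = x.shape
    k, _, cout = W.shape
    y = np.zeros((L, cout))
    for t in range(L):
        for tap in range(k):
            src = t - (k - 1 - tap) * d
            if src >= 0:
                y[t] += x[src] @ W[tap]
        y[t] += b
    return y


class TestReceptiveField:
    def test_single_stage_ladder(self):
        assert receptive_field(5, [1, 2, 4, 8, 16, 32, 64]) == 509

    def test_two_stage_ladder(self):
        assert receptive_field(5, [1, 2, 4, 8, 16, 32, 64] * 2) == 1017

    def test_two_layer_example(self):
        assert receptive_field(2, [1, 2]) == 4

    def test_degenerate_no_convolution(self):
        assert receptive_field(5, []) == 1

    def test_per_layer_kernel_list(self):
        assert receptive_field([3, 5], [1, 2]) == 1 + 2 + 8

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            receptive_field([2, 2], [1])
        with pytest.raises(ValueError):
            receptive_field(2, [0, 1])


class TestCausalConv:
    def test_identity_kernel_reproduces_input(self, rng):
        x = rng.standard_normal(50)
        W = np.zeros((3, 1, 1))
        W[2, 0, 0] = 1.0  # tap at the current time step
        out = causal_conv(x, ConvParams(W=W), dilation=4)
        assert np.allclose(out, x)

    def test_impulse_dilation_geometry(self):
        x = np.zeros(32)
        x[0] = 1.0
        out = causal_conv(x, ConvParams(W=np.array([1.0, 1.0])), dilation=4)
        nonzero = np.flatnonzero(out)
        assert list(nonzero) == [0, 4]

    def test_matches_bruteforce_double_loop(self, rng):
        x = rng.standard_normal((64, 3))
        W = rng.standard_normal((5, 3, 2))
        b = rng.standard_normal(2)
        out = causal_conv(x, ConvParams(W=W, b=b), dilation=3)
        assert np.allclose(out, brute_force_causal_conv(x, W, b, 3), atol=1e-10)

    def test_causality_no_future_leakage(self, rng):
        x = rng.standard_normal(40)
        params = ConvParams(W=rng.standard_normal((4, 1, 1)))
        base = causal_conv(x, params, dilation=2)
        for t in range(40):
            xp = x.copy()
            xp[t] += 10.0
            pert = causal_conv(xp, params, dilation=2)
            assert np.allclose(pert[:t], base[:t], atol=1e-12)

    def test_activation_applied(self):
        x = np.array([-1.0, -2.0])
        out = causal_conv(x, ConvParams(W=np.array([1.0]),
                                        activation=lambda z: np.maximum(z, 0)))
        assert np.all(out == 0.0)


class TestResidualBlock:
    def _zeroed_block(self, ch=3, k=2, d=1, activation="identity"):
        rng = np.random.default_rng(0)
        block = ResidualBlock(ch, ch, k, d, dropout=0.0, rng=rng,
                              activation=activation)
        for conv in (block.conv1, block.conv2):
            conv.g.value[...] = 0.0
            conv.b.value[...] = 0.0
        return block

    def test_zero_f_identity_sigma_passes_input_through(self, rng):
        block = self._zeroed_block()
        x = rng.standard_normal((2, 20, 3)).astype(np.float32)
        assert np.allclose(block.forward(x), x, atol=1e-7)

    def test_channel_projection_when_widths_differ(self, rng):
        block = ResidualBlock(1, 6, 5, 2, dropout=0.0,
                              rng=np.random.default_rng(1))
        x = rng.standard_normal((2, 30, 1)).astype(np.float32)
        out = block.forward(x)
        assert out.shape == (2, 30, 6)
        assert block.proj is not None

    def test_matches_manual_primitive_chaining(self, rng):
        """Block forward equals hand-composition of causal convs, ReLUs and
        the shortcut, built from the block's own effective kernels."""
        block = ResidualBlock(2, 2, 3, 2, dropout=0.0,
                              rng=np.random.default_rng(7))
        x = rng.standard_normal((1, 40, 2)).astype(np.float32)

        h1 = causal_conv(x[0], ConvParams(W=block.conv1.weight(),
                                          b=block.conv1.b.value), dilation=2)
        h1 = np.maximum(h1, 0.0)
        h2 = causal_conv(h1, ConvParams(W=block.conv2.weight(),
                                        b=block.conv2.b.value), dilation=2)
        h2 = np.maximum(h2, 0.0)
        expected = np.maximum(h2 + x[0], 0.0)
        assert np.allclose(block.forward(x)[0], expected, atol=1e-5)

    def test_empirical_receptive_field_single_block(self, rng):
        """Perturbing the input exactly RF-1 samples back changes the
        output; one sample further back does not.  RF follows from the
        per-conv-layer dilation list [d, d]."""
        k, d = 5, 8
        block = ResidualBlock(1, 6, k, d, dropout=0.0,
                              rng=np.random.default_rng(3))
        rf = receptive_field([k, k], block.conv_layer_dilations)
        assert rf == 1 + (k - 1) * 2 * d
        L = 200
        x = rng.standard_normal((1, L, 1)).astype(np.float32)
        base = block.forward(x)
        t = 150
        for offset, should_change in ((rf - 1, True), (rf, False)):
            xp = x.copy()
            xp[0, t - offset, 0] += 100.0
            out = block.forward(xp)
            changed = not np.allclose(out[0, t], base[0, t], atol=1e-6)
            assert changed == should_change
            # causality: nothing before the perturbation moves
            assert np.allclose(out[0, : t - offset], base[0, : t - offset],
                               atol=1e-6)


class TestModel:
    def test_default_receptive_field_two_stage(self):
        assert build_model(NetConfig()).receptive_field == 1017

    def test_single_stage_receptive_field(self):
        cfg = NetConfig(filters_per_stage=[32])
        assert build_model(cfg).receptive_field == 509

    def test_zero_input_yields_valid_probabilities(self):
        model = build_model(NetConfig(**SMALL))
        proba = model.predict_proba_batch(np.zeros((2, 64), dtype=np.float32))
        assert proba.shape == (2, 3)
        assert np.all(proba >= 0)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_batch_equals_single_item_calls(self, rng):
        model = build_model(NetConfig(**SMALL))
        X = rng.standard_normal((4, 64)).astype(np.float32)
        batch = model.predict_proba_batch(X)
        for i in range(4):
            series = normalize_length(X[i], L=64)
            single = predict_proba(model, series)
            assert np.allclose(single.as_array(), batch[i], atol=1e-6)

    def test_wrong_input_length_rejected(self, rng):
        model = build_model(NetConfig(**SMALL))
        with pytest.raises(ValueError):
            predict_proba(model, rng.standard_normal(65))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            NetConfig(n_classes=2)
        with pytest.raises(ValueError):
            NetConfig(dilations=[0, 1])

    def test_save_load_roundtrip(self, tmp_path, rng):
        model = build_model(NetConfig(**SMALL))
        model.norm_mu, model.norm_sd = 0.3, 1.7
        X = rng.standard_normal((3, 64)).astype(np.float32)
        model.save(tmp_path / "model")
        from myofuse.tcn import TCNClassifier

        back = TCNClassifier.load(tmp_path / "model")
        assert np.allclose(back.predict_proba_batch(X),
                           model.predict_proba_batch(X), atol=1e-7)


def _toy_training_set(n_per_state=15, L=64, seed=0):
    """Separable toy periods: state-dependent amplitude of a noisy tone."""
    rng = np.random.default_rng(seed)
    amps = {-1: 0.5, 0: 1.5, 1: 3.0}
    X, y = [], []
    t = np.arange(L)
    for state in STATES:
        for _ in range(n_per_state):
            x = amps[state] * np.sin(2 * np.pi * t / 16 + rng.uniform(0, 6.28))
            X.append(x + 0.1 * rng.standard_normal(L))
            y.append(state)
    return np.asarray(X, np.float32), np.asarray(y)


class TestTraining:
    def test_same_seed_identical_final_weights(self):
        X, y = _toy_training_set()
        cfg = NetConfig(**SMALL, epochs=2, batch_size=8)
        runs = []
        for _ in range(2):
            model = build_model(cfg)
            train(model, X, y, cfg)
            runs.append(np.concatenate([p.value.ravel() for p in model.params()]))
        assert np.array_equal(runs[0], runs[1])

    def test_single_class_rejected(self):
        X, y = _toy_training_set(n_per_state=5)
        cfg = NetConfig(**SMALL, epochs=1)
        model = build_model(cfg)
        with pytest.raises(ValueError):
            train(model, X, np.full_like(y, 1), cfg)

    def test_learns_separable_toy_problem(self):
        X, y = _toy_training_set(n_per_state=30, seed=4)
        cfg = NetConfig(input_len=64, filters_per_stage=[8], dilations=[1, 2],
                        kernel_size=2, dropout_rate=0.0, seed=0,
                        epochs=40, batch_size=8,
                        stop_train_acc=0.95, val_fraction=0.0)
        model = build_model(cfg)
        _, history = train(model, X, y, cfg)
        assert history["train_acc"][-1] > 1 / 3
        pred = model.predict_states(X)
        assert np.mean(pred == y) >= 0.8

    def test_prototype_classified_after_training(self):
        """An archetypal high-amplitude input lands in the fatigue class."""
        X, y = _toy_training_set(n_per_state=30, seed=4)
        cfg = NetConfig(input_len=64, filters_per_stage=[8], dilations=[1, 2],
                        kernel_size=2, dropout_rate=0.0, seed=0,
                        epochs=40, batch_size=8,
                        stop_train_acc=0.95, val_fraction=0.0)
        model = build_model(cfg)
        train(model, X, y, cfg)
        proto = 3.0 * np.sin(2 * np.pi * np.arange(64) / 16).astype(np.float32)
        probs = predict_proba(model, proto)
        assert probs.argmax_state == 1


class TestGradients:
    def test_backprop_matches_finite_differences(self, rng):
        """Analytic gradient of the loss w.r.t. a sample of weights agrees
        with central finite differences on a tiny network."""
        from myofuse._nn import softmax_xent

        cfg = NetConfig(input_len=16, filters_per_stage=[2], dilations=[1, 2],
                        kernel_size=2, dropout_rate=0.0, seed=1)
        model = build_model(cfg)
        for p in model.params():
            # float64 for clean finite differences; jitter the zero-init
            # biases so no pre-activation sits exactly on the ReLU kink
            p.value = p.value.astype(np.float64)
            if p.value.ndim == 1:
                p.value = p.value + rng.uniform(0.01, 0.02, p.value.shape)
            p.grad = np.zeros_like(p.value)
        X = rng.standard_normal((3, 16))
        y_idx = np.array([0, 1, 2])

        def loss_value():
            return softmax_xent(model.forward(X), y_idx)[0]

        logits = model.forward(X, train=True)
        _, _, dlogits = softmax_xent(logits, y_idx)
        model.backward(dlogits)

        eps = 1e-6
        checked = 0
        for p in model.params():
            flat = p.value.ravel()
            gflat = p.grad.ravel()
            for idx in range(0, flat.size, max(flat.size // 3, 1)):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss_value()
                flat[idx] = orig - eps
                down = loss_value()
                flat[idx] = orig
                fd = (up - down) / (2 * eps)
                assert gflat[idx] == pytest.approx(fd, rel=1e-3, abs=1e-7)
                checked += 1
        assert checked >= 10
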