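import numpy as np
import pytest

from graintemp.model_zoo import (
    MODEL_NAMES,
    ConvParams,
    LSTMParams,
    SEBlockParams,
    build_model,
    conv1d_forward,
    lstm_cell_forward,
    maxpool1d_forward,
    relu,
    se_block_forward,
    softmax,
)
from graintemp.synthetic_granary import ValidationError


def random_lstm_params(rng, d, h):
    return LSTMParams(
        W_ix=rng.normal(size=(h, d)), W_fx=rng.normal(size=(h, d)),
        W_ox=rng.normal(size=(h, d)), W_cx=rng.normal(size=(h, d)),
        W_ih=rng.normal(size=(h, h)), W_fh=rng.normal(size=(h, h)),
        W_oh=rng.normal(size=(h, h)), W_ch=rng.normal(size=(h, h)),
        b_i=rng.normal(size=h), b_f=rng.normal(size=h),
        b_o=rng.normal(size=h), b_c=rng.normal(size=h),
    )


def scalar_lstm_oracle(x, h_prev, c_prev, p):
    """Independent per-unit evaluation of the gate algebra."""
    h = len(h_prev)
    sig = lambda v: 1.0 / (1.0 + np.exp(-v))
    h_t, c_t = np.zeros(h), np.zeros(h)
    for u in range(h):
        i = sig(np.dot(p.W_ix[u], x) + np.dot(p.W_ih[u], h_prev) + p.b_i[u])
        f = sig(np.dot(p.W_fx[u], x) + np.dot(p.W_fh[u], h_prev) + p.b_f[u])
        o = sig(np.dot(p.W_ox[u], x) + np.dot(p.W_oh[u], h_prev) + p.b_o[u])
        c_tilde = np.tanh(np.dot(p.W_cx[u], x) + np.dot(p.W_ch[u], h_prev) + p.b_c[u])
        c_t[u] = f * c_prev[u] + i * c_tilde
        h_t[u] = o * np.tanh(c_t[u])
    return h_t, c_t


def scalar_se_oracle(u, p):
    """Independent per-channel evaluation of squeeze/excite/scale."""
    C, T = u.shape
    z = np.array([u[c].mean() for c in range(C)])
    a = np.maximum(0.0, p.W1 @ z)
    s = 1.0 / (1.0 + np.exp(-(p.W2 @ a)))
    return u * s[:, None], s


class TestLSTMCell:
    def test_zero_weights_zero_state_gives_zeros(self, rng):
        p = random_lstm_params(rng, 3, 4)
        zero = LSTMParams(**{
            k: np.zeros_like(getattr(p, k))
            for k in ("W_ix W_fx W_ox W_cx W_ih W_fh W_oh W_ch b_i b_f b_o b_c".split())
        })
        h, c = lstm_cell_forward(np.ones(3), np.zeros(4), np.zeros(4), zero)
        np.testing.assert_array_equal(h, 0.0)
        np.testing.assert_array_equal(c, 0.0)

    def test_zero_weights_halve_previous_cell_state(self, rng):
        p = random_lstm_params(rng, 2, 3)
        zero = LSTMParams(**{
            k: np.zeros_like(getattr(p, k))
            for k in ("W_ix W_fx W_ox W_cx W_ih W_fh W_oh W_ch b_i b_f b_o b_c".split())
        })
        c_prev = np.array([1.0, -2.0, 0.5])
        h, c = lstm_cell_forward(np.zeros(2), np.zeros(3), c_prev, zero)
        np.testing.assert_allclose(c, 0.5 * c_prev)
        np.testing.assert_allclose(h, 0.5 * np.tanh(0.5 * c_prev))

    def test_matches_scalar_loop_oracle(self, rng):
        for _ in range(100):
            d, h = rng.integers(1, 5), rng.integers(1, 6)
            p = random_lstm_params(rng, d, h)
            x = rng.normal(size=d)
            h_prev, c_prev = rng.normal(size=h), rng.normal(size=h)
            got_h, got_c = lstm_cell_forward(x, h_prev, c_prev, p)
            exp_h, exp_c = scalar_lstm_oracle(x, h_prev, c_prev, p)
            np.testing.assert_allclose(got_h, exp_h, rtol=1e-9, atol=1e-12)
            np.testing.assert_allclose(got_c, exp_c, rtol=1e-9, atol=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValidationError):
            LSTMParams(**{
                **{k: rng.normal(size=(3, 2)) for k in ("W_ix", "W_fx", "W_ox", "W_cx")},
                **{k: rng.normal(size=(3, 3)) for k in ("W_ih", "W_fh", "W_oh")},
                "W_ch": rng.normal(size=(2, 3)),
                **{k: rng.normal(size=3) for k in ("b_i", "b_f", "b_o", "b_c")},
            })


class TestConvPoolRelu:
    def test_identity_kernel(self):
        p = ConvParams(weights=np.ones((1, 1, 1)), biases=np.zeros(1))
        np.testing.assert_array_equal(conv1d_forward(np.arange(5.0), p), np.arange(5.0))

    def test_hand_cross_correlation(self):
        p = ConvParams(weights=np.array([[[1.0, -1.0]]]), biases=np.zeros(1))
        np.testing.assert_allclose(
            conv1d_forward(np.array([1.0, 2.0, 3.0, 4.0]), p), [-1, -1, -1]
        )

    def test_bias_and_multichannel_output_length(self, rng):
        p = ConvParams(weights=rng.normal(size=(5, 2, 3)), biases=rng.normal(size=5))
        out = conv1d_forward(rng.normal(size=(2, 10)), p)
        assert out.shape == (5, 8)

    def test_maxpool_and_relu_direct_definitions(self):
        np.testing.assert_array_equal(
            maxpool1d_forward(np.array([3.0, 1, 4, 1, 5, 9]), 2), [3, 4, 9]
        )
        np.testing.assert_array_equal(relu(np.array([-1.0, 2.0])), [0, 2])

    def test_maxpool_truncates_remainder(self):
        np.testing.assert_array_equal(
            maxpool1d_forward(np.array([1.0, 2, 3, 4, 5]), 2), [2, 4]
        )

    def test_input_shorter_than_kernel_rejected(self):
        p = ConvParams(weights=np.ones((1, 1, 4)), biases=np.zeros(1))
        with pytest.raises(ValidationError):
            conv1d_forward(np.arange(3.0), p)


class TestSEBlock:
    def test_zero_weights_scale_everything_by_half(self, rng):
        p = SEBlockParams(W1=np.zeros((2, 4)), W2=np.zeros((4, 2)))
        u = rng.normal(size=(4, 6))
        np.testing.assert_allclose(se_block_forward(u, p), 0.5 * u)

    def test_constant_channel_squeezes_to_its_value(self):
        # checked through the scalar oracle: z_c is the plain channel mean
        u = np.vstack([np.full(5, 3.0), np.full(5, -1.0)])
        p = SEBlockParams(W1=np.zeros((1, 2)), W2=np.zeros((2, 1)))
        _, s = scalar_se_oracle(u, p)
        out = se_block_forward(u, p)
        np.testing.assert_allclose(out, u * s[:, None])

    def test_matches_scalar_loop_oracle(self, rng):
        for _ in range(100):
            p = SEBlockParams(W1=rng.normal(size=(2, 4)), W2=rng.normal(size=(4, 2)))
            u = rng.normal(size=(4, 7))
            expected, s = scalar_se_oracle(u, p)
            np.testing.assert_allclose(
                se_block_forward(u, p), expected, rtol=1e-9, atol=1e-12
            )
            assert ((s > 0) & (s < 1)).all()

    def test_indivisible_reduction_rejected(self):
        with pytest.raises(ValidationError):
            SEBlockParams(W1=np.zeros((3, 4)), W2=np.zeros((4, 3)))


def test_softmax_normalizes_and_orders():
    p = softmax(np.array([1.0, 2.0, 3.0]))
    assert p.sum() == pytest.approx(1.0)
    assert p[2] > p[1] > p[0]
    # translation invariance
    np.testing.assert_allclose(p, softmax(np.array([1001.0, 1002.0, 1003.0])))


class TestRegistry:
    def test_unknown_name_rejected(self):
        with pytest.raises(ValidationError):
            build_model("resnet")

    def test_plain_lstm_has_eight_hidden_units(self):
        model = build_model("LSTM")
        assert model.hidden == 8
        assert model.params["lstm.Wh_i"].data.shape == (8, 8)

    def test_hybrid_layers_match_the_reference_structure(self):
        model = build_model("CNN-SE-LSTM")
        layers = {l["type"]: l for l in model.spec.layers}
        assert layers["conv1d"]["channels"] == 64
        assert layers["conv1d"]["kernel"] == 3
        assert layers["conv1d"]["activation"] == "relu"
        assert layers["maxpool"]["pool"] == 2
        lstm_hidden = [l["hidden"] for l in model.spec.layers if l["type"] == "lstm"]
        assert lstm_hidden == [64, 32]
        assert all(l["activation"] == "tanh"
                   for l in model.spec.layers if l["type"] == "lstm")
        assert model.spec.layers[-1] == {"type": "dense", "units": 1,
                                         "activation": "linear"}

    def test_fta_variant_shares_the_architecture(self):
        a = build_model("CNN-SE-LSTM", seed=3)
        b = build_model("FTA-CNN-SE-LSTM", seed=3)
        assert {k: v.data.shape for k, v in a.params.items()} == \
               {k: v.data.shape for k, v in b.params.items()}

    @pytest.mark.parametrize(
        "name,expected",
        [
            # closed forms from the layer shapes, lookback L=10
            ("LSTM", 4 * (1 * 8 + 8 * 8 + 8) + (8 * 1 + 1)),
            ("BP", (10 * 64 + 64) + (64 * 32 + 32) + (32 * 1 + 1)),
            ("GRU", 3 * (1 * 64 + 64 * 64 + 64) + (64 * 1 + 1)),
            ("CNN", (64 * 1 * 3 + 64) + (64 * ((10 - 3 + 1) // 2) * 1 + 1)),
            ("CNN-LSTM",
             (64 * 1 * 3 + 64)
             + 4 * (64 * 64 + 64 * 64 + 64)
             + 4 * (64 * 32 + 32 * 32 + 32)
             + (32 * 1 + 1)),
            ("CNN-SE-LSTM",
             (64 * 1 * 3 + 64)
             + (64 * 16 + 16 * 64)          # SE gate, reduction 4
             + 4 * (64 * 64 + 64 * 64 + 64)
             + 4 * (64 * 32 + 32 * 32 + 32)
             + (32 * 1 + 1)),
            ("LSM", 11),
        ],
    )
    def test_parameter_counts_match_closed_form(self, name, expected):
        assert build_model(name, lookback=10).parameter_count() == expected

    def test_initialization_is_seed_deterministic(self):
        for name in MODEL_NAMES:
            if name == "LSM":
                continue
            a = build_model(name, seed=11)
            b = build_model(name, seed=11)
            c = build_model(name, seed=12)
            for k in a.params:
                np.testing.assert_array_equal(a.params[k].data, b.params[k].data)
            assert any(
                not np.array_equal(a.params[k].data, c.params[k].data) for k in a.params
            )

    def test_every_network_outputs_one_value_per_window(self, rng):
        X = rng.normal(size=(5, 10))
        for name in MODEL_NAMES:
            model = build_model(name, lookback=10, seed=0)
            if name == "LSM":
                model.fit(X, rng.normal(size=5))
            out = model.predict_batch(X)
            assert out.shape == (5,)
            assert np.isfinite(out).all()

    def test_se_between_lstm_placement_runs(self, rng):
        model = build_model("CNN-SE-LSTM", se_position="between_lstm")
        out = model.predict_batch(rng.normal(size=(3, 10)))
        assert out.shape == (3,)


class TestGradients:
    """Finite-difference checks of the autodiff tape through full models."""

    @pytest.mark.parametrize("name", ["LSTM", "CNN-SE-LSTM", "TCN", "GRU"])
    def test_backprop_matches_finite_differences(self, name, rng):
        from graintemp.training_eval import TrainConfig

        model = build_model(name, lookback=10, seed=7)
        X = rng.normal(size=(4, 10))
        y = rng.normal(size=4)

        def loss_value():
            pred = model.forward(X, train=False)
            return float(np.mean((pred.data[:, 0] - y) ** 2))

        pred = model.forward(X, train=False)
        err = pred.reshape(4) - y
        loss = err.square().mean()
        loss.backward()

        eps = 1e-6
        param_rng = np.random.default_rng(0)
        names = sorted(model.params)
        for pname in param_rng.choice(names, size=min(6, len(names)), replace=False):
            t = model.params[pname]
            flat_idx = param_rng.integers(t.data.size)
            idx = np.unravel_index(flat_idx, t.data.shape)
            orig = t.data[idx]
            t.data[idx] = orig + eps
            up = loss_value()
            t.data[idx] = orig - eps
            down = loss_value()
            t.data[idx] = orig
            numeric = (up - down) / (2 * eps)
            assert t.grad[idx] == pytest.approx(numeric, rel=1e-4, abs=1e-7), pname
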