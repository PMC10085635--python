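"""The transformer classifier: encodings, attention, gradients, invariances."""

import numpy as np
import pytest

from grnmotif import (
    ModelConfig,
    MotifTransformer,
    encode_pair,
    positional_encoding,
    scaled_dot_attention,
)
from grnmotif.model import LN_EPS, sigmoid, softmax


def tiny_model(**kw) -> MotifTransformer:
    defaults = dict(window=4, n_heads=2, dropout=0.0, seed=3, d_ff=16, d_hidden=8)
    defaults.update(kw)
    return MotifTransformer(ModelConfig(**defaults))


class TestPositionalEncoding:
    def test_position_zero_channels(self):
        pe = positional_encoding(3, 8)
        np.testing.assert_allclose(pe[0, 0::2], 0.0)
        np.testing.assert_allclose(pe[0, 1::2], 1.0)

    def test_first_even_channel_is_plain_sine(self):
        pe = positional_encoding(4, 8)
        assert pe[1, 0] == pytest.approx(np.sin(1.0))

    @pytest.mark.parametrize("d_pe", [None, 4], ids=["standard", "literal"])
    def test_matches_scalar_double_loop(self, d_pe):
        # oracle: naive elementwise evaluation of the two formulas
        L, d = 4, 6
        pe = positional_encoding(L, d, d_pe=d_pe)
        div = d if d_pe is None else d_pe
        for m in range(L):
            for n in range(d // 2):
                assert pe[m, 2 * n] == pytest.approx(
                    np.sin(m / 10000 ** (2 * n / div))
                )
                assert pe[m, 2 * n + 1] == pytest.approx(
                    np.cos(m / 10000 ** ((2 * n + 1) / div))
                )

    def test_bounded(self):
        pe = positional_encoding(50, 20)
        assert np.all(np.abs(pe) <= 1.0)

    def test_odd_width_rejected(self):
        with pytest.raises(ValueError):
            positional_encoding(3, 7)


class TestAddPositional:
    def test_zero_input_yields_pe_matrix(self):
        model = tiny_model()
        out = model.add_positional(np.zeros((5, 8)))
        np.testing.assert_allclose(out, positional_encoding(5, 8))

    def test_subtracting_pe_recovers_input(self):
        model = tiny_model()
        rng = np.random.default_rng(0)
        seq = rng.normal(size=(6, 8))
        np.testing.assert_allclose(
            model.add_positional(seq) - positional_encoding(6, 8), seq
        )

    def test_pe_depends_only_on_shape(self):
        model = tiny_model()
        a, b = np.zeros((4, 8)), np.ones((4, 8))
        np.testing.assert_allclose(
            model.add_positional(a) + 1.0, model.add_positional(b)
        )

    def test_disabled_is_identity(self):
        model = tiny_model(use_positional=False)
        seq = np.arange(16.0).reshape(2, 8)
        np.testing.assert_array_equal(model.add_positional(seq), seq)


class TestScaledDotAttention:
    def test_constant_values_pass_through(self):
        rng = np.random.default_rng(0)
        Q, K = rng.normal(size=(2, 5, 4))
        V = np.tile([1.0, 2.0, 3.0, 4.0], (5, 1))
        out, _ = scaled_dot_attention(Q, K, V)
        np.testing.assert_allclose(out, V)

    def test_zero_queries_give_uniform_weights(self):
        V = np.arange(20.0).reshape(5, 4)
        out, A = scaled_dot_attention(np.zeros((5, 4)), np.zeros((5, 4)), V)
        np.testing.assert_allclose(A, 1 / 5)
        np.testing.assert_allclose(out, np.tile(V.mean(axis=0), (5, 1)))

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(5)
        Q, K, V = rng.normal(size=(3, 8, 8))
        _, A = scaled_dot_attention(Q, K, V)
        np.testing.assert_allclose(A.sum(axis=-1), 1.0)

    def test_matches_triple_loop_oracle(self):
        # brute-force per-entry evaluation on >= 50 random instances
        rng = np.random.default_rng(12)
        for _ in range(50):
            L, d = int(rng.integers(2, 9)), int(rng.integers(2, 9))
            Q, K, V = rng.normal(size=(3, L, d))
            out, _ = scaled_dot_attention(Q, K, V)
            scale = np.sqrt(d)
            expected = np.empty_like(out)
            for i in range(L):
                logits = np.array(
                    [sum(Q[i, a] * K[j, a] for a in range(d)) / scale for j in range(L)]
                )
                w = np.exp(logits - logits.max())
                w /= w.sum()
                for c in range(d):
                    expected[i, c] = sum(w[j] * V[j, c] for j in range(L))
            np.testing.assert_allclose(out, expected, rtol=1e-5)


class TestEncoderForward:
    def test_shape_preserved_and_deterministic(self):
        model = tiny_model()
        rng = np.random.default_rng(1)
        X = rng.normal(size=(3, 6, 8))
        a = model.encoder_outputs(X)
        b = model.encoder_outputs(X)
        assert a.shape == X.shape
        np.testing.assert_array_equal(a, b)

    def test_layernorm_rows_standardized(self):
        model = tiny_model()
        rng = np.random.default_rng(2)
        X = rng.normal(size=(2, 5, 8))
        _, cache = model._forward(X, training=False)
        x_att = cache["X1"]
        np.testing.assert_allclose(x_att.mean(axis=-1), 0.0, atol=1e-7)
        np.testing.assert_allclose(x_att.var(axis=-1), 1.0, atol=10 * LN_EPS)

    def test_single_head_with_identity_projections_reduces_to_attention(self):
        model = tiny_model(n_heads=1, use_positional=False)
        D = model.config.d_model
        model.params["Wq"] = np.eye(D)[None]
        model.params["Wk"] = np.eye(D)[None]
        model.params["Wv"] = np.eye(D)[None]
        rng = np.random.default_rng(4)
        X = rng.normal(size=(1, 5, D))
        _, cache = model._forward(X, training=False)
        expected, _ = scaled_dot_attention(X[0], X[0], X[0])
        np.testing.assert_allclose(cache["O_h"][0, 0], expected)

    def test_attention_weight_tensor_shape(self):
        model = tiny_model()
        prob, trace = model.forward(
            encode_pair(np.ones(20), np.ones(20), s=4), trace=True
        )
        assert trace.attn_weights.shape == (2, 5, 5)
        np.testing.assert_allclose(trace.attn_weights.sum(axis=-1), 1.0)
        assert 0.0 < prob < 1.0


class TestClassify:
    def test_identical_rows_pool_to_that_row(self):
        model = tiny_model()
        row = np.linspace(-1, 1, 8)
        enc = np.tile(row, (1, 5, 1))
        pooled = enc.mean(axis=1)
        np.testing.assert_allclose(pooled[0], row)

    def test_pooled_vector_matches_loop_mean(self):
        model = tiny_model()
        rng = np.random.default_rng(6)
        pair = encode_pair(rng.random(18), rng.random(18), s=4)
        _, trace = model.forward(pair, trace=True)
        manual = np.array(
            [sum(trace.x_encoder[m, c] for m in range(trace.x_encoder.shape[0]))
             / trace.x_encoder.shape[0]
             for c in range(trace.x_encoder.shape[1])]
        )
        np.testing.assert_allclose(trace.x_average, manual)

    def test_sigmoid_midpoint(self):
        assert sigmoid(np.array([0.0]))[0] == pytest.approx(0.5)


class TestForward:
    def test_seeded_init_reproducible(self):
        pair = encode_pair(np.arange(20.0), np.arange(20.0)[::-1], s=4)
        p1 = tiny_model(seed=9).forward(pair)
        p2 = tiny_model(seed=9).forward(pair)
        assert p1 == p2

    def test_direction_changes_probability(self):
        model = tiny_model()
        rng = np.random.default_rng(8)
        xa, xb = rng.random((2, 20))
        assert model.forward(encode_pair(xa, xb, 4)) != model.forward(
            encode_pair(xb, xa, 4)
        )

    def test_batch_equals_single_passes(self):
        model = tiny_model()
        rng = np.random.default_rng(10)
        X = rng.normal(size=(7, 5, 8))
        batch = model.predict_proba(X)
        singles = [model.predict_proba(X[i : i + 1])[0] for i in range(7)]
        np.testing.assert_allclose(batch, singles, rtol=1e-12)

    def test_window_mismatch_rejected(self):
        model = tiny_model()
        with pytest.raises(ValueError, match="window"):
            model.forward(encode_pair(np.ones(20), np.ones(20), s=5))


class TestPermutationEquivariance:
    def _pooled(self, model, X):
        return model.encoder_outputs(X).mean(axis=1)

    def test_invariant_without_positional_encoding(self):
        model = tiny_model(use_positional=False)
        rng = np.random.default_rng(11)
        X = rng.normal(size=(1, 6, 8))
        perm = rng.permutation(6)
        np.testing.assert_allclose(
            self._pooled(model, X), self._pooled(model, X[:, perm]), rtol=1e-9
        )

    def test_broken_with_positional_encoding(self):
        model = tiny_model(use_positional=True)
        rng = np.random.default_rng(11)
        X = rng.normal(size=(1, 6, 8))
        perm = np.array([1, 0, 3, 2, 5, 4])
        assert not np.allclose(
            self._pooled(model, X), self._pooled(model, X[:, perm])
        )


class TestGradients:
    @pytest.mark.parametrize(
        "mode",
        ["default", "literal", "no_pe"],
    )
    def test_analytic_gradients_match_finite_differences(self, mode):
        kw = {}
        if mode == "literal":
            kw = dict(literal_scale=True, literal_pe=True, literal_no_post_ln=True)
        elif mode == "no_pe":
            kw = dict(use_positional=False)
        model = tiny_model(window=3, d_ff=8, d_hidden=6, **kw)
        rng = np.random.default_rng(13)
        X = rng.normal(size=(4, 4, 6))
        y = np.array([1.0, 0.0, 1.0, 0.0])
        loss, grads, _ = model.loss_and_grads(X, y, training=False)
        eps = 1e-6
        for name, p in model.params.items():
            for _ in range(3):
                ix = tuple(int(rng.integers(0, s)) for s in p.shape)
                orig = p[ix]
                p[ix] = orig + eps
                lp, _, _ = model.loss_and_grads(X, y, training=False)
                p[ix] = orig - eps
                lm, _, _ = model.loss_and_grads(X, y, training=False)
                p[ix] = orig
                num = (lp - lm) / (2 * eps)
                assert grads[name][ix] == pytest.approx(num, rel=1e-4, abs=1e-7), name


class TestConfig:
    def test_d_model_is_twice_window(self):
        assert ModelConfig(window=7, n_heads=2).d_model == 14

    def test_head_divisibility_enforced(self):
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(window=3, n_heads=4)

    def test_single_encoder_layer_only(self):
        with pytest.raises(ValueError):
            ModelConfig(window=4, n_encoder_layers=2)

    def test_default_architecture(self):
        cfg = ModelConfig()
        assert cfg.n_heads == 2 and cfg.n_encoder_layers == 1


class TestCheckpoint:
    def test_round_trip_and_window_guard(self, tmp_path):
        model = tiny_model()
        path = tmp_path / "ckpt.npz"
        model.save(path, fingerprint="abc")
        loaded = MotifTransformer.load(path, expect_window=4)
        pair = encode_pair(np.arange(20.0), np.ones(20), s=4)
        assert loaded.forward(pair) == model.forward(pair)
        with pytest.raises(ValueError, match="window"):
            MotifTransformer.load(path, expect_window=8)
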