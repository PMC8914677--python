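"""Transformer core: normalization, attention, FFN, blocks, init, forward,
parameter counting and checkpoints — each checked against an independent
straight-line or brute-force oracle."""

import numpy as np
import pytest
from scipy.stats import truncnorm

from harformer.datasets import SignalWindow
from harformer.model import (
    AttentionParams,
    AttentionRecord,
    EncoderBlockParams,
    FFNParams,
    ModelConfig,
    NormalizerState,
    apply_normalizer,
    backward,
    count_parameters,
    encoder_block,
    fit_normalizer,
    forward,
    forward_with_cache,
    init_params,
    load_checkpoint,
    multi_head_attention,
    position_wise_ffn,
    save_checkpoint,
    scaled_dot_product_attention,
)
from harformer.training import smoothed_cross_entropy

TINY = ModelConfig(
    n_steps=6, n_channels=3, n_classes=4, d_model=8, d_ff=12, n_heads=2,
    n_layers=2, dropout_rate=0.0, attention_dropout_rate=0.0,
)


class TestNormalizer:
    def test_two_point_standardization(self):
        x = np.array([[[1.0], [3.0]]])  # one window, T=2, C=1
        state = fit_normalizer(x)
        assert state.mean[0] == pytest.approx(2.0)
        assert state.std[0] == pytest.approx(1.0)
        out = apply_normalizer(state, x[0])
        assert out[:, 0] == pytest.approx([-1.0, 1.0], abs=1e-5)

    def test_constant_channel_maps_to_zero(self):
        x = np.full((1, 5, 2), 7.0)
        state = fit_normalizer(x)
        assert np.all(apply_normalizer(state, x[0]) == 0.0)

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.normal(3.0, 2.5, size=(4, 10, 3))
        state = fit_normalizer(x)
        pooled = x.reshape(-1, 3)
        mu = pooled.sum(axis=0) / len(pooled)
        sd = np.sqrt(((pooled - mu) ** 2).sum(axis=0) / len(pooled))
        assert state.mean == pytest.approx(mu, abs=1e-9)
        assert state.std == pytest.approx(sd, abs=1e-9)
        normed = (pooled - state.mean) / (state.std + state.epsilon)
        assert normed.mean(axis=0) == pytest.approx(np.zeros(3), abs=1e-6)
        assert normed.std(axis=0) == pytest.approx(np.ones(3), abs=1e-4)

    def test_identity_and_centering_cases(self):
        ident = NormalizerState(np.zeros(2), np.ones(2), epsilon=1e-12)
        x = np.array([[1.0, -2.0]])
        assert apply_normalizer(ident, x) == pytest.approx(x, abs=1e-9)
        center = NormalizerState(np.array([5.0, 0.0]), np.array([2.0, 1.0]))
        assert apply_normalizer(center, np.array([[5.0, 0.0]]))[0, 0] == 0.0

    def test_errors(self):
        with pytest.raises(ValueError):
            fit_normalizer(np.zeros((0, 4, 2)))
        state = NormalizerState(np.zeros(3), np.ones(3))
        with pytest.raises(ValueError):
            apply_normalizer(state, np.zeros((4, 2)))


class TestScaledDotProductAttention:
    def test_singleton_sequence(self):
        out, w = scaled_dot_product_attention([[1.0]], [[1.0]], [[42.0]])
        assert w == pytest.approx(np.array([[1.0]]))
        assert out == pytest.approx(np.array([[42.0]]))

    def test_identical_keys_give_uniform_rows(self):
        k = np.ones((4, 3))
        q = np.random.default_rng(0).normal(size=(4, 3))
        v = np.arange(8.0).reshape(4, 2)
        out, w = scaled_dot_product_attention(q, k, v)
        assert w == pytest.approx(np.full((4, 4), 0.25))
        assert out == pytest.approx(np.tile(v.mean(axis=0), (4, 1)))

    def test_hand_computed_two_step_case(self):
        out, w = scaled_dot_product_attention(
            [[1.0], [0.0]], [[1.0], [0.0]], [[2.0], [4.0]]
        )
        assert w[0] == pytest.approx([0.7311, 0.2689], abs=1e-4)
        assert out[0, 0] == pytest.approx(2.5378, abs=1e-4)

    def test_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(7)
        for t, d in [(2, 1), (5, 3), (8, 8)]:
            q, k = rng.normal(size=(2, t, d))
            v = rng.normal(size=(t, d))
            out, w = scaled_dot_product_attention(q, k, v)
            # brute force, one scalar at a time
            scores = np.empty((t, t))
            for i in range(t):
                for j in range(t):
                    scores[i, j] = sum(q[i, a] * k[j, a] for a in range(d)) / np.sqrt(d)
            for i in range(t):
                e = np.exp(scores[i] - scores[i].max())
                row = e / e.sum()
                assert w[i] == pytest.approx(row, abs=1e-6)
                for b in range(d):
                    expect = sum(row[j] * v[j, b] for j in range(t))
                    assert out[i, b] == pytest.approx(expect, abs=1e-6)
            assert w.sum(axis=1) == pytest.approx(np.ones(t), abs=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            scaled_dot_product_attention(np.zeros((2, 3)), np.zeros((2, 4)), np.zeros((2, 4)))


class TestMultiHeadAttention:
    def test_single_identity_head_reduces_to_plain_attention(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(5, 4))
        eye = np.eye(4)
        params = AttentionParams(eye, eye, eye, eye, n_heads=1)
        y, records = multi_head_attention(x, params)
        expect, w = scaled_dot_product_attention(x, x, x)
        assert y == pytest.approx(expect, abs=1e-12)
        assert records[0].matrix == pytest.approx(w, abs=1e-12)

    def test_matches_loop_over_heads_oracle(self):
        rng = np.random.default_rng(1)
        t, d, h = 6, 4, 2
        x = rng.normal(size=(t, d))
        params = AttentionParams(
            *[rng.normal(0, 0.5, size=(d, d)) for _ in range(4)], n_heads=h
        )
        y, records = multi_head_attention(x, params)
        heads = []
        for i in range(h):
            s = params.head_slice(i)
            out, w = scaled_dot_product_attention(
                x @ params.w_query[:, s], x @ params.w_key[:, s],
                x @ params.w_value[:, s],
            )
            heads.append(out)
            assert records[i].matrix == pytest.approx(w, abs=1e-6)
        expect = np.concatenate(heads, axis=1) @ params.w_output
        assert y == pytest.approx(expect, abs=1e-6)

    def test_output_shape_and_row_sums(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(7, 8))
        params = AttentionParams(
            *[rng.normal(0, 0.2, size=(8, 8)) for _ in range(4)], n_heads=4
        )
        y, records = multi_head_attention(x, params)
        assert y.shape == (7, 8)
        for rec in records:
            assert rec.matrix.sum(axis=1) == pytest.approx(np.ones(7), abs=1e-5)
            assert np.all((rec.matrix >= 0) & (rec.matrix <= 1))


class TestPositionWiseFFN:
    def test_zero_weights_give_b2(self):
        params = FFNParams(
            np.zeros((3, 5)), np.zeros(5), np.zeros((5, 3)), np.array([1.0, 2.0, 3.0])
        )
        out = position_wise_ffn(np.random.default_rng(0).normal(size=(4, 3)), params)
        assert out == pytest.approx(np.tile([1.0, 2.0, 3.0], (4, 1)))

    def test_relu_hand_case(self):
        # pre-activation (-1, 2); relu keeps (0, 2); W2 passes through
        params = FFNParams(np.eye(2), np.zeros(2), np.eye(2), np.zeros(2))
        out = position_wise_ffn(np.array([[-1.0, 2.0]]), params, activation="relu")
        assert out == pytest.approx(np.array([[0.0, 2.0]]))

    def test_timestep_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        params = FFNParams(
            rng.normal(size=(4, 6)), rng.normal(size=6),
            rng.normal(size=(6, 4)), rng.normal(size=4),
        )
        x = rng.normal(size=(5, 4))
        perm = rng.permutation(5)
        assert position_wise_ffn(x, params)[perm] == pytest.approx(
            position_wise_ffn(x[perm], params), abs=1e-12
        )


def _zeroed_sublayer_block(d, d_ff, h, rng):
    return EncoderBlockParams(
        ln1_gain=np.ones(d), ln1_bias=np.zeros(d),
        attn=AttentionParams(
            rng.normal(size=(d, d)), rng.normal(size=(d, d)),
            rng.normal(size=(d, d)), np.zeros((d, d)), n_heads=h,
        ),
        ln2_gain=np.ones(d), ln2_bias=np.zeros(d),
        ffn=FFNParams(
            rng.normal(size=(d, d_ff)), rng.normal(size=d_ff),
            np.zeros((d_ff, d)), np.zeros(d),
        ),
    )


class TestEncoderBlock:
    def test_zeroed_sublayers_make_identity(self):
        rng = np.random.default_rng(0)
        block = _zeroed_sublayer_block(4, 6, 2, rng)
        x = rng.normal(size=(5, 4))
        y, _ = encoder_block(x, block)
        assert np.array_equal(y, x)  # exact

    def test_matches_straight_line_composition(self):
        from harformer.model import _layer_norm

        rng = np.random.default_rng(4)
        d, h = 4, 2
        block = EncoderBlockParams(
            ln1_gain=rng.normal(1, 0.1, d), ln1_bias=rng.normal(0, 0.1, d),
            attn=AttentionParams(
                *[rng.normal(0, 0.4, size=(d, d)) for _ in range(4)], n_heads=h
            ),
            ln2_gain=rng.normal(1, 0.1, d), ln2_bias=rng.normal(0, 0.1, d),
            ffn=FFNParams(
                rng.normal(size=(d, 6)), rng.normal(size=6),
                rng.normal(size=(6, d)), rng.normal(size=d),
            ),
        )
        x = rng.normal(size=(5, d))
        y, _ = encoder_block(x, block, activation="gelu")
        ln1, _ = _layer_norm(x, block.ln1_gain, block.ln1_bias)
        u = x + multi_head_attention(ln1, block.attn)[0]
        ln2, _ = _layer_norm(u, block.ln2_gain, block.ln2_bias)
        expect = u + position_wise_ffn(ln2, block.ffn, "gelu")
        assert y == pytest.approx(expect, abs=1e-12)

    def test_output_shape(self):
        rng = np.random.default_rng(5)
        block = _zeroed_sublayer_block(8, 12, 4, rng)
        assert encoder_block(rng.normal(size=(6, 8)), block)[0].shape == (6, 8)


class TestInit:
    def test_same_seed_is_bit_identical(self):
        a, b = init_params(TINY, seed=42), init_params(TINY, seed=42)
        for (na, ta), (_, tb) in zip(a.named_tensors(), b.named_tensors()):
            assert np.array_equal(ta, tb), na

    def test_weights_within_truncation_bounds(self):
        params = init_params(TINY, seed=0)
        for name, tensor in params.named_tensors():
            if "gain" in name or "bias" in name:
                continue
            assert np.all(np.abs(tensor) <= 0.04 + 1e-12), name

    def test_biases_zero_and_gains_one(self):
        params = init_params(TINY, seed=0)
        for name, tensor in params.named_tensors():
            if "bias" in name:
                assert np.all(tensor == 0.0), name
            if "gain" in name:
                assert np.all(tensor == 1.0), name

    def test_empirical_sd_matches_truncated_normal(self):
        big = ModelConfig(
            n_steps=4, n_channels=2, n_classes=2, d_model=96, d_ff=512,
            n_heads=2, n_layers=2,
        )
        params = init_params(big, seed=1)
        draws = np.concatenate(
            [t.ravel() for n, t in params.named_tensors()
             if "gain" not in n and "bias" not in n]
        )
        assert len(draws) > 1e5
        expected_sd = truncnorm.std(-2, 2, loc=0, scale=0.02)
        assert draws.std() == pytest.approx(expected_sd, rel=0.05)


class TestForward:
    def test_full_scale_logit_shape(self):
        config = ModelConfig()  # 300 steps, 18 classes
        params = init_params(config, seed=0)
        logits = forward(np.zeros((300, 6)), params)
        assert logits.shape == (300, 18)

    def test_eval_mode_is_deterministic(self):
        params = init_params(TINY, seed=0)
        x = np.random.default_rng(0).normal(size=(6, 3))
        assert np.array_equal(forward(x, params), forward(x, params))

    def test_attention_rows_sum_to_one_everywhere(self):
        params = init_params(TINY, seed=0)
        x = np.random.default_rng(1).normal(size=(6, 3))
        _, records = forward(x, params, return_attention=True)
        assert len(records) == TINY.n_layers * TINY.n_heads
        for rec in records:
            assert rec.matrix.sum(axis=1) == pytest.approx(np.ones(6), abs=1e-5)

    def test_accepts_signal_window_and_batches(self):
        params = init_params(TINY, seed=0)
        w = SignalWindow(np.zeros((6, 3)), np.zeros(6, int), "w")
        assert forward(w, params).shape == (6, 4)
        assert forward(np.zeros((5, 6, 3)), params).shape == (5, 6, 4)

    def test_zero_position_embedding_is_permutation_equivariant(self):
        params = init_params(TINY, seed=0)
        params.position_embedding[...] = 0.0
        rng = np.random.default_rng(2)
        x = rng.normal(size=(6, 3))
        perm = rng.permutation(6)
        assert forward(x, params)[perm] == pytest.approx(
            forward(x[perm], params), abs=1e-10
        )

    def test_position_embedding_breaks_equivariance(self):
        params = init_params(TINY, seed=0)
        params.position_embedding[...] = np.random.default_rng(3).normal(
            0, 1.0, params.position_embedding.shape
        )
        rng = np.random.default_rng(4)
        x = rng.normal(size=(6, 3))
        perm = np.roll(np.arange(6), 1)
        assert not np.allclose(forward(x, params)[perm], forward(x[perm], params))

    def test_shape_mismatch_rejected(self):
        params = init_params(TINY, seed=0)
        with pytest.raises(ValueError):
            forward(np.zeros((7, 3)), params)


class TestBackward:
    def test_gradients_match_finite_differences(self):
        """Analytic reverse pass vs central differences on every tensor."""
        rng = np.random.default_rng(0)
        params = init_params(TINY, seed=1)
        for name, a in params.named_tensors():
            if "gain" not in name:
                a += rng.normal(0, 0.3, a.shape)
        x = rng.normal(size=(3, 6, 3))
        y = rng.integers(0, 4, (3, 6))

        logits, cache, _ = forward_with_cache(x, params, training=False, rng=None)
        _, dlogits = smoothed_cross_entropy(logits, y, 0.1, return_grad=True)
        grads = backward(dlogits, params, cache)

        eps = 1e-6
        for name, tensor in params.named_tensors():
            idx = tuple(rng.integers(0, s) for s in tensor.shape)
            orig = tensor[idx]
            tensor[idx] = orig + eps
            up = smoothed_cross_entropy(
                forward_with_cache(x, params, False, None)[0], y, 0.1
            )
            tensor[idx] = orig - eps
            down = smoothed_cross_entropy(
                forward_with_cache(x, params, False, None)[0], y, 0.1
            )
            tensor[idx] = orig
            fd = (up - down) / (2 * eps)
            assert grads[name][idx] == pytest.approx(fd, abs=1e-7, rel=1e-4), name


class TestParameterCount:
    @staticmethod
    def _hand_count(cfg):
        d, t, c, k = cfg.d_model, cfg.n_steps, cfg.n_channels, cfg.n_classes
        inner = (d // cfg.n_heads) * cfg.n_heads
        per_block = 4 * d * inner + 2 * (d * cfg.d_ff) + cfg.d_ff + d + 4 * d
        return c * d + d + t * d + cfg.n_layers * per_block + 2 * d + d * k + k

    def test_toy_config_matches_shape_arithmetic(self):
        cfg = ModelConfig(
            n_steps=6, n_channels=2, n_classes=3, d_model=4, d_ff=8,
            n_heads=2, n_layers=1,
        )
        assert count_parameters(init_params(cfg, 0)) == self._hand_count(cfg)

    def test_monotone_in_layers_and_ff_delta(self):
        base = dict(n_steps=6, n_channels=2, n_classes=3, d_model=4, n_heads=2)
        c1 = ModelConfig(d_ff=8, n_layers=1, **base)
        c2 = ModelConfig(d_ff=8, n_layers=2, **base)
        c3 = ModelConfig(d_ff=16, n_layers=1, **base)
        n1, n2, n3 = (count_parameters(init_params(c, 0)) for c in (c1, c2, c3))
        assert n2 > n1
        # doubling d_ff adds exactly L * (2 d * d_ff + d_ff) extra scalars
        assert n3 - n1 == 2 * 4 * 8 + 8


class TestCheckpoint:
    def test_bit_exact_round_trip(self, tmp_path):
        params = init_params(TINY, seed=9)
        params.normalizer = NormalizerState(
            np.array([0.1, -0.2, 3.0]), np.array([1.0, 2.0, 0.5]), epsilon=1e-5
        )
        path = tmp_path / "model.npz"
        save_checkpoint(params, path)
        back = load_checkpoint(path)
        assert back.config == params.config
        for (name, a), (_, b) in zip(params.named_tensors(), back.named_tensors()):
            assert np.array_equal(a, b), name
        assert np.array_equal(back.normalizer.mean, params.normalizer.mean)
        assert np.array_equal(back.normalizer.std, params.normalizer.std)
        assert back.normalizer.epsilon == params.normalizer.epsilon


class TestAttentionRecord:
    def test_rejects_unnormalized_rows(self):
        with pytest.raises(ValueError):
            AttentionRecord(0, 0, np.array([[0.5, 0.2], [0.5, 0.5]]))

    def test_accepts_valid_matrix(self):
        rec = AttentionRecord(1, 2, np.array([[0.25, 0.75], [1.0, 0.0]]))
        assert rec.layer == 1 and rec.head == 2
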