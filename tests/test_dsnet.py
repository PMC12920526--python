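"""Encoder contracts: gate equations, attention normalization, fusion,
forward shapes and the variant algebra."""

import numpy as np
import pytest

from dsfusion.autodiff import Tensor
from dsfusion.dsnet import (LSTMState, ModelConfig, causal_contexts,
                            encode_stream, forward, fuse, init_params,
                            lstm_step, temporal_attention)


def _zero_state(hidden):
    return LSTMState(h=Tensor(np.zeros(hidden)), c=Tensor(np.zeros(hidden)))


class TestLSTMStep:
    def test_zero_weights_give_zero_state(self):
        hidden, d = 3, 2
        Wx = Tensor(np.zeros((d, 4 * hidden)))
        Wh = Tensor(np.zeros((hidden, 4 * hidden)))
        b = Tensor(np.zeros(4 * hidden))
        out = lstm_step(Tensor(np.ones(d)), _zero_state(hidden), Wx, Wh, b)
        assert np.allclose(out.h.data, 0)
        assert np.allclose(out.c.data, 0)

    def test_saturated_gates_freeze_cell(self):
        # forget gate ~1 (huge bias), input gate ~0: c carries through
        hidden, d = 2, 2
        b = np.zeros(4 * hidden)
        b[0:hidden] = -30.0  # input gate -> 0
        b[hidden:2 * hidden] = +30.0  # forget gate -> 1
        Wx = Tensor(np.zeros((d, 4 * hidden)))
        Wh = Tensor(np.zeros((hidden, 4 * hidden)))
        state = LSTMState(h=Tensor(np.zeros(hidden)),
                          c=Tensor(np.array([0.7, -1.3])))
        out = lstm_step(Tensor(np.ones(d)), state, Wx, Wh, Tensor(b))
        assert np.allclose(out.c.data, [0.7, -1.3], atol=1e-10)

    def test_single_unit_matches_hand_computation(self):
        # one unit, hand-set scalars: evaluate the four gates explicitly
        wx = np.array([[0.5, -0.3, 0.8, 0.2]])  # (i, f, g, o) columns
        wh = np.array([[0.1, 0.4, -0.2, 0.3]])
        b = np.array([0.05, -0.1, 0.2, 0.0])
        x, h0, c0 = 0.7, 0.2, -0.4

        def sig(v):
            return 1 / (1 + np.exp(-v))

        i = sig(x * 0.5 + h0 * 0.1 + 0.05)
        f = sig(x * -0.3 + h0 * 0.4 - 0.1)
        g = np.tanh(x * 0.8 + h0 * -0.2 + 0.2)
        o = sig(x * 0.2 + h0 * 0.3 + 0.0)
        c1 = f * c0 + i * g
        h1 = o * np.tanh(c1)

        out = lstm_step(Tensor([x]),
                        LSTMState(h=Tensor([h0]), c=Tensor([c0])),
                        Tensor(wx), Tensor(wh), Tensor(b))
        assert out.c.data[0] == pytest.approx(c1, abs=1e-12)
        assert out.h.data[0] == pytest.approx(h1, abs=1e-12)


class TestEncodeStream:
    def test_single_step_equals_one_lstm_step(self):
        cfg = ModelConfig(kinematic_dim=3, physiological_dim=3, n_joints=1,
                          n_emg=1, hidden_size=4, attention_dim=2,
                          fusion_dim=2)
        params = init_params(cfg, seed=0)
        x = np.random.default_rng(0).normal(size=(1, 3))
        H, finals = encode_stream(x, params, "kin", 4)
        step = lstm_step(Tensor(x[0]), _zero_state(4), params["kin.l0.Wx"],
                         params["kin.l0.Wh"], params["kin.l0.b"])
        assert np.allclose(H.data[0], step.h.data)

    def test_batched_encoding_matches_per_sequence_loop(self):
        rng = np.random.default_rng(5)
        cfg = ModelConfig(kinematic_dim=3, physiological_dim=3, n_joints=1,
                          n_emg=1, hidden_size=6, attention_dim=2,
                          fusion_dim=2)
        params = init_params(cfg, seed=2)
        X = rng.normal(size=(4, 9, 3))  # B=4 sequences
        H_batch, _ = encode_stream(X, params, "kin", 6)
        for b in range(4):
            H_one, _ = encode_stream(X[b], params, "kin", 6)
            assert np.allclose(H_batch.data[b], H_one.data, atol=1e-6)

    def test_recurrence_is_order_sensitive(self):
        rng = np.random.default_rng(1)
        cfg = ModelConfig(kinematic_dim=2, physiological_dim=2, n_joints=1,
                          n_emg=1, hidden_size=3, attention_dim=2,
                          fusion_dim=2)
        params = init_params(cfg, seed=3)
        X = rng.normal(size=(6, 2))
        H_fwd, _ = encode_stream(X, params, "kin", 3)
        H_perm, _ = encode_stream(X[::-1].copy(), params, "kin", 3)
        assert not np.allclose(H_fwd.data[-1], H_perm.data[-1])

    def test_empty_sequence_rejected(self):
        cfg = ModelConfig(kinematic_dim=2, physiological_dim=2, n_joints=1,
                          n_emg=1, hidden_size=3, attention_dim=2,
                          fusion_dim=2)
        params = init_params(cfg, seed=0)
        with pytest.raises(ValueError):
            encode_stream(np.empty((0, 2)), params, "kin", 3)


class TestTemporalAttention:
    def test_single_step_gets_full_weight(self):
        H = Tensor(np.array([[0.3, -0.2]]))
        W, b, u = Tensor(np.eye(2)), Tensor(np.zeros(2)), Tensor([1.0, 1.0])
        alpha, ctx = temporal_attention(H, W, b, u)
        assert np.allclose(alpha.data, [1.0])
        assert np.allclose(ctx.data, H.data[0])

    def test_identical_states_give_uniform_weights(self):
        h = np.array([0.5, -1.0, 0.2])
        H = Tensor(np.tile(h, (6, 1)))
        rng = np.random.default_rng(2)
        W = Tensor(rng.normal(size=(3, 3)))
        b = Tensor(rng.normal(size=3))
        u = Tensor(rng.normal(size=3))
        alpha, ctx = temporal_attention(H, W, b, u)
        assert np.allclose(alpha.data, 1 / 6)
        assert np.allclose(ctx.data, h)

    def test_three_step_hand_computed_softmax(self):
        H = Tensor(np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]))
        W = Tensor(np.array([[0.5, -0.2], [0.3, 0.4]]))
        b = Tensor(np.array([0.1, -0.1]))
        u = Tensor(np.array([0.7, 0.9]))
        scores = np.tanh(H.data @ W.data + b.data) @ u.data
        e = np.exp(scores - scores.max())
        alpha_hand = e / e.sum()
        ctx_hand = alpha_hand @ H.data
        alpha, ctx = temporal_attention(H, W, b, u)
        assert np.allclose(alpha.data, alpha_hand, atol=1e-12)
        assert np.allclose(ctx.data, ctx_hand, atol=1e-12)

    def test_weights_normalized_on_random_inputs(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            T, d = rng.integers(1, 12), rng.integers(1, 6)
            H = Tensor(rng.normal(scale=3.0, size=(T, d)))
            W = Tensor(rng.normal(size=(d, 4)))
            b = Tensor(rng.normal(size=4))
            u = Tensor(rng.normal(size=4))
            alpha, _ = temporal_attention(H, W, b, u)
            assert np.all(alpha.data >= 0)
            assert alpha.data.sum() == pytest.approx(1.0, abs=1e-6)

    def test_causal_uniform_context_is_running_mean(self):
        rng = np.random.default_rng(3)
        H = Tensor(rng.normal(size=(5, 3)))
        C = causal_contexts(H, None, None, None, attentive=False)
        expect = np.cumsum(H.data, axis=0) / np.arange(1, 6)[:, None]
        assert np.allclose(C.data, expect, atol=1e-12)

    def test_causal_attentive_final_context_matches_full_window(self):
        rng = np.random.default_rng(4)
        H = Tensor(rng.normal(size=(6, 3)))
        W = Tensor(rng.normal(size=(3, 3)))
        b = Tensor(rng.normal(size=3))
        u = Tensor(rng.normal(size=3))
        C = causal_contexts(H, W, b, u, attentive=True)
        _, ctx = temporal_attention(H, W, b, u)
        assert np.allclose(C.data[-1], ctx.data, atol=1e-10)


class TestFuse:
    def test_zero_parameters_sigmoid_gives_half(self):
        ctx = Tensor(np.array([1.0, -2.0, 3.0]))
        z = fuse(ctx, Tensor(np.zeros((3, 4))), Tensor(np.zeros(4)),
                 activation="sigmoid")
        assert np.allclose(z.data, 0.5)

    def test_toy_case_matches_hand_computation(self):
        ctx = Tensor(np.array([0.5, -0.5]))
        Wf = Tensor(np.array([[1.0, 0.0], [0.0, 1.0]]))
        bf = Tensor(np.array([0.1, 0.1]))
        z = fuse(ctx, Wf, bf, activation="tanh")
        assert np.allclose(z.data, np.tanh([0.6, -0.4]), atol=1e-12)

    def test_output_dim_is_fusion_dim(self):
        cfg = ModelConfig(kinematic_dim=4, physiological_dim=9, n_joints=2,
                          n_emg=3, hidden_size=5, attention_dim=3,
                          fusion_dim=7)
        params = init_params(cfg, seed=0)
        rng = np.random.default_rng(0)
        bundle = forward(rng.normal(size=(4, 4)), rng.normal(size=(4, 9)),
                         params, cfg)
        assert bundle.z_seq.shape == (4, 7)
        assert bundle.z_global.shape == (7,)


class TestForward:
    def test_shapes_and_determinism(self, tiny_model):
        cfg, params, Xk, Xp, _ = tiny_model
        b1 = forward(Xk, Xp, params, cfg)
        b2 = forward(Xk, Xp, params, cfg)
        T = Xk.shape[0]
        assert b1.y_hat_pose.shape == (T, cfg.n_joints * 3)
        assert b1.y_hat_emg.shape == (T, cfg.n_emg)
        assert b1.y_hat_vel.shape == (T, cfg.vel_dim)
        assert b1.attention.shape == (2, T)
        assert np.array_equal(b1.y_hat_pose.data, b2.y_hat_pose.data)

    def test_attention_rows_sum_to_one(self, tiny_model):
        cfg, params, Xk, Xp, _ = tiny_model
        b = forward(Xk, Xp, params, cfg)
        assert np.allclose(b.attention.data.sum(axis=-1), 1.0, atol=1e-9)

    def test_stream_independence(self, tiny_model):
        cfg, params, Xk, Xp, _ = tiny_model
        from dsfusion.dsnet import encode_stream
        Hk1, _ = encode_stream(Xk, params, "kin", cfg.hidden_size)
        Hk2, _ = encode_stream(Xk, params, "kin", cfg.hidden_size)
        b1 = forward(Xk, Xp, params, cfg)
        b2 = forward(Xk, np.zeros_like(Xp), params, cfg)
        # kinematic hidden states are bit-identical regardless of Xp
        assert np.array_equal(Hk1.data, Hk2.data)
        # but the fused outputs change through the physiological context
        assert not np.allclose(b1.y_hat_vel.data, b2.y_hat_vel.data)

    def test_no_attention_variant_equals_uniformly_frozen_attention(self):
        """With attention frozen uniform the model is mean pooling, which is
        exactly the no-attention variant's context."""
        rng = np.random.default_rng(8)
        base = dict(kinematic_dim=3, physiological_dim=4, n_joints=1,
                    n_emg=2, vel_dim=2, hidden_size=4, attention_dim=3,
                    fusion_dim=3, layer_norm=False)
        cfg_att = ModelConfig(**base, variant="dual_with_attention")
        cfg_uni = ModelConfig(**base, variant="dual_no_attention")
        params = init_params(cfg_att, seed=4)
        # freeze attention scores to constants -> softmax is uniform
        for stream in ("att_kin", "att_phys"):
            params[f"{stream}.W"].data[:] = 0
            params[f"{stream}.u"].data[:] = 0
        Xk, Xp = rng.normal(size=(5, 3)), rng.normal(size=(5, 4))
        b_att = forward(Xk, Xp, params, cfg_att)
        params_uni = {k: v for k, v in params.items()
                      if not k.startswith("att_")}
        b_uni = forward(Xk, Xp, params_uni, cfg_uni)
        assert np.allclose(b_att.y_hat_pose.data, b_uni.y_hat_pose.data,
                           atol=1e-12)
        assert np.allclose(b_att.y_hat_vel.data, b_uni.y_hat_vel.data,
                           atol=1e-12)

    def test_classification_head_emits_probabilities(self):
        cfg = ModelConfig(kinematic_dim=3, physiological_dim=3, n_joints=1,
                          n_emg=1, hidden_size=4, attention_dim=2,
                          fusion_dim=3, n_classes=6)
        params = init_params(cfg, seed=0)
        rng = np.random.default_rng(0)
        b = forward(rng.normal(size=(5, 3)), rng.normal(size=(5, 3)),
                    params, cfg)
        assert b.class_scores.shape == (6,)
        assert b.class_scores.data.sum() == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("variant", ["single_stream",
                                         "single_stream_attention"])
    def test_single_stream_variants_run(self, variant):
        cfg = ModelConfig(kinematic_dim=3, physiological_dim=4, n_joints=1,
                          n_emg=2, hidden_size=4, attention_dim=3,
                          fusion_dim=3, variant=variant)
        params = init_params(cfg, seed=0)
        rng = np.random.default_rng(1)
        b = forward(rng.normal(size=(6, 3)), rng.normal(size=(6, 4)),
                    params, cfg)
        assert b.attention.shape == (1, 6)
        assert b.attention.data.sum() == pytest.approx(1.0, abs=1e-9)
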