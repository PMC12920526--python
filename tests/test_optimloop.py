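"""Optimizer and schedule closed forms, TBPTT segmentation, early stopping,
and a training smoke property."""

import numpy as np
import pytest

from dsfusion.dsnet import ModelConfig
from dsfusion.objectives import LossWeights, TaskTargets
from dsfusion.optimloop import (ClipConfig, EarlyStopper, OptimizerState,
                                ScheduleConfig, TrainConfig, adam_update,
                                clip_gradient, cosine_lr, tbptt_chunks, train)


class TestClipGradient:
    def test_norm_ten_clipped_to_five(self):
        g = np.array([6.0, 8.0])  # norm 10
        out = clip_gradient(g, ClipConfig(C=5.0))
        assert np.linalg.norm(out) == pytest.approx(5.0)
        # direction preserved
        assert np.allclose(out / np.linalg.norm(out), g / 10.0)

    def test_small_gradient_unchanged(self):
        g = np.array([0.3, -0.4])
        assert np.array_equal(clip_gradient(g, ClipConfig(C=5.0)), g)

    def test_zero_gradient_stays_zero(self):
        assert np.array_equal(clip_gradient(np.zeros(4), ClipConfig(C=1.0)),
                              np.zeros(4))

    def test_never_increases_norm(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            g = rng.normal(scale=rng.uniform(0.1, 20), size=5)
            out = clip_gradient(g, ClipConfig(C=2.5))
            assert np.linalg.norm(out) <= np.linalg.norm(g) + 1e-12
            if np.linalg.norm(g) > 0:
                cos = (out @ g) / (np.linalg.norm(out) * np.linalg.norm(g))
                assert cos == pytest.approx(1.0, abs=1e-12)

    def test_non_finite_gradient_rejected(self):
        with pytest.raises(FloatingPointError):
            clip_gradient(np.array([1.0, np.nan]), ClipConfig(C=1.0))


class TestAdam:
    def test_zero_gradient_from_zero_state_keeps_theta(self):
        theta = np.array([1.0, -2.0])
        state = OptimizerState.init(2)
        new, _ = adam_update(theta, np.zeros(2), state)
        assert np.array_equal(new, theta)

    def test_first_step_is_signed_learning_rate(self):
        # with bias correction, t=1: delta = -eta * g / (|g| + eps)
        theta = np.array([0.0])
        state = OptimizerState.init(1, eta=1e-3)
        new, _ = adam_update(theta, np.array([0.37]), state)
        assert new[0] == pytest.approx(-1e-3, rel=1e-6)

    def test_two_steps_match_hand_iterated_recurrences(self):
        beta1, beta2, eps, eta = 0.9, 0.999, 1e-8, 1e-3
        g1, g2 = 0.5, -0.2
        # hand iteration of the printed update rules
        m = v = 0.0
        theta_hand = 1.0
        for t, g in [(1, g1), (2, g2)]:
            m = beta1 * m + (1 - beta1) * g
            v = beta2 * v + (1 - beta2) * g * g
            m_hat = m / (1 - beta1 ** t)
            v_hat = v / (1 - beta2 ** t)
            theta_hand -= eta * m_hat / (np.sqrt(v_hat) + eps)

        theta = np.array([1.0])
        state = OptimizerState.init(1, eta=eta)
        theta, state = adam_update(theta, np.array([g1]), state)
        theta, state = adam_update(theta, np.array([g2]), state)
        assert theta[0] == pytest.approx(theta_hand, abs=1e-15)

    def test_second_moment_nonnegative(self):
        rng = np.random.default_rng(1)
        state = OptimizerState.init(3)
        theta = np.zeros(3)
        for _ in range(20):
            theta, state = adam_update(theta, rng.normal(size=3), state)
            assert np.all(state.v >= 0)


class TestCosineSchedule:
    def test_endpoints(self):
        cfg = ScheduleConfig(eta0=1e-3, eta_min=1e-6, T_max=500)
        assert cosine_lr(0, cfg) == pytest.approx(1e-3)
        assert cosine_lr(500, cfg) == pytest.approx(1e-6)

    def test_midpoint(self):
        cfg = ScheduleConfig(eta0=1e-3, eta_min=1e-6, T_max=500)
        assert cosine_lr(250, cfg) == pytest.approx(5.005e-4, rel=1e-6)

    def test_monotone_nonincreasing_and_bounded(self):
        cfg = ScheduleConfig(eta0=1e-3, eta_min=1e-6, T_max=100)
        lrs = [cosine_lr(t, cfg) for t in range(101)]
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))
        assert all(1e-6 - 1e-15 <= lr <= 1e-3 + 1e-15 for lr in lrs)

    def test_out_of_range_rejected(self):
        cfg = ScheduleConfig(T_max=10)
        with pytest.raises(ValueError):
            cosine_lr(11, cfg)


class TestTBPTT:
    def test_250_with_tau_100_gives_100_100_50(self):
        chunks = tbptt_chunks(250, 100)
        assert [e - s for s, e in chunks] == [100, 100, 50]

    def test_tau_at_least_T_gives_single_segment(self):
        assert tbptt_chunks(30, 100) == [(0, 30)]

    def test_concatenation_reproduces_sequence(self):
        chunks = tbptt_chunks(173, 40)
        covered = np.concatenate([np.arange(s, e) for s, e in chunks])
        assert np.array_equal(covered, np.arange(173))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            tbptt_chunks(0, 10)


class TestEarlyStopping:
    def test_scripted_plateau_stops_patience_epochs_after_minimum(self):
        # losses 5, 4, 3, then flat: best at epoch 2, stop 20 epochs later
        stopper = EarlyStopper(patience=20)
        losses = [5.0, 4.0, 3.0] + [3.0] * 40
        stopped_at = None
        for i, v in enumerate(losses):
            if stopper.update(v):
                stopped_at = i
                break
        assert stopper.best_epoch == 2
        assert stopped_at == 22  # exactly p = 20 epochs after the minimum

    def test_strictly_decreasing_never_stops(self):
        stopper = EarlyStopper(patience=3)
        assert not any(stopper.update(10.0 - i) for i in range(50))

    def test_improvement_below_tolerance_counts_as_stale(self):
        stopper = EarlyStopper(patience=2, tol=1e-6)
        assert not stopper.update(1.0)
        assert not stopper.update(1.0 - 1e-9)  # below tol: stale
        assert stopper.update(1.0 - 2e-9)


class TestTrainLoop:
    @pytest.fixture(scope="class")
    def toy_seqs(self):
        rng = np.random.default_rng(0)
        seqs = []
        for _ in range(4):
            T = 30
            Xk = rng.normal(size=(T, 2))
            Xp = rng.normal(size=(T, 2))
            targets = TaskTargets(
                y_pose=np.cumsum(Xk, axis=0)[:, :1].repeat(3, axis=1) * 0.1,
                y_emg=Xp[:, :1] * 0.5,
                y_vel=Xk[:, :1] * 0.3, action=0)
            seqs.append((Xk, Xp, targets))
        return seqs

    def _cfg(self):
        return ModelConfig(kinematic_dim=2, physiological_dim=2, n_joints=1,
                           n_emg=1, vel_dim=1, hidden_size=4,
                           attention_dim=3, fusion_dim=3)

    def test_seeded_run_repeats_identically(self, toy_seqs):
        kw = dict(train_cfg=TrainConfig(batch_size=2, tau=16, patience=3,
                                        max_epochs=4, seed=5))
        _, h1 = train(self._cfg(), toy_seqs[:3], toy_seqs[3:], **kw)
        _, h2 = train(self._cfg(), toy_seqs[:3], toy_seqs[3:], **kw)
        assert h1.column("val_loss") == h2.column("val_loss")

    def test_training_reduces_loss_on_learnable_task(self, toy_seqs):
        _, hist = train(self._cfg(), toy_seqs[:3], toy_seqs[3:],
                        TrainConfig(batch_size=3, tau=30, patience=20,
                                    max_epochs=25, seed=1))
        losses = hist.column("L_total")
        assert losses[-1] < losses[0]

    def test_history_logs_every_component_and_lr(self, toy_seqs):
        _, hist = train(self._cfg(), toy_seqs[:3], toy_seqs[3:],
                        TrainConfig(batch_size=3, tau=30, patience=2,
                                    max_epochs=2, seed=0))
        row = hist.epochs[0]
        for key in ("L_pose", "L_emg", "L_vel", "L_att", "L_smooth",
                    "L_reg", "L_total", "lr", "grad_norm", "val_loss"):
            assert key in row

    def test_empty_split_rejected(self, toy_seqs):
        with pytest.raises(ValueError):
            train(self._cfg(), [], toy_seqs[3:])


class TestClippingPropertyBased:
    """Clipping invariants over hypothesis-generated gradients."""

    from hypothesis import given, settings, strategies as st

    @staticmethod
    @given(st.lists(st.floats(min_value=-1e6, max_value=1e6,
                              allow_nan=False, allow_infinity=False),
                    min_size=1, max_size=32),
           st.floats(min_value=1e-6, max_value=1e3))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_norm_bounded_and_direction_preserved(g_list, C):
        g = np.array(g_list)
        out = clip_gradient(g, ClipConfig(C=C))
        norm_in, norm_out = np.linalg.norm(g), np.linalg.norm(out)
        assert norm_out <= min(norm_in, C) * (1 + 1e-12) + 1e-300
        if norm_in > 0 and norm_out > 0:
            cos = (out @ g) / (norm_in * norm_out)
            assert cos == pytest.approx(1.0, abs=1e-9)
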