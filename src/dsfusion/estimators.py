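"""Scikit-learn-style estimator facade over the dual-stream model.

:class:`DualStreamRegressor` wraps configuration, training (TBPTT +
clipped Adam + cosine annealing + early stopping) and prediction behind
the familiar ``fit`` / ``predict`` / ``get_params`` surface, so the model
composes with sklearn model-selection utilities.  Samples are sequences:
``fit`` takes a list of ``(Xk, Xp, TaskTargets)`` tuples (one per trial)
rather than a flat design matrix.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .dsnet import ModelConfig, PredictionBundle, forward
from .objectives import LossWeights
from .optimloop import ClipConfig, ScheduleConfig, TrainConfig, train

__all__ = ["DualStreamRegressor"]


class DualStreamRegressor(BaseEstimator):
    """Dual-stream LSTM with temporal attention as an sklearn estimator.

    Parameters mirror the model/optimizer configuration; fitted state
    lives in ``params_`` (the trained parameter dict), ``config_`` and
    ``history_``.

    Example
    -------
    >>> est = DualStreamRegressor(hidden_size=16, max_epochs=5)
    >>> est.fit(train_sequences, val_sequences)  # doctest: +SKIP
    >>> bundles = est.predict(test_sequences)    # doctest: +SKIP
    """

    def __init__(self, hidden_size: int = 64, num_layers: int = 1,
                 attention_dim: int = 32, fusion_dim: int = 32,
                 fusion_activation: str = "tanh", layer_norm: bool = True,
                 variant: str = "dual_with_attention", n_classes: int = 0,
                 batch_size: int = 32, tau: int = 100, patience: int = 20,
                 max_epochs: int = 200, clip_C: float = 5.0,
                 eta0: float = 1e-3, eta_min: float = 1e-6, T_max: int = 500,
                 w_p: float = 1.0, w_e: float = 0.8, w_v: float = 0.8,
                 lambda_att: float = 0.01, lambda_smooth: float = 0.1,
                 lambda_reg: float = 1e-4, w_c: float = 0.0,
                 random_state: int = 0):
        self.hidden_size = hidden_size
        self.num_layers = num_layers
        self.attention_dim = attention_dim
        self.fusion_dim = fusion_dim
        self.fusion_activation = fusion_activation
        self.layer_norm = layer_norm
        self.variant = variant
        self.n_classes = n_classes
        self.batch_size = batch_size
        self.tau = tau
        self.patience = patience
        self.max_epochs = max_epochs
        self.clip_C = clip_C
        self.eta0 = eta0
        self.eta_min = eta_min
        self.T_max = T_max
        self.w_p = w_p
        self.w_e = w_e
        self.w_v = w_v
        self.lambda_att = lambda_att
        self.lambda_smooth = lambda_smooth
        self.lambda_reg = lambda_reg
        self.w_c = w_c
        self.random_state = random_state

    # ------------------------------------------------------------------ fit
    def _configs(self, sample):
        Xk, Xp, targets = sample
        n_joints = targets.y_pose.shape[1] // 3 or 1
        config = ModelConfig(
            kinematic_dim=Xk.shape[1], physiological_dim=Xp.shape[1],
            n_joints=n_joints, n_emg=targets.y_emg.shape[1],
            vel_dim=targets.y_vel.shape[1], n_classes=self.n_classes,
            hidden_size=self.hidden_size, num_layers=self.num_layers,
            attention_dim=self.attention_dim, fusion_dim=self.fusion_dim,
            fusion_activation=self.fusion_activation,
            layer_norm=self.layer_norm, variant=self.variant)
        weights = LossWeights(w_p=self.w_p, w_e=self.w_e, w_v=self.w_v,
                              lambda_att=self.lambda_att,
                              lambda_smooth=self.lambda_smooth,
                              lambda_reg=self.lambda_reg, w_c=self.w_c)
        train_cfg = TrainConfig(batch_size=self.batch_size, tau=self.tau,
                                patience=self.patience,
                                max_epochs=self.max_epochs,
                                seed=self.random_state)
        sched_cfg = ScheduleConfig(eta0=self.eta0, eta_min=self.eta_min,
                                   T_max=self.T_max)
        clip_cfg = ClipConfig(C=self.clip_C)
        return config, weights, train_cfg, sched_cfg, clip_cfg

    def fit(self, sequences, val_sequences=None):
        """Train on `(Xk, Xp, TaskTargets)` tuples.

        If `val_sequences` is omitted, the last max(1, 15%) of the
        training sequences serve as the validation split (they are then
        excluded from gradient updates).
        """
        if not sequences:
            raise ValueError("no training sequences")
        if val_sequences is None:
            n_val = max(1, int(0.15 * len(sequences)))
            if len(sequences) <= n_val:
                raise ValueError("too few sequences to hold out validation")
            val_sequences = sequences[-n_val:]
            sequences = sequences[:-n_val]
        cfg, weights, train_cfg, sched_cfg, clip_cfg = self._configs(
            sequences[0])
        self.config_ = cfg
        self.params_, self.history_ = train(
            cfg, list(sequences), list(val_sequences), train_cfg, sched_cfg,
            clip_cfg, weights, init_seed=self.random_state)
        self.n_epochs_ = len(self.history_.epochs)
        self.best_val_loss_ = self.history_.best_val
        return self

    # -------------------------------------------------------------- predict
    def predict(self, sequences) -> list[PredictionBundle]:
        if not hasattr(self, "params_"):
            raise RuntimeError("estimator is not fitted")
        out = []
        for Xk, Xp, *_ in sequences:
            out.append(forward(Xk, Xp, self.params_, self.config_))
        return out

    def predict_velocity(self, sequences) -> list[np.ndarray]:
        return [b.y_hat_vel.data for b in self.predict(sequences)]
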