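"""Training procedure: TBPTT, gradient clipping, Adam, cosine annealing.

The optimizer is written out from the printed update rules rather than
delegated to a framework:

* global-norm gradient clipping   g~ = g * min(1, C / ||g||_2)
* Adam with bias correction       m_t = b1 m_{t-1} + (1-b1) g_t, ...
                                  theta <- theta - eta m^_t / (sqrt(v^_t)+eps)
* cosine annealing                eta_t = eta_min + (eta0-eta_min)(1+cos(pi t/T_max))/2
* truncated backpropagation through time over contiguous segments of
  length tau with the hidden state carried (detached) across boundaries
* early stopping: training stops when the validation loss has not
  improved (strict decrease by >= 1e-6) for p consecutive epochs, and the
  parameters are rolled back to the best-validation epoch.

Defaults follow the published recipe: B=32, tau=100, C=5.0,
beta=(0.9, 0.999), eps=1e-8, eta0=1e-3, eta_min=1e-6, T_max=500, p=20.
The schedule advances per optimizer step by default (per-epoch stepping
selectable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .dsnet import (ModelConfig, flatten_params, forward, grad_vector,
                    init_params, set_params_from_vector, zero_grads)
from .objectives import LossBreakdown, LossWeights, TaskTargets, total_loss

__all__ = [
    "ClipConfig",
    "OptimizerState",
    "ScheduleConfig",
    "TrainConfig",
    "clip_gradient",
    "adam_update",
    "cosine_lr",
    "tbptt_chunks",
    "train",
    "EarlyStopper",
    "evaluate_split",
    "TrainingHistory",
]


@dataclass
class ClipConfig:
    C: float = 5.0

    def __post_init__(self):
        if self.C <= 0:
            raise ValueError("clipping threshold C must be > 0")


@dataclass
class OptimizerState:
    m: np.ndarray
    v: np.ndarray
    t: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    eta: float = 1e-3

    @classmethod
    def init(cls, n_params: int, **kw) -> "OptimizerState":
        return cls(m=np.zeros(n_params), v=np.zeros(n_params), **kw)


@dataclass
class ScheduleConfig:
    eta0: float = 1e-3
    eta_min: float = 1e-6
    T_max: int = 500
    step_per: str = "step"  # "step" or "epoch"

    def __post_init__(self):
        if self.eta_min > self.eta0:
            raise ValueError("eta_min must be <= eta0")
        if self.T_max < 1:
            raise ValueError("T_max must be >= 1")


@dataclass
class TrainConfig:
    batch_size: int = 32
    tau: int = 100
    patience: int = 20
    max_epochs: int = 200
    seed: int = 0
    improvement_tol: float = 1e-6

    def __post_init__(self):
        if self.batch_size < 1 or self.tau < 1 or self.patience < 1:
            raise ValueError("batch_size, tau and patience must be >= 1")


def clip_gradient(g: np.ndarray, config: ClipConfig) -> np.ndarray:
    """Global-norm clipping; preserves direction, never raises the norm."""
    g = np.asarray(g, dtype=float)
    if not np.all(np.isfinite(g)):
        raise FloatingPointError("non-finite gradient")
    norm = float(np.linalg.norm(g))
    if norm == 0.0 or norm <= config.C:
        return g.copy()
    return g * (config.C / norm)


def adam_update(theta: np.ndarray, g: np.ndarray,
                state: OptimizerState) -> tuple[np.ndarray, OptimizerState]:
    """One bias-corrected Adam step on the flat parameter vector."""
    if theta.shape != g.shape:
        raise ValueError("parameter/gradient shape mismatch")
    t = state.t + 1
    m = state.beta1 * state.m + (1 - state.beta1) * g
    v = state.beta2 * state.v + (1 - state.beta2) * (g * g)
    m_hat = m / (1 - state.beta1 ** t)
    v_hat = v / (1 - state.beta2 ** t)
    theta_new = theta - state.eta * m_hat / (np.sqrt(v_hat) + state.eps)
    new_state = OptimizerState(m=m, v=v, t=t, beta1=state.beta1,
                               beta2=state.beta2, eps=state.eps, eta=state.eta)
    return theta_new, new_state


def cosine_lr(t: int, config: ScheduleConfig) -> float:
    """Half-cosine decay from eta0 to eta_min over T_max steps."""
    if not 0 <= t <= config.T_max:
        raise ValueError(f"step {t} outside [0, {config.T_max}]")
    return config.eta_min + 0.5 * (config.eta0 - config.eta_min) * (
        1 + np.cos(np.pi * t / config.T_max))


def tbptt_chunks(T: int, tau: int) -> list[tuple[int, int]]:
    """Contiguous non-overlapping (start, stop) segments of length tau."""
    if T < 1:
        raise ValueError("empty sequence")
    if tau < 1:
        raise ValueError("tau must be >= 1")
    return [(s, min(s + tau, T)) for s in range(0, T, tau)]


@dataclass
class TrainingHistory:
    epochs: list[dict] = field(default_factory=list)

    def log(self, **kw) -> None:
        self.epochs.append(dict(kw))

    def column(self, key: str) -> list:
        return [e[key] for e in self.epochs]

    def to_csv(self, path) -> None:
        import csv
        if not self.epochs:
            return
        keys = sorted({k for e in self.epochs for k in e})
        with open(path, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=keys)
            w.writeheader()
            for e in self.epochs:
                w.writerow(e)


class EarlyStopper:
    """Stop after `patience` consecutive epochs without strict improvement.

    Improvement means the validation loss drops below the best seen so far
    by at least `tol`.  ``update`` returns True when training should stop;
    ``best_epoch`` indexes the epoch to roll back to.
    """

    def __init__(self, patience: int, tol: float = 1e-6):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.tol = tol
        self.best = np.inf
        self.best_epoch = -1
        self.stale = 0
        self.epoch = -1

    def update(self, val_loss: float) -> bool:
        self.epoch += 1
        if val_loss < self.best - self.tol:
            self.best = val_loss
            self.best_epoch = self.epoch
            self.stale = 0
            return False
        self.stale += 1
        return self.stale >= self.patience


def _detach_states(states: dict) -> dict:
    out = {}
    for key, layer_states in states.items():
        out[key] = [type(s)(h=Tensor(s.h.data.copy()),
                            c=Tensor(s.c.data.copy())) for s in layer_states]
    return out


def evaluate_split(sequences: list, params: dict, config: ModelConfig,
                   weights: LossWeights) -> float:
    """Mean L_total over a split (full-window forward, no gradients)."""
    if not sequences:
        raise ValueError("empty split")
    totals = []
    for Xk, Xp, targets in sequences:
        bundle = forward(Xk, Xp, params, config)
        bd = total_loss(bundle, targets, params, weights)
        totals.append(bd.L_total)
    return float(np.mean(totals))


def train(config: ModelConfig,
          train_seqs: list, val_seqs: list,
          train_cfg: TrainConfig | None = None,
          sched_cfg: ScheduleConfig | None = None,
          clip_cfg: ClipConfig | None = None,
          weights: LossWeights | None = None,
          init_seed: int | None = None,
          ) -> tuple[dict, TrainingHistory]:
    """Fit the model; returns (best parameters, per-epoch history).

    Each element of `train_seqs` / `val_seqs` is a tuple
    ``(Xk, Xp, TaskTargets)`` with arrays on the reference clock.  Within
    an epoch, sequences are processed in mini-batches; each batch is cut
    into TBPTT segments of length tau, the segment loss (batch mean of
    L_total) is backpropagated, the global gradient norm is clipped and
    one Adam step is taken, with the learning rate from the cosine
    schedule.  Hidden states carry across segment boundaries detached.
    """
    train_cfg = train_cfg or TrainConfig()
    sched_cfg = sched_cfg or ScheduleConfig()
    clip_cfg = clip_cfg or ClipConfig()
    weights = weights or LossWeights()
    if not train_seqs or not val_seqs:
        raise ValueError("empty split")
    params = init_params(config, seed=train_cfg.seed
                         if init_seed is None else init_seed)
    opt = OptimizerState.init(flatten_params(params).size)
    history = TrainingHistory()
    rng = np.random.default_rng(train_cfg.seed)

    stopper = EarlyStopper(train_cfg.patience, train_cfg.improvement_tol)
    best_params = None
    global_step = 0

    for epoch in range(train_cfg.max_epochs):
        order = rng.permutation(len(train_seqs))
        epoch_components: list[dict] = []
        grad_norms: list[float] = []
        for b0 in range(0, len(order), train_cfg.batch_size):
            batch = [train_seqs[i] for i in order[b0:b0 + train_cfg.batch_size]]
            T = batch[0][0].shape[0]
            carried = [None] * len(batch)
            for (s, e) in tbptt_chunks(T, train_cfg.tau):
                zero_grads(params)
                breakdowns: list[LossBreakdown] = []
                new_states = []
                for i, (Xk, Xp, targets) in enumerate(batch):
                    bundle = forward(Xk[s:e], Xp[s:e], params, config,
                                     init_states=carried[i])
                    seg_targets = TaskTargets(
                        y_pose=targets.y_pose[s:e],
                        y_emg=targets.y_emg[s:e],
                        y_vel=targets.y_vel[s:e],
                        action=targets.action)
                    bd = total_loss(bundle, seg_targets, params, weights)
                    breakdowns.append(bd)
                    new_states.append(_detach_states(bundle.final_states))
                carried = new_states
                mean_total = breakdowns[0].total_tensor
                for bd in breakdowns[1:]:
                    mean_total = mean_total + bd.total_tensor
                mean_total = mean_total / float(len(breakdowns))
                mean_total.backward()
                g = grad_vector(params)
                g = clip_gradient(g, clip_cfg)
                grad_norms.append(float(np.linalg.norm(g)))
                sched_t = (min(global_step, sched_cfg.T_max)
                           if sched_cfg.step_per == "step"
                           else min(epoch, sched_cfg.T_max))
                opt.eta = cosine_lr(sched_t, sched_cfg)
                theta = flatten_params(params)
                theta, opt = adam_update(theta, g, opt)
                set_params_from_vector(params, theta)
                global_step += 1
                epoch_components.append(
                    {k: v for k, v in breakdowns[0].components().items()})
        val_loss = evaluate_split(val_seqs, params, config, weights)
        mean_comp = {k: float(np.mean([c[k] for c in epoch_components]))
                     for k in epoch_components[0]}
        history.log(epoch=epoch, val_loss=val_loss, lr=opt.eta,
                    grad_norm=float(np.mean(grad_norms)), **mean_comp)
        improved_before = stopper.best_epoch
        stop = stopper.update(val_loss)
        if stopper.best_epoch != improved_before:  # this epoch is the new best
            best_params = {k: Tensor(v.data.copy(), requires_grad=True)
                           for k, v in params.items()}
        if stop:
            break
    if best_params is None:  # no epoch improved on +inf: keep final params
        best_params = params
        stopper.best_epoch = len(history.epochs) - 1
    history.best_epoch = stopper.best_epoch  # type: ignore[attr-defined]
    history.best_val = stopper.best  # type: ignore[attr-defined]
    return best_params, history
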