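"""Multi-task joint loss with entropy and smoothness regularization.

The total training objective combines three per-step regression losses
(pose, EMG, velocity), an attention-entropy regularizer, a first-order
smoothness term on the spliced prediction vector and an L2 penalty:

    L_total = w_p L_pose + w_e L_emg + w_v L_vel
              + lambda_att L_att + lambda_smooth L_smooth
              + lambda_reg ||theta||^2

Each regression loss is a mean squared error normalized by (channels x T)
exactly; the entropy term averages per-head attention entropies
-(1/H) sum_h sum_t a_{h,t} log(a_{h,t} + eps); smoothness is the mean of
squared first differences of the concatenated per-step predictions
(classification scores excluded).  An optional cross-entropy term for the
action-classification head can be added with weight w_c; it is off by
default so the printed composition above holds exactly.

Default weights: w_p = 1.0, w_e = 0.8, w_v = 0.8, lambda_att = 0.01,
lambda_smooth = 0.1.  No published value exists for lambda_reg; the
default here is 1e-4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, cat
from .dsnet import PredictionBundle

__all__ = [
    "LossWeights",
    "TaskTargets",
    "LossBreakdown",
    "pose_loss",
    "emg_loss",
    "vel_loss",
    "attention_entropy",
    "smoothness",
    "total_loss",
    "batch_loss",
]


@dataclass
class LossWeights:
    w_p: float = 1.0
    w_e: float = 0.8
    w_v: float = 0.8
    lambda_att: float = 0.01
    lambda_smooth: float = 0.1
    lambda_reg: float = 1e-4  # not a published value; artifact default
    epsilon_att: float = 1e-8
    w_c: float = 0.0  # classification head weight; 0 = head unused

    def __post_init__(self):
        for name in ("w_p", "w_e", "w_v", "lambda_att", "lambda_smooth",
                     "lambda_reg", "w_c"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class TaskTargets:
    """Ground-truth per-step targets matching a PredictionBundle."""

    y_pose: np.ndarray  # (T, N_j * 3)
    y_emg: np.ndarray  # (T, N_m)
    y_vel: np.ndarray  # (T, D)
    action: int | None = None  # class index for the optional head


@dataclass
class LossBreakdown:
    L_pose: float
    L_emg: float
    L_vel: float
    L_att: float
    L_smooth: float
    L_reg: float
    L_total: float
    L_class: float | None = None
    L_fb: float | None = None
    L_total_prime: float | None = None
    total_tensor: Tensor | None = field(default=None, repr=False)

    def components(self) -> dict[str, float]:
        out = {"L_pose": self.L_pose, "L_emg": self.L_emg,
               "L_vel": self.L_vel, "L_att": self.L_att,
               "L_smooth": self.L_smooth, "L_reg": self.L_reg,
               "L_total": self.L_total}
        if self.L_class is not None:
            out["L_class"] = self.L_class
        if self.L_fb is not None:
            out["L_fb"] = self.L_fb
            out["L_total_prime"] = self.L_total_prime
        return out


def _mse(pred: Tensor, target: np.ndarray, label: str) -> Tensor:
    if pred.shape != np.shape(target):
        raise ValueError(
            f"{label}: prediction shape {pred.shape} != target "
            f"{np.shape(target)}")
    diff = pred - Tensor(target)
    return (diff * diff).sum() / float(np.prod(pred.shape))


def pose_loss(pred: Tensor | np.ndarray, target: np.ndarray) -> Tensor:
    """Sum of squared joint-coordinate errors over t, j, divided by N_j T."""
    pred = pred if isinstance(pred, Tensor) else Tensor(pred)
    target = np.asarray(target, dtype=float)
    if pred.ndim == 3:  # (T, N_j, 3): norm over xyz, normalize by N_j * T
        if pred.shape != target.shape:
            raise ValueError("pose shape mismatch")
        diff = pred - Tensor(target)
        T, Nj = pred.shape[0], pred.shape[1]
        return (diff * diff).sum() / float(Nj * T)
    # flattened (T, N_j*3) layout: same sum, same N_j * T normalizer
    if pred.shape != target.shape:
        raise ValueError("pose shape mismatch")
    T, d = pred.shape
    Nj = d // 3 if d % 3 == 0 else d
    diff = pred - Tensor(target)
    return (diff * diff).sum() / float(Nj * T)


def emg_loss(pred: Tensor | np.ndarray, target: np.ndarray) -> Tensor:
    pred = pred if isinstance(pred, Tensor) else Tensor(pred)
    return _mse(pred, np.asarray(target, dtype=float), "emg")


def vel_loss(pred: Tensor | np.ndarray, target: np.ndarray) -> Tensor:
    pred = pred if isinstance(pred, Tensor) else Tensor(pred)
    return _mse(pred, np.asarray(target, dtype=float), "vel")


def attention_entropy(A: np.ndarray | Tensor, epsilon_att: float = 1e-8,
                      check: bool = True) -> Tensor:
    """L_att = -(1/H) sum_h sum_t a_{h,t} log(a_{h,t} + eps).

    `A` has shape (H, T); every head must be normalized to sum 1.
    """
    A = A if isinstance(A, Tensor) else Tensor(A)
    if A.ndim == 1:
        A = A.reshape(1, -1)
    if check:
        sums = A.data.sum(axis=-1)
        if np.any(np.abs(sums - 1.0) > 1e-5):
            raise ValueError(
                f"attention heads must sum to 1 (got sums {sums})")
    H = A.shape[0]
    return -(A * (A + epsilon_att).log()).sum() / float(H)


def smoothness(pred_concat: Tensor | np.ndarray) -> Tensor:
    """Mean squared first difference of the (T, d) spliced predictions.

    Returns 0 for T <= 1 (empty sum; denominator guarded).
    """
    x = pred_concat if isinstance(pred_concat, Tensor) else Tensor(pred_concat)
    if x.ndim == 1:
        x = x.reshape(-1, 1)
    T = x.shape[0]
    if T <= 1:
        return Tensor(0.0)
    diff = x[1:, :] - x[:-1, :]
    return (diff * diff).sum() / float(T - 1)


def l2_penalty(params: dict[str, Tensor]) -> Tensor:
    total = Tensor(0.0)
    for k in sorted(params):
        t = params[k]
        total = total + (t * t).sum()
    return total


def total_loss(bundle: PredictionBundle, targets: TaskTargets,
               params: dict[str, Tensor] | None,
               weights: LossWeights) -> LossBreakdown:
    """Evaluate every term of the joint objective on one sequence.

    The returned breakdown carries the differentiable total in
    ``total_tensor`` (call ``.backward()`` on it to populate gradients).
    """
    Lp = pose_loss(bundle.y_hat_pose, targets.y_pose)
    Le = emg_loss(bundle.y_hat_emg, targets.y_emg)
    Lv = vel_loss(bundle.y_hat_vel, targets.y_vel)
    La = attention_entropy(bundle.attention, weights.epsilon_att)
    spliced = cat([bundle.y_hat_pose, bundle.y_hat_emg, bundle.y_hat_vel],
                  axis=-1)
    Ls = smoothness(spliced)
    Lr = l2_penalty(params) if params is not None else Tensor(0.0)
    total = (weights.w_p * Lp + weights.w_e * Le + weights.w_v * Lv
             + weights.lambda_att * La + weights.lambda_smooth * Ls
             + weights.lambda_reg * Lr)
    L_class = None
    if weights.w_c > 0 and bundle.class_scores is not None \
            and targets.action is not None:
        ce = -(bundle.class_scores[int(targets.action)] + 1e-12).log()
        total = total + weights.w_c * ce
        L_class = ce.item()
    return LossBreakdown(
        L_pose=Lp.item(), L_emg=Le.item(), L_vel=Lv.item(),
        L_att=La.item(), L_smooth=Ls.item(), L_reg=Lr.item(),
        L_total=total.item(), L_class=L_class, total_tensor=total)


def batch_loss(per_sample: list[LossBreakdown]) -> float:
    """Mini-batch loss: arithmetic mean of per-sample totals."""
    if not per_sample:
        raise ValueError("empty batch")
    return float(np.mean([b.L_total for b in per_sample]))
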