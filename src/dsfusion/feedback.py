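"""Closed-loop feedback generation from fused sequence features.

At each step the fused feature z_t is mapped to a bounded feedback
feature vector, the prediction's deviation from a target baseline is
normalized within a window and converted to a scalar intensity, and the
two are spliced into a clipped continuous control vector:

    f_t = sigmoid(W_f^fb z_t + b_f^fb)                      (0, 1)^Rf
    Delta_t = y_t^ref - y^_t
    s_t = ||Delta_t||_2 / (max_{t' in W} ||Delta_t'||_2 + delta)
    I_t = sigmoid(gamma s_t)                                (0, 1)
    u_t = clip(W_u [f_t; I_t] + b_u, u_min, u_max)

The feedback-utility auxiliary loss scores whether feedback precedes
improvement of a scalar performance metric m_t:

    R_{t->t+K} = (1/K) sum_{i=1..K} (m_{t+i} - m_t),   L_fb = -R
    L'_total = L_total + lambda_fb * L_fb

m_t is a posterior evaluation and generally not differentiable in the
model parameters; the default mode therefore records L_fb for logging
and model selection only.  A differentiable surrogate mode defines
m_t := -L_total on held-out batches instead.

The weight symbols W_f/b_f here are the feedback head's own parameters,
distinct from the fusion-layer parameters of the encoder (the two
families are stored and typed separately).  The target baseline y_ref
defaults to the per-action mean trajectory over the training split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FeedbackConfig",
    "FeedbackSignal",
    "feedback_features",
    "deviation",
    "intensity",
    "control_signal",
    "utility",
    "total_with_feedback",
    "generate_feedback",
    "reference_baseline",
    "init_feedback_params",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


@dataclass
class FeedbackConfig:
    gamma: float = 10.0  # deviation-to-intensity gain
    delta: float = 1e-6  # divide guard in the window normalization
    u_min: float = -1.0
    u_max: float = 1.0
    lambda_fb: float = 0.5
    K: int = 10  # utility evaluation window (steps)
    feature_dim: int = 4  # Rf
    control_dim: int = 3
    mode: str = "logging"  # or "surrogate" (m_t := -L_total)

    def __post_init__(self):
        if self.u_min >= self.u_max:
            raise ValueError("u_min must be < u_max")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.mode not in ("logging", "surrogate"):
            raise ValueError(f"unknown feedback mode {self.mode!r}")


@dataclass
class FeedbackSignal:
    """Per-step feedback quantities over a sequence."""

    f: np.ndarray  # (T, Rf) in (0, 1)
    delta: np.ndarray  # (T, d) deviation vectors
    s: np.ndarray  # (T,) normalized deviation
    I: np.ndarray  # (T,) intensity in (0, 1)
    u: np.ndarray  # (T, control_dim) clipped control


def init_feedback_params(z_dim: int, config: FeedbackConfig,
                         seed: int = 0) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(seed)
    s = np.sqrt(6.0 / (z_dim + config.feature_dim))
    return {
        "Wf_fb": rng.uniform(-s, s, size=(config.feature_dim, z_dim)),
        "bf_fb": np.zeros(config.feature_dim),
        "Wu": rng.uniform(-0.5, 0.5,
                          size=(config.control_dim, config.feature_dim + 1)),
        "bu": np.zeros(config.control_dim),
    }


def feedback_features(z_t: np.ndarray, Wf_fb: np.ndarray,
                      bf_fb: np.ndarray) -> np.ndarray:
    """f_t = sigmoid(W_f^fb z_t + b_f^fb); strictly inside (0, 1)."""
    z_t = np.asarray(z_t, dtype=float)
    if Wf_fb.shape[1] != z_t.shape[-1]:
        raise ValueError(
            f"feedback weight expects z of dim {Wf_fb.shape[1]}, "
            f"got {z_t.shape[-1]}")
    return _sigmoid(z_t @ Wf_fb.T + bf_fb)


def deviation(y_hat_t: np.ndarray, y_ref_t: np.ndarray,
              window_norms: np.ndarray, delta: float = 1e-6,
              ) -> tuple[np.ndarray, float]:
    """Deviation vector and window-normalized scalar (Euclidean norms)."""
    window_norms = np.asarray(window_norms, dtype=float)
    if window_norms.size == 0:
        raise ValueError("empty normalization window")
    d = np.asarray(y_ref_t, dtype=float) - np.asarray(y_hat_t, dtype=float)
    s = float(np.linalg.norm(d) / (window_norms.max() + delta))
    return d, s


def intensity(s_t: float, gamma: float = 10.0) -> float:
    """I_t = sigmoid(gamma s_t); strictly increasing in s_t."""
    return float(_sigmoid(np.asarray([float(gamma) * float(s_t)]))[0])


def control_signal(f_t: np.ndarray, I_t: float, Wu: np.ndarray,
                   bu: np.ndarray, u_min: float = -1.0,
                   u_max: float = 1.0) -> np.ndarray:
    """u_t = clip(W_u [f_t; I_t] + b_u, u_min, u_max)."""
    f_t = np.asarray(f_t, dtype=float)
    spliced = np.concatenate([f_t, [float(I_t)]])
    if Wu.shape[1] != spliced.size:
        raise ValueError(
            f"control map expects input dim {Wu.shape[1]}, got {spliced.size}")
    return np.clip(Wu @ spliced + bu, u_min, u_max)


def utility(m_series: np.ndarray, t: int, K: int) -> tuple[float, float]:
    """Average improvement R over (t, t+K] and the utility loss L_fb = -R."""
    m = np.asarray(m_series, dtype=float)
    if t < 0 or t + K > len(m) - 1:
        raise ValueError(
            f"window K={K} at t={t} exceeds series length {len(m)}")
    R = float(np.mean(m[t + 1:t + K + 1] - m[t]))
    return R, -R


def total_with_feedback(L_total: float, L_fb: float,
                        lambda_fb: float = 0.5) -> float:
    """L'_total = L_total + lambda_fb * L_fb."""
    return float(L_total + lambda_fb * L_fb)


def reference_baseline(targets_by_action: dict[str, list[np.ndarray]],
                       ) -> dict[str, np.ndarray]:
    """Per-action mean trajectory over the training split (default y_ref)."""
    return {a: np.mean(np.stack(seqs), axis=0)
            for a, seqs in targets_by_action.items()}


def generate_feedback(z_seq: np.ndarray, y_hat: np.ndarray,
                      y_ref: np.ndarray, params: dict[str, np.ndarray],
                      config: FeedbackConfig | None = None) -> FeedbackSignal:
    """Run the full per-step feedback chain over a sequence.

    The normalization window W defaults to the whole sequence (in the
    training loop it is the current TBPTT segment).
    """
    config = config or FeedbackConfig()
    z_seq = np.asarray(z_seq, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    y_ref = np.asarray(y_ref, dtype=float)
    T = z_seq.shape[0]
    deltas = y_ref - y_hat
    norms = np.linalg.norm(deltas.reshape(T, -1), axis=1)
    f = feedback_features(z_seq, params["Wf_fb"], params["bf_fb"])
    s = norms / (norms.max() + config.delta)
    I = _sigmoid(config.gamma * s)
    u = np.stack([
        control_signal(f[t], I[t], params["Wu"], params["bu"],
                       config.u_min, config.u_max)
        for t in range(T)])
    return FeedbackSignal(f=f, delta=deltas, s=s, I=I, u=u)
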