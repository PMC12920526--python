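"""Dual-stream LSTM encoder with temporal attention and task heads.

Kinematic features (motion capture, gyroscope) and physiological features
(sEMG, acceleration, force) evolve on different time scales and interfere
when forced through a single recurrent state.  The encoder therefore runs
two parameter-independent LSTM branches:

    h_t^k, c_t^k = LSTM_k(x_t^k, h_{t-1}^k, c_{t-1}^k)
    h_t^p, c_t^p = LSTM_p(x_t^p, h_{t-1}^p, c_{t-1}^p)

Each branch is followed by its own temporal-attention module

    alpha_t = softmax_t( u^T tanh(W h_t + b) ),      c = sum_t alpha_t h_t

and the two context vectors are fused by concatenation plus a nonlinear
map, z = act(W_f [c^k; c^p] + b_f).  Per-step fused features z_t (used by
the per-step task heads and the feedback generator) apply the same fusion
to *causal* contexts computed over h_{1..t}; because the attention score
of step i does not depend on t, causal softmax normalization reduces to
cumulative sums and costs O(T).

Task heads are linear maps from z_t to pose coordinates (N_j joints x 3),
EMG channels (N_m) and the velocity vector (D); an optional softmax
classification head over action classes reads the sequence-level z.

Four ablation variants share this code path: ``single_stream`` (one LSTM
over concatenated blocks, uniform weights), ``dual_no_attention`` (two
streams, uniform weights), ``single_stream_attention`` and the full
``dual_with_attention``.  Uniform weights make attention equal to mean
pooling, so the no-attention variants are exactly the attention models
with alpha frozen at 1/T.

Everything runs on the package's float64 autodiff tensors; no deep-learning
framework is involved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, cat, softmax, stack

__all__ = [
    "ModelConfig",
    "LSTMState",
    "PredictionBundle",
    "VARIANTS",
    "init_params",
    "lstm_step",
    "encode_stream",
    "temporal_attention",
    "causal_contexts",
    "fuse",
    "forward",
    "forward_chunked",
    "flatten_params",
    "set_params_from_vector",
    "grad_vector",
    "zero_grads",
    "count_params",
]

VARIANTS = ("single_stream", "dual_no_attention",
            "single_stream_attention", "dual_with_attention")


@dataclass
class ModelConfig:
    kinematic_dim: int
    physiological_dim: int
    n_joints: int  # N_j (pose head emits N_j * 3 coordinates)
    n_emg: int  # N_m
    vel_dim: int = 3  # D
    n_classes: int = 0  # 0 disables the classification head
    hidden_size: int = 64
    num_layers: int = 1
    attention_dim: int = 32
    fusion_dim: int = 32
    fusion_activation: str = "tanh"  # or "sigmoid"
    layer_norm: bool = True
    variant: str = "dual_with_attention"
    class_weight: float = 1.0  # w_c for the optional head
    # The reference ablation protocol holds depth and hidden dimension
    # identical across variants; widening the single stream to match the
    # dual model's parameter count is available behind this flag.
    match_budget: bool = False

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        for name in ("kinematic_dim", "physiological_dim", "n_joints",
                     "n_emg", "vel_dim", "hidden_size", "num_layers",
                     "attention_dim", "fusion_dim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def dual(self) -> bool:
        return self.variant.startswith("dual")

    @property
    def attentive(self) -> bool:
        return self.variant in ("single_stream_attention", "dual_with_attention")

    @property
    def single_hidden(self) -> int:
        """Hidden size of the single-stream variants.

        With ``match_budget`` the single stream is widened so its parameter
        count roughly matches the two separate streams combined.
        """
        if not self.match_budget:
            return self.hidden_size
        return int(round(self.hidden_size * 1.4))

    @property
    def context_dim(self) -> int:
        return 2 * self.hidden_size if self.dual else self.single_hidden


@dataclass
class LSTMState:
    h: Tensor
    c: Tensor


@dataclass
class PredictionBundle:
    """Per-step predictions, fused features and attention weights."""

    y_hat_pose: Tensor  # (T, N_j * 3)
    y_hat_emg: Tensor  # (T, N_m)
    y_hat_vel: Tensor  # (T, D)
    z_seq: Tensor  # (T, fusion_dim) per-step fused features
    z_global: Tensor  # (fusion_dim,) full-window fused feature
    attention: "Tensor"  # (H, T) per-stream full-window weights (in-graph)
    class_scores: Tensor | None = None  # (n_classes,) softmax probabilities
    final_states: dict = field(default_factory=dict)

    def pose_array(self, n_joints: int) -> np.ndarray:
        return self.y_hat_pose.data.reshape(-1, n_joints, 3)

    @property
    def attention_array(self) -> np.ndarray:
        return self.attention.data


# ------------------------------------------------------------------- params

def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=(fan_in, fan_out))


def _lstm_params(rng, prefix: str, in_dim: int, hidden: int, n_layers: int,
                 out: dict[str, Tensor]) -> None:
    d = in_dim
    for layer in range(n_layers):
        out[f"{prefix}.l{layer}.Wx"] = Tensor(_glorot(rng, d, 4 * hidden),
                                              requires_grad=True)
        out[f"{prefix}.l{layer}.Wh"] = Tensor(_glorot(rng, hidden, 4 * hidden),
                                              requires_grad=True)
        b = np.zeros(4 * hidden)
        b[hidden:2 * hidden] = 1.0  # forget-gate bias +1
        out[f"{prefix}.l{layer}.b"] = Tensor(b, requires_grad=True)
        d = hidden


def _attn_params(rng, prefix: str, hidden: int, attn: int,
                 out: dict[str, Tensor]) -> None:
    out[f"{prefix}.W"] = Tensor(_glorot(rng, hidden, attn), requires_grad=True)
    out[f"{prefix}.b"] = Tensor(np.zeros(attn), requires_grad=True)
    out[f"{prefix}.u"] = Tensor(rng.uniform(-0.1, 0.1, size=attn),
                                requires_grad=True)


def init_params(config: ModelConfig, seed: int = 0) -> dict[str, Tensor]:
    """Initialize every trainable parameter of `config` (Glorot uniform)."""
    rng = np.random.default_rng(seed)
    p: dict[str, Tensor] = {}
    H = config.hidden_size
    if config.dual:
        _lstm_params(rng, "kin", config.kinematic_dim, H, config.num_layers, p)
        _lstm_params(rng, "phys", config.physiological_dim, H,
                     config.num_layers, p)
        if config.attentive:
            _attn_params(rng, "att_kin", H, config.attention_dim, p)
            _attn_params(rng, "att_phys", H, config.attention_dim, p)
    else:
        Hs = config.single_hidden
        in_dim = config.kinematic_dim + config.physiological_dim
        _lstm_params(rng, "single", in_dim, Hs, config.num_layers, p)
        if config.attentive:
            _attn_params(rng, "att_single", Hs, config.attention_dim, p)
    ctx = config.context_dim
    p["fuse.W"] = Tensor(_glorot(rng, ctx, config.fusion_dim), requires_grad=True)
    p["fuse.b"] = Tensor(np.zeros(config.fusion_dim), requires_grad=True)
    if config.layer_norm:
        p["ln.gamma"] = Tensor(np.ones(config.fusion_dim), requires_grad=True)
        p["ln.beta"] = Tensor(np.zeros(config.fusion_dim), requires_grad=True)
    F = config.fusion_dim
    p["head.pose.W"] = Tensor(_glorot(rng, F, config.n_joints * 3),
                              requires_grad=True)
    p["head.pose.b"] = Tensor(np.zeros(config.n_joints * 3), requires_grad=True)
    p["head.emg.W"] = Tensor(_glorot(rng, F, config.n_emg), requires_grad=True)
    p["head.emg.b"] = Tensor(np.zeros(config.n_emg), requires_grad=True)
    p["head.vel.W"] = Tensor(_glorot(rng, F, config.vel_dim), requires_grad=True)
    p["head.vel.b"] = Tensor(np.zeros(config.vel_dim), requires_grad=True)
    if config.n_classes:
        p["head.class.W"] = Tensor(_glorot(rng, F, config.n_classes),
                                   requires_grad=True)
        p["head.class.b"] = Tensor(np.zeros(config.n_classes),
                                   requires_grad=True)
    return p


# ------------------------------------------------------------------ encoder

def lstm_step(x_t: Tensor, state: LSTMState, Wx: Tensor, Wh: Tensor,
              b: Tensor) -> LSTMState:
    """One LSTM update (input/forget/output gates, tanh candidate).

    Gate pre-activations are sliced from a single affine map in the order
    (input, forget, candidate, output).
    """
    hidden = Wh.shape[0]
    gates = x_t @ Wx + state.h @ Wh + b
    i = gates[..., 0 * hidden:1 * hidden].sigmoid()
    f = gates[..., 1 * hidden:2 * hidden].sigmoid()
    g = gates[..., 2 * hidden:3 * hidden].tanh()
    o = gates[..., 3 * hidden:4 * hidden].sigmoid()
    c = f * state.c + i * g
    h = o * c.tanh()
    return LSTMState(h=h, c=c)


def encode_stream(X: Tensor | np.ndarray, params: dict[str, Tensor],
                  prefix: str, hidden: int, num_layers: int = 1,
                  init_state: list[LSTMState] | None = None,
                  ) -> tuple[Tensor, list[LSTMState]]:
    """Run a (possibly stacked) LSTM over X.

    X has shape (T, d) or (B, T, d); returns the hidden sequence with the
    same leading layout, (T, H) or (B, T, H), plus the final per-layer
    states (for carrying across TBPTT segment boundaries).
    """
    X = X if isinstance(X, Tensor) else Tensor(X)
    if X.shape[-2] < 1:
        raise ValueError("empty sequence")
    batched = X.ndim == 3
    T = X.shape[-2]
    lead = X.shape[0:1] if batched else ()
    states: list[LSTMState] = []
    if init_state is not None:
        states = [LSTMState(h=s.h, c=s.c) for s in init_state]
    else:
        zero = np.zeros(lead + (hidden,))
        states = [LSTMState(h=Tensor(zero), c=Tensor(zero))
                  for _ in range(num_layers)]
    hs: list[Tensor] = []
    for t in range(T):
        inp = X[..., t, :]
        for layer in range(num_layers):
            Wx = params[f"{prefix}.l{layer}.Wx"]
            Wh = params[f"{prefix}.l{layer}.Wh"]
            b = params[f"{prefix}.l{layer}.b"]
            states[layer] = lstm_step(inp, states[layer], Wx, Wh, b)
            inp = states[layer].h
        hs.append(inp)
    H = stack(hs, axis=-2)
    return H, states


# ---------------------------------------------------------------- attention

def temporal_attention(H: Tensor, W: Tensor, b: Tensor, u: Tensor,
                       ) -> tuple[Tensor, Tensor]:
    """Full-window attention: returns (alpha over T, context vector)."""
    e = (H @ W + b).tanh() @ u  # (..., T)
    alpha = softmax(e, axis=-1)
    ctx = (alpha.reshape(alpha.shape + (1,)) * H).sum(axis=-2)
    return alpha, ctx


def causal_contexts(H: Tensor, W: Tensor | None, b: Tensor | None,
                    u: Tensor | None, attentive: bool) -> Tensor:
    """Per-step contexts over h_{1..t}.

    Attention scores depend only on each step's hidden state, so causal
    renormalization is a ratio of cumulative sums (O(T)).  With
    ``attentive=False`` the weights are uniform and the context is the
    running mean — identical to attention frozen at alpha = 1/T.
    """
    T = H.shape[-2]
    if not attentive:
        counts = np.arange(1, T + 1, dtype=float).reshape(
            (1,) * (H.ndim - 2) + (T, 1))
        return H.cumsum(axis=-2) / counts
    e = (H @ W + b).tanh() @ u  # (..., T)
    w = (e - float(e.data.max())).exp()
    wH = w.reshape(w.shape + (1,)) * H
    num = wH.cumsum(axis=-2)
    den = w.cumsum(axis=-1).reshape(w.shape + (1,))
    return num / den


# ------------------------------------------------------------------- fusion

def fuse(context: Tensor, Wf: Tensor, bf: Tensor,
         activation: str = "tanh") -> Tensor:
    """z = act(W_f context + b_f); `context` is already concatenated."""
    pre = context @ Wf + bf
    return pre.sigmoid() if activation == "sigmoid" else pre.tanh()


def _layer_norm(z: Tensor, gamma: Tensor, beta: Tensor,
                eps: float = 1e-5) -> Tensor:
    m = z.mean(axis=-1, keepdims=True)
    centered = z - m
    v = (centered * centered).mean(axis=-1, keepdims=True)
    return centered / ((v + eps) ** 0.5) * gamma + beta


# ------------------------------------------------------------------ forward

def forward(Xk: np.ndarray | Tensor, Xp: np.ndarray | Tensor,
            params: dict[str, Tensor], config: ModelConfig,
            init_states: dict | None = None) -> PredictionBundle:
    """Full encoder pass for one sequence (or a batch).

    Xk: (T, d_k) kinematic block, Xp: (T, d_p) physiological block (or
    (B, T, d) each).  Returns per-step predictions from heads applied to
    causal fused features z_t, the sequence-level fused feature from
    full-window attention, and the attention weight sequences A.
    """
    Xk = Xk if isinstance(Xk, Tensor) else Tensor(Xk)
    Xp = Xp if isinstance(Xp, Tensor) else Tensor(Xp)
    init_states = init_states or {}
    finals: dict = {}
    if config.dual:
        Hk, fk = encode_stream(Xk, params, "kin", config.hidden_size,
                               config.num_layers,
                               init_states.get("kin"))
        Hp, fp = encode_stream(Xp, params, "phys", config.hidden_size,
                               config.num_layers,
                               init_states.get("phys"))
        finals["kin"], finals["phys"] = fk, fp
        if config.attentive:
            ak, ck = temporal_attention(Hk, params["att_kin.W"],
                                        params["att_kin.b"], params["att_kin.u"])
            ap, cp = temporal_attention(Hp, params["att_phys.W"],
                                        params["att_phys.b"],
                                        params["att_phys.u"])
            Ck = causal_contexts(Hk, params["att_kin.W"], params["att_kin.b"],
                                 params["att_kin.u"], True)
            Cp = causal_contexts(Hp, params["att_phys.W"], params["att_phys.b"],
                                 params["att_phys.u"], True)
        else:
            T = Hk.shape[-2]
            uniform = np.full(Hk.shape[:-1], 1.0 / T)
            ak, ap = Tensor(uniform), Tensor(uniform)
            ck, cp = Hk.mean(axis=-2), Hp.mean(axis=-2)
            Ck = causal_contexts(Hk, None, None, None, False)
            Cp = causal_contexts(Hp, None, None, None, False)
        ctx_global = cat([ck, cp], axis=-1)
        ctx_steps = cat([Ck, Cp], axis=-1)
        A = stack([ak, ap], axis=-2)  # (H=2, T)
    else:
        X = cat([Xk, Xp], axis=-1)
        Hs, fs = encode_stream(X, params, "single", config.single_hidden,
                               config.num_layers, init_states.get("single"))
        finals["single"] = fs
        if config.attentive:
            a1, c1 = temporal_attention(Hs, params["att_single.W"],
                                        params["att_single.b"],
                                        params["att_single.u"])
            Cs = causal_contexts(Hs, params["att_single.W"],
                                 params["att_single.b"],
                                 params["att_single.u"], True)
        else:
            T = Hs.shape[-2]
            a1 = Tensor(np.full(Hs.shape[:-1], 1.0 / T))
            c1 = Hs.mean(axis=-2)
            Cs = causal_contexts(Hs, None, None, None, False)
        ctx_global, ctx_steps = c1, Cs
        A = a1.reshape(a1.shape[:-1] + (1,) + a1.shape[-1:])  # (..., H=1, T)

    act = config.fusion_activation
    z_global = fuse(ctx_global, params["fuse.W"], params["fuse.b"], act)
    z_seq = fuse(ctx_steps, params["fuse.W"], params["fuse.b"], act)
    if config.layer_norm:
        z_seq = _layer_norm(z_seq, params["ln.gamma"], params["ln.beta"])
        z_global = _layer_norm(z_global, params["ln.gamma"], params["ln.beta"])

    y_pose = z_seq @ params["head.pose.W"] + params["head.pose.b"]
    y_emg = z_seq @ params["head.emg.W"] + params["head.emg.b"]
    y_vel = z_seq @ params["head.vel.W"] + params["head.vel.b"]
    scores = None
    if config.n_classes:
        logits = z_global @ params["head.class.W"] + params["head.class.b"]
        scores = softmax(logits, axis=-1)
    return PredictionBundle(y_hat_pose=y_pose, y_hat_emg=y_emg,
                            y_hat_vel=y_vel, z_seq=z_seq, z_global=z_global,
                            attention=A, class_scores=scores,
                            final_states=finals)


# ------------------------------------------------------------- param vector

def forward_chunked(Xk: np.ndarray, Xp: np.ndarray,
                    params: dict[str, Tensor], config: ModelConfig,
                    tau: int = 50) -> PredictionBundle:
    """Forward pass in TBPTT-sized segments, as the model is trained.

    LSTM state carries across segment boundaries; attention pooling
    restarts per segment, matching the training-time computation of the
    per-step fused features.  Returns one bundle with per-step outputs
    concatenated over segments (class scores and global features come
    from the last segment).
    """
    T = Xk.shape[0]
    states = None
    parts: list[PredictionBundle] = []
    for s0 in range(0, T, tau):
        b = forward(Xk[s0:s0 + tau], Xp[s0:s0 + tau], params, config,
                    init_states=states)
        states = {k: [LSTMState(h=Tensor(st.h.data.copy()),
                                c=Tensor(st.c.data.copy()))
                      for st in v] for k, v in b.final_states.items()}
        parts.append(b)
    last = parts[-1]
    return PredictionBundle(
        y_hat_pose=cat([p.y_hat_pose for p in parts], axis=0),
        y_hat_emg=cat([p.y_hat_emg for p in parts], axis=0),
        y_hat_vel=cat([p.y_hat_vel for p in parts], axis=0),
        z_seq=cat([p.z_seq for p in parts], axis=0),
        z_global=last.z_global,
        attention=cat([p.attention for p in parts], axis=-1),
        class_scores=last.class_scores,
        final_states=last.final_states)


def flatten_params(params: dict[str, Tensor]) -> np.ndarray:
    return np.concatenate([params[k].data.ravel() for k in sorted(params)])


def set_params_from_vector(params: dict[str, Tensor], vec: np.ndarray) -> None:
    i = 0
    for k in sorted(params):
        n = params[k].data.size
        params[k].data = vec[i:i + n].reshape(params[k].data.shape).copy()
        i += n
    if i != vec.size:
        raise ValueError("parameter vector size mismatch")


def grad_vector(params: dict[str, Tensor]) -> np.ndarray:
    parts = []
    for k in sorted(params):
        g = params[k].grad
        parts.append(np.zeros(params[k].data.size) if g is None else g.ravel())
    return np.concatenate(parts)


def zero_grads(params: dict[str, Tensor]) -> None:
    for t in params.values():
        t.grad = None


def count_params(params: dict[str, Tensor]) -> int:
    return sum(t.data.size for t in params.values())
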