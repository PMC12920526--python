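# dsfusion

Dual-stream LSTM with temporal attention for multimodal physiological
state estimation — with a seeded synthetic multimodal-recording
simulator, a complete preprocessing chain, a from-scratch training loop,
closed-loop feedback generation, and evaluation/reliability tooling.

## Who this is for

Researchers in sports science and biomedical signal processing who model
athlete state from heterogeneous sensors — optical motion capture,
multi-channel surface EMG, accelerometer/gyroscope, force plates — and
need a fully inspectable reference implementation: every formula from
preprocessing to the optimizer is written out and unit-tested against
independent oracles, and every experiment runs on synthetic data with
known ground truth, since comparable human-subject datasets are rarely
shareable.

## The model

Kinematic features x_t^k and physiological features x_t^p are encoded by
two parameter-independent LSTM branches,

    h_t^k, c_t^k = LSTM_k(x_t^k, h_{t-1}^k, c_{t-1}^k),
    h_t^p, c_t^p = LSTM_p(x_t^p, h_{t-1}^p, c_{t-1}^p),

each followed by its own temporal attention

    alpha_t = softmax_t( u' tanh(W h_t + b) ),    c = sum_t alpha_t h_t,

fused as z = tanh(W_f [c^k; c^p] + b_f), with task heads for pose, EMG
load and velocity. Training minimizes the multi-task objective

    L_total = w_p L_pose + w_e L_emg + w_v L_vel
              + lambda_att L_att + lambda_smooth L_smooth
              + lambda_reg ||theta||^2

(mean-squared task losses; attention-entropy and first-difference
smoothness regularizers) with truncated BPTT, global-norm gradient
clipping, bias-corrected Adam and cosine annealing, early-stopped on the
validation loss with rollback. Feedback signals f_t, s_t, I_t and the
clipped control u_t are generated per step from the fused features
(details in `docs/methods.md`). The network and optimizer run on an
in-package float64 reverse-mode autodiff engine; gradients are verified
against central finite differences.

## Worked example

```python
import numpy as np

from dsfusion import synthgen, pipeline
from dsfusion.estimators import DualStreamRegressor
from dsfusion.dsnet import forward_chunked
from dsfusion.evalkit import emg_percent_error, r_squared

# simulate 2 subjects x 2 actions x 2 trials of 10 s continuous repetitions
recs = synthgen.generate_cohort(
    [("G1", 2, ["spike", "serve"], 5.0)],
    specs=synthgen.desk_specs(duration=10.0), seed=11, trials_per_action=2)

# filter, align to the EMG clock, build targets, split chronologically
seqs = pipeline.build_sequences(recs, model_rate=40.0)
(tr, va, te), norms = pipeline.standardize_and_split(
    seqs, return_normalizers=True)

est = DualStreamRegressor(hidden_size=12, attention_dim=8, fusion_dim=12,
                          batch_size=4, tau=50, patience=20, max_epochs=60,
                          random_state=1)
est.fit(tr, va)
print(f"epochs run: {est.n_epochs_}, best val loss: {est.best_val_loss_:.3f}")

# evaluate every chronological test tail, state warmed on each past
vel_hat, vel_true, emg_errs = [], [], []
for trs, vas, tes in zip(tr, va, te):
    Xk = np.concatenate([trs[0], vas[0], tes[0]])
    Xp = np.concatenate([trs[1], vas[1], tes[1]])
    n_test = tes[0].shape[0]
    b = forward_chunked(Xk, Xp, est.params_, est.config_, tau=50)
    vel_hat.append(b.y_hat_vel.data[-n_test:].ravel())
    vel_true.append(tes[2].y_vel.ravel())
    emg_errs.append(emg_percent_error(
        norms["emg"].inverse_transform(b.y_hat_emg.data[-n_test:]),
        norms["emg"].inverse_transform(tes[2].y_emg)))
r2 = r_squared(np.concatenate(vel_hat), np.concatenate(vel_true))
print(f"velocity R^2 (pooled test tails): {r2:.3f}")
print(f"EMG envelope error: {np.mean(emg_errs):.1f}%")
```

Output from this exact script:

```
epochs run: 60, best val loss: 1.570
velocity R^2 (pooled test tails): 0.321
EMG envelope error: 112.8%
```

The best validation loss is the batch mean of L_total on held-out
chronological segments. At this desk scale (8 short training sequences,
hidden size 12) the velocity head explains about a third of the held-out
variance, and the per-step EMG-envelope error is of the same order as
the envelope's own fluctuation — per-step envelope tracking is the
hardest task for pooled-context heads (see `docs/methods.md`, known
limitations). These numbers are meaningful as *relative* quantities,
e.g. across the ablation variants, not as reproductions of any
full-scale experiment.

A command-line surface wraps the same pipeline:
`dsfusion simulate|preprocess|train|predict|ablate|feedback-demo|reliability`.

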