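# Methods

`dsfusion` estimates physiological training state from multimodal sensor
sequences with a dual-stream recurrent model, and closes the loop with a
bounded feedback signal. This note documents the model, the synthetic data
that stands in for (unavailable) human-subject recordings, the numerical
choices, and what the shipped tests do and do not demonstrate.

## Model

Two LSTM branches with no shared parameters encode the kinematic block
(motion-capture joint coordinates, gyroscope) and the physiological block
(sEMG, accelerometer, force plate) on a common clock:

    h_t^k, c_t^k = LSTM_k(x_t^k, h_{t-1}^k, c_{t-1}^k)
    h_t^p, c_t^p = LSTM_p(x_t^p, h_{t-1}^p, c_{t-1}^p)

The LSTM uses the standard input/forget/output-gate equations with a tanh
candidate and forget-gate bias initialized at +1. Each branch has its own
temporal-attention module

    alpha_t = softmax_t( u' tanh(W h_t + b) ),    c = sum_t alpha_t h_t

and the stream contexts are fused by concatenation and a nonlinear map
z = tanh(W_f [c^k; c^p] + b_f) (sigmoid selectable), followed by layer
normalization. Per-step fused features z_t apply the same fusion to
*causal* contexts computed over h_{1..t}. Because each step's attention
score depends only on that step's hidden state, the causal softmax reduces
to a ratio of cumulative sums and costs O(T) for the whole sequence.
Task heads are linear maps from z_t: pose coordinates (N_j joints x 3),
EMG load envelope (N_m channels), velocity (D = 3). An optional softmax
action-classification head reads the sequence-level z; it is off by
default so the printed loss composition below holds exactly.

Design points that were genuinely open:

* Whether attention operates on stacked streams or per stream: resolved
  per stream (two modules of identical form, separate parameters), which
  is what the separate c^k, c^p in the fusion step require.
* Per-step features: the fusion equation produces a single sequence-level
  vector, but the feedback generator and the per-step heads need a
  feature per time step; causal contexts reconcile the two readings.
* Classification results are reported for the reference experiment but the
  joint loss has no classification term; the head is additive (weight
  `w_c`) and disabled by default.

## Objective

    L_total = w_p L_pose + w_e L_emg + w_v L_vel
              + lambda_att L_att + lambda_smooth L_smooth + lambda_reg ||theta||^2

with mean-squared task losses normalized by (channels x T) exactly, the
attention-entropy regularizer
L_att = -(1/H) sum_h sum_t a_{h,t} log(a_{h,t} + eps_att), eps_att = 1e-8,
and the first-order smoothness penalty on the concatenated per-step
prediction vector, mean of ||y^_t - y^_{t-1}||^2 over t = 2..T (0 when
T <= 1). Batch loss is the arithmetic mean over sequences. Defaults:
w_p = 1.0, w_e = 0.8, w_v = 0.8, lambda_att = 0.01, lambda_smooth = 0.1.
No published value exists for lambda_reg; the package default is 1e-4 and
is flagged as artifact-defined. Minimizing +lambda_att L_att *lowers*
attention entropy, i.e. favors peaked, interpretable weight profiles.

## Training procedure

Truncated BPTT over contiguous segments of length tau = 100 (hidden state
carried across boundaries, detached), global-norm gradient clipping
g~ = g min(1, C/||g||) with C = 5.0, bias-corrected Adam
(beta1 = 0.9, beta2 = 0.999, eps = 1e-8) written out from the update
recurrences rather than delegated to a framework, cosine annealing
eta_t = eta_min + (eta0 - eta_min)(1 + cos(pi t / T_max))/2 with
eta0 = 1e-3, eta_min = 1e-6, T_max = 500, stepped per optimizer step
(per-epoch stepping selectable), batch size 32 (reduced at desk scale),
and early stopping: if the validation loss (batch mean of L_total on the
validation split, feedback term excluded) fails to improve by at least
1e-6 for p = 20 consecutive epochs, training stops and parameters roll
back to the best-validation epoch. Whether T_max counts steps or epochs
is ambiguous in the source description; both are supported, steps is the
default.

The whole network runs on an in-package float64 reverse-mode autodiff
engine (`dsfusion.autodiff`). Analytic gradients of the full
forward-plus-loss are validated against central finite differences to
within 1e-4 relative error, and the Adam implementation against a
hand-iterated transcription of its recurrences to 1e-10.

## Feedback generation

f_t = sigmoid(W_f^fb z_t + b_f^fb); deviation Delta_t = y_t^ref - y^_t
normalized by the window maximum norm plus delta = 1e-6; intensity
I_t = sigmoid(gamma s_t) with gamma = 10; control
u_t = clip(W_u [f_t; I_t] + b_u, -1, 1). The target baseline y_ref
defaults to the per-action mean trajectory over the training split. The
utility term R = (1/K) sum (m_{t+i} - m_t), L_fb = -R,
L'_total = L_total + 0.5 L_fb depends on a posterior performance metric
m_t that is not differentiable in the model parameters in general; the
default mode records L_fb for logging/model selection only, and a
surrogate mode defines m_t := -L_total on a validation batch when a
differentiable stand-in is wanted. What m_t should be in deployment is
left to the caller.

## Synthetic recordings

No human-subject data is released for this task, so the package ships a
seeded simulator. Each trial is driven by a smooth three-phase activation
profile (preparation / execution / recovery) per action; six volleyball
actions are parameterized by execution timing, width, amplitude and
tempo. From the profile the generator derives a joint-coordinate pose
template (per-joint sinusoids gated by the profile, subject-level warps),
a velocity curve and its exact derivative (accelerometer channels), a
nonnegative load envelope, and ground-reaction forces. sEMG is rectified
20-450 Hz band-limited Gaussian noise, amplitude-modulated by the load
envelope and by *physiological-private* slow per-channel recruitment
modulations — dynamics deliberately invisible in the kinematic block, so
that the two streams carry genuinely distinct information, which is the
regime the dual-stream architecture targets.

All sensors sample band-limited master-grid signals by interpolation, so
injected clock offsets (bounded to +-10 ms) are exact time shifts and can
be recovered by sub-sample cross-correlation; additive noise is scaled in
closed form so the realized SNR equals the requested value. The full
acquisition geometry is 120 Hz x 18 mocap, 1 kHz x 8 sEMG, 200 Hz x 6
accelerometer, 200 Hz x 3 gyroscope, 500 Hz x 3 force over 30 s trials;
an alternative description of the capture hardware lists 100 Hz x 12 —
the 120 Hz x 18 reading is the default and both are configurable. The
desk-scale preset shortens trials and scales rates (EMG 200 Hz, still the
reference clock) for fast tests.

What the simulator does *not* emulate: biomechanically valid human
movement, musculoskeletal force-sharing, electrode artifacts such as
motion-induced baseline wander or power-line interference, and
inter-session electrode placement variability. Tests passing on this data
show the pipeline's numerics and the architecture's relative behavior
under controlled conditions, not clinical validity on real athletes.

## Preprocessing

Zero-phase (forward-backward) Butterworth bandpass for sEMG (20-450 Hz at
1 kHz, edges scaled proportionally at reduced rates, order 4), centered
5-sample moving average for mocap and inertial channels, zero-phase
low-pass (50 Hz, order 4) for force. Standard-score normalization uses
the population standard deviation, is fit on the chronological training
segment only, and raises on zero-variance features rather than silently
adding an epsilon. Alignment linearly interpolates every modality onto
the highest-rate modality's timeline restricted to the half-open overlap
[max start, min end); gyroscope joins the kinematic block and force the
physiological block by default (both configurable). Signal quality is
reported as SNR before/after filtering (dB, against the stored clean
series, capped at 60 dB), residual alignment error (ms, cross-correlation
lag with parabolic sub-sample refinement), and a stability index
1/(1 + CV of sliding-window RMS) clipped to [0, 1] — an artifact-defined
stationarity summary, not a standard metric.

## Evaluation

Chronological 70/15/15 splits (floor train, floor val, remainder test;
strictly increasing order required). Metrics: classification accuracy
(%), R^2 = 1 - SS_res/SS_tot, and "EMG error (%)" defined here as
normalized mean absolute error 100 mean|y^-y| / mean|y| — the percent-EMG
-error convention is not standardized, so this definition is
artifact-defined and stated wherever reported. Reliability uses ICC(2,1)
(two-way random effects, absolute agreement, single rater) computed from
ANOVA mean squares, cross-checked against pingouin in the tests, and
CV% = 100 SD/mean with population SD.

The ablation harness trains four variants — single-stream LSTM, dual
streams without attention, single stream with attention, dual streams
with attention — on identical data, depth, hidden dimension, optimizer,
schedule and stopping rule; only the architecture flag differs. Without
attention the per-step context is the running mean of hidden states,
which equals attention frozen at alpha = 1/T, so the no-attention
variants are exact special cases of the attentive code path.

## Problem sizes used by the shipped checks

The stochastic structural-ordering check trains on a 3-subject,
4-action, 2-trial desk-scale cohort (5 s trials of 2.5 s action cycles,
model clock 40 Hz, T = 200 per sequence, hidden size 12, batch 4) for up
to 60 epochs — the full 500-step cosine schedule at this batch count.
Trial length was set so the chronological validation segments span about
30 steps: much shorter windows are dominated by cold-start transients
and stop discriminating between architectures.

Reported test-split metrics use a separate 2-subject, 2-action, 2-trial
cohort of 10 s trials (4 action cycles), so the final 15% of every
sequence contains complete executions; the recurrent state is warmed on
the preceding 85% by forwarding the sequence in tau-length segments
exactly as in training (causal, no future leakage), and EMG percent
error is computed on the native envelope scale, where the denominator
mean|y| is meaningful. These sizes let each model train to its plateau
while the whole run remains a desk-scale computation; analytic and
oracle checks run on toy sizes in well under a second.

## Known limitations

* Causal attention contexts integrate the whole past; late in a long
  sequence they change slowly, which bounds how sharply per-step
  predictions can track fast transients. The attentive variants can
  counteract this by concentrating weight (the entropy regularizer pushes
  the same way); the uniform-pooling baselines cannot.
* The Adam/TBPTT loop is plain numpy: correct and deterministic, but not
  fast. Desk-scale problems train in minutes; the full 45-subject
  geometry at 1 kHz is out of its intended range.
* ICC assumes a complete subjects x trials table; unbalanced designs are
  not supported.
* The feedback utility loss is observational by default; the surrogate
  mode changes the optimization objective and should be treated as a
  distinct experiment, not a drop-in.
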