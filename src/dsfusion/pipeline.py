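"""From raw synthetic recordings to model-ready training sequences.

Chains the preprocessing stages (filter -> align -> normalize) and builds
per-step regression targets on a common model clock:

* pose targets: the ground-truth joint trajectory,
* EMG targets: a short moving-RMS envelope of the clean EMG channels
  (the muscle-load curve the EMG head regresses; raw rectified EMG is
  stochastic carrier noise and has no predictable per-sample value),
* velocity targets: the ground-truth velocity curve.

The aligned reference clock runs at the EMG rate, far denser than the
recurrent model needs; sequences are linearly resampled to a model rate
(default 40 Hz).  Features and targets are standardized with statistics
fit on the chronological training portion only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .objectives import TaskTargets
from .preprocess import (AlignedSequence, StandardNormalizer,
                         preprocess_recording)
from .synthgen import ACTIONS, MultimodalRecording

__all__ = ["ModelSequence", "build_sequences", "standardize_and_split"]


@dataclass
class ModelSequence:
    Xk: np.ndarray
    Xp: np.ndarray
    targets: TaskTargets
    action: str
    subject_id: str

    def as_tuple(self):
        return (self.Xk, self.Xp, self.targets)


def _moving_rms(x: np.ndarray, window: int) -> np.ndarray:
    w = max(1, window)
    pad = w // 2
    xp = np.pad(x ** 2, ((pad, w - 1 - pad), (0, 0)), mode="edge")
    kernel = np.ones(w) / w
    sm = np.column_stack([
        np.convolve(xp[:, c], kernel, mode="valid") for c in range(x.shape[1])])
    return np.sqrt(sm)


def _resample(t_src: np.ndarray, x: np.ndarray, t_dst: np.ndarray) -> np.ndarray:
    return np.column_stack([
        np.interp(t_dst, t_src, x[:, c]) for c in range(x.shape[1])])


def build_sequences(recordings: list[MultimodalRecording],
                    model_rate: float = 40.0,
                    envelope_window_s: float = 0.1,
                    ) -> list[ModelSequence]:
    """Preprocess and target-annotate every recording."""
    out: list[ModelSequence] = []
    for rec in recordings:
        aligned: AlignedSequence = preprocess_recording(rec)
        t0, t1 = aligned.timeline[0], aligned.timeline[-1]
        n = max(2, int(round((t1 - t0) * model_rate)))
        tm = t0 + np.arange(n) / model_rate
        Xk = _resample(aligned.timeline, aligned.kinematic, tm)
        Xp = _resample(aligned.timeline, aligned.physiological, tm)
        gt = rec.ground_truth
        pose = _resample(gt.times, gt.pose_trajectory, tm)
        vel = _resample(gt.times, gt.velocity_curve, tm)
        emg_spec = rec.spec("emg")
        env = _moving_rms(rec.clean["emg"],
                          int(round(envelope_window_s * emg_spec.rate)))
        emg = _resample(emg_spec.timestamps(), env, tm)
        targets = TaskTargets(
            y_pose=pose, y_emg=emg, y_vel=vel,
            action=sorted(ACTIONS).index(gt.action_label))
        out.append(ModelSequence(Xk=Xk, Xp=Xp, targets=targets,
                                 action=gt.action_label,
                                 subject_id=rec.subject_id))
    return out


def standardize_and_split(sequences: list[ModelSequence],
                          fractions=(0.70, 0.15, 0.15),
                          return_normalizers: bool = False):
    """Chronological per-sequence split with train-only normalization.

    Every sequence is cut along time into train/val/test segments
    (earliest to latest); feature and target normalizers are fit on the
    concatenated training segments of all sequences and applied
    everywhere, so no statistic leaks from the future.
    """
    f_tr, f_va, _ = fractions
    cut = []
    for s in sequences:
        T = s.Xk.shape[0]
        n_tr = int(np.floor(f_tr * T))
        n_va = int(np.floor(f_va * T))
        cut.append((n_tr, n_tr + n_va, T))

    def fit_norm(getter):
        data = np.concatenate([getter(s)[:c[0]] for s, c in zip(sequences, cut)])
        return StandardNormalizer().fit(data)

    norms = {
        "Xk": fit_norm(lambda s: s.Xk),
        "Xp": fit_norm(lambda s: s.Xp),
        "pose": fit_norm(lambda s: s.targets.y_pose),
        "emg": fit_norm(lambda s: s.targets.y_emg),
        "vel": fit_norm(lambda s: s.targets.y_vel),
    }

    splits: tuple[list, list, list] = ([], [], [])
    for s, (a, b, T) in zip(sequences, cut):
        Xk = norms["Xk"].transform(s.Xk)
        Xp = norms["Xp"].transform(s.Xp)
        pose = norms["pose"].transform(s.targets.y_pose)
        emg = norms["emg"].transform(s.targets.y_emg)
        vel = norms["vel"].transform(s.targets.y_vel)
        for i, sl in enumerate((slice(0, a), slice(a, b), slice(b, T))):
            splits[i].append((Xk[sl], Xp[sl], TaskTargets(
                y_pose=pose[sl], y_emg=emg[sl], y_vel=vel[sl],
                action=s.targets.action)))
    if return_normalizers:
        return splits, norms
    return splits
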