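"""Chronological splitting, task metrics, reliability statistics, ablation.

Splits are chronological per sequence: the earliest 70% of steps train,
the next 15% validate and the final 15% test, so every test sample occurs
strictly after the training data (no leakage across the boundary).

Metrics:

* classification accuracy, in percent;
* R^2 = 1 - SS_res / SS_tot for velocity-curve fitting;
* "EMG error (%)", defined here as the normalized mean absolute error
  100 * mean|y^ - y| / mean|y| — an artifact-defined formula chosen for
  scale invariance, since percent EMG error has no single standard form;
* ICC(2,1) (two-way random effects, absolute agreement, single rater)
  from the ANOVA mean squares, for cross-trial reliability;
* CV% = 100 * population SD / mean.

The ablation harness trains the four architecture variants (single
stream, dual without attention, single stream with attention, full dual
with attention) under identical data, depth, optimizer, schedule and
seeds, and reports per-variant metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dsnet import VARIANTS, ModelConfig, forward
from .objectives import LossWeights, TaskTargets
from .optimloop import ClipConfig, ScheduleConfig, TrainConfig, evaluate_split, train

__all__ = [
    "SplitSpec",
    "chronological_split",
    "split_sequence",
    "classification_accuracy",
    "r_squared",
    "emg_percent_error",
    "icc",
    "cv_percent",
    "MetricReport",
    "ReliabilityReport",
    "run_ablation",
]


@dataclass(frozen=True)
class SplitSpec:
    train: float = 0.70
    val: float = 0.15
    test: float = 0.15

    def __post_init__(self):
        if abs(self.train + self.val + self.test - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if min(self.train, self.val, self.test) <= 0:
            raise ValueError("all split fractions must be positive")


def chronological_split(indices: np.ndarray,
                        spec: SplitSpec | None = None,
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split ordered indices into contiguous train/val/test index sets.

    Rounding rule: floor for train and val, remainder to test.  The input
    must already be in chronological order (strictly increasing); a
    shuffled input is an error, because a chronological split of unordered
    data would silently leak future samples into training.
    """
    spec = spec or SplitSpec()
    idx = np.asarray(indices)
    n = len(idx)
    if n < 3:
        raise ValueError("need at least 3 samples to split")
    if np.any(np.diff(idx.astype(float)) <= 0):
        raise ValueError("indices must be strictly increasing (chronological)")
    n_train = int(np.floor(spec.train * n))
    n_val = int(np.floor(spec.val * n))
    if n_train == 0 or n_val == 0 or n - n_train - n_val == 0:
        raise ValueError(f"too few samples ({n}) for a non-empty split")
    return idx[:n_train], idx[n_train:n_train + n_val], idx[n_train + n_val:]


def split_sequence(Xk: np.ndarray, Xp: np.ndarray, targets: TaskTargets,
                   spec: SplitSpec | None = None):
    """Chronological 70/15/15 split of one aligned sequence by time step."""
    T = Xk.shape[0]
    tr, va, te = chronological_split(np.arange(T), spec)

    def cut(sl):
        return (Xk[sl], Xp[sl],
                TaskTargets(y_pose=targets.y_pose[sl],
                            y_emg=targets.y_emg[sl],
                            y_vel=targets.y_vel[sl],
                            action=targets.action))

    return cut(tr), cut(va), cut(te)


# ------------------------------------------------------------------ metrics

def classification_accuracy(preds, labels) -> float:
    preds = np.asarray(preds)
    labels = np.asarray(labels)
    if preds.shape != labels.shape:
        raise ValueError("prediction/label length mismatch")
    return float(100.0 * np.mean(preds == labels))


def r_squared(y_hat: np.ndarray, y: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot."""
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if y_hat.shape != y.shape:
        raise ValueError("shape mismatch")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("zero-variance target: R^2 undefined")
    ss_res = float(np.sum((y - y_hat) ** 2))
    return 1.0 - ss_res / ss_tot


def emg_percent_error(y_hat: np.ndarray, y: np.ndarray) -> float:
    """Normalized mean absolute error, percent (artifact-defined)."""
    y_hat = np.asarray(y_hat, dtype=float)
    y = np.asarray(y, dtype=float)
    if y_hat.shape != y.shape:
        raise ValueError("shape mismatch")
    denom = float(np.mean(np.abs(y)))
    if denom == 0:
        raise ValueError("zero-magnitude target: percent error undefined")
    return float(100.0 * np.mean(np.abs(y_hat - y)) / denom)


# ---------------------------------------------------------------- reliability

def icc(measurements: np.ndarray, form: str = "ICC2") -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    `measurements` is a subjects x trials table.  Computed from the ANOVA
    mean squares:  (MS_R - MS_E) / (MS_R + (k-1) MS_E + k (MS_C - MS_E)/n).
    """
    if form != "ICC2":
        raise ValueError("only ICC(2,1) is implemented")
    X = np.asarray(measurements, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need a subjects x trials table, >= 2 each")
    n, k = X.shape
    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((X - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n
    if denom == 0:
        raise ValueError("degenerate table: zero total variance")
    return float((ms_r - ms_e) / denom)


def cv_percent(values: np.ndarray) -> float:
    """Coefficient of variation, percent (population SD / mean)."""
    v = np.asarray(values, dtype=float)
    m = v.mean()
    if m == 0:
        raise ValueError("zero mean: CV undefined")
    return float(100.0 * v.std(ddof=0) / abs(m))


@dataclass
class ReliabilityReport:
    icc: float
    cv_percent: float


@dataclass
class MetricReport:
    accuracy: float  # % correct actions
    emg_error: float  # %
    velocity_r2: float
    val_loss: float = np.nan


# ------------------------------------------------------------------ ablation

def evaluate_model(params: dict, config: ModelConfig, test_seqs: list,
                   val_seqs: list | None = None,
                   weights: LossWeights | None = None) -> MetricReport:
    """Test-set metrics (and validation loss) for a trained model."""
    weights = weights or LossWeights()
    correct, total = 0, 0
    emg_errs, vel_hat, vel_true = [], [], []
    for Xk, Xp, targets in test_seqs:
        bundle = forward(Xk, Xp, params, config)
        if config.n_classes and targets.action is not None:
            pred = int(np.argmax(bundle.class_scores.data))
            correct += int(pred == int(targets.action))
            total += 1
        emg_errs.append(emg_percent_error(bundle.y_hat_emg.data, targets.y_emg))
        vel_hat.append(bundle.y_hat_vel.data.ravel())
        vel_true.append(targets.y_vel.ravel())
    acc = 100.0 * correct / total if total else np.nan
    r2 = r_squared(np.concatenate(vel_hat), np.concatenate(vel_true))
    val_loss = (evaluate_split(val_seqs, params, config, weights)
                if val_seqs else np.nan)
    return MetricReport(accuracy=acc, emg_error=float(np.mean(emg_errs)),
                        velocity_r2=r2, val_loss=val_loss)


def run_ablation(train_seqs: list, val_seqs: list, test_seqs: list,
                 base_config: ModelConfig, seeds: list[int],
                 train_cfg: TrainConfig | None = None,
                 sched_cfg: ScheduleConfig | None = None,
                 clip_cfg: ClipConfig | None = None,
                 weights: LossWeights | None = None,
                 ) -> dict[str, dict]:
    """Train all four variants under identical conditions per seed.

    Returns {variant: {"metrics": [MetricReport per seed],
                       "mean": MetricReport, "sd": MetricReport}}.
    Data batches, depth, optimizer, schedule and stopping rule are shared;
    only the architecture flag differs.
    """
    if not seeds:
        raise ValueError("seeds list must be nonempty")
    results: dict[str, dict] = {}
    for variant in VARIANTS:
        cfg_kw = {f.name: getattr(base_config, f.name)
                  for f in base_config.__dataclass_fields__.values()}
        cfg_kw["variant"] = variant
        cfg = ModelConfig(**cfg_kw)
        reports = []
        for seed in seeds:
            tc = train_cfg or TrainConfig()
            tc = TrainConfig(batch_size=tc.batch_size, tau=tc.tau,
                             patience=tc.patience, max_epochs=tc.max_epochs,
                             seed=seed, improvement_tol=tc.improvement_tol)
            params, _hist = train(cfg, train_seqs, val_seqs, tc, sched_cfg,
                                  clip_cfg, weights, init_seed=seed)
            reports.append(evaluate_model(params, cfg, test_seqs,
                                          val_seqs, weights))
        arr = {f: np.array([getattr(r, f) for r in reports])
               for f in ("accuracy", "emg_error", "velocity_r2", "val_loss")}
        results[variant] = {
            "metrics": reports,
            "mean": MetricReport(**{k: float(np.nanmean(v))
                                    for k, v in arr.items()}),
            "sd": MetricReport(**{k: float(np.nanstd(v))
                                  for k, v in arr.items()}),
        }
    return results
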