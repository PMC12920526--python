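"""Seeded synthetic multimodal training recordings with known latent structure.

Real multimodal strength-and-conditioning datasets combine optical motion
capture, multi-channel surface EMG, inertial sensors and force plates, each
on its own clock and sampling rate.  This module simulates such recordings
for six core volleyball actions (serve, spike, block, set, dig, approach
run) so that every downstream stage — filtering, alignment, the dual-stream
encoder, the training loop — can be exercised against known ground truth.

Every trial is driven by a smooth three-phase activation profile
(preparation / execution / recovery).  From that latent profile the
generator derives:

* a joint-coordinate pose trajectory (action template + per-subject warp),
* a nonnegative muscle-load envelope,
* a velocity curve and its derivative (the accelerometer channels),
* sEMG as load-envelope-modulated, rectified band-limited Gaussian noise,
* gyroscope and ground-reaction-force channels tied to the same latents.

All sensors are sampled from band-limited master-grid signals, so an
injected clock offset is an exact time shift of the same underlying
process and can be recovered by cross-correlation downstream.  Generation
is fully deterministic given the seed.

The sensor specifications default to a typical acquisition setup:
motion capture 120 Hz x 18 channels, sEMG 1000 Hz x 8, accelerometer
200 Hz x 6 (velocity + acceleration), gyroscope 200 Hz x 3, force plate
500 Hz x 3, 30 s trials.  A desk-scale preset (``default_specs(scale=...)``)
shrinks durations and the EMG rate for fast tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "SensorSpec",
    "GroundTruth",
    "MultimodalRecording",
    "ACTIONS",
    "CYCLE_S",
    "default_specs",
    "generate_recording",
    "generate_cohort",
    "inject_noise",
    "DEFAULT_GROUP_TABLE",
]

#: The six core actions and their phase-template parameters:
#: (execution center as fraction of trial, execution width, amplitude, tempo)
ACTIONS: dict[str, tuple[float, float, float, float]] = {
    "serve": (0.45, 0.10, 1.0, 1.0),
    "spike": (0.55, 0.07, 1.4, 1.8),
    "block": (0.50, 0.08, 1.1, 1.5),
    "set": (0.40, 0.14, 0.7, 0.8),
    "dig": (0.60, 0.09, 0.9, 1.6),
    "approach_run": (0.50, 0.22, 1.2, 1.2),
}


@dataclass(frozen=True)
class SensorSpec:
    """Acquisition parameters of one sensor stream."""

    name: str
    rate: float  # Hz
    dim: int
    duration: float  # s

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError(f"sensor {self.name!r}: rate must be > 0, got {self.rate}")
        if self.dim < 1:
            raise ValueError(f"sensor {self.name!r}: dim must be >= 1, got {self.dim}")
        if self.duration <= 0:
            raise ValueError(f"sensor {self.name!r}: duration must be > 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.rate * self.duration))

    def timestamps(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate


def default_specs(scale: float = 1.0, emg_rate: float | None = None,
                  duration: float = 30.0) -> list[SensorSpec]:
    """Standard acquisition setup; `scale` < 1 shrinks trial durations.

    `emg_rate` overrides the 1000 Hz EMG rate (the desk-scale preset uses
    200 Hz so tests stay light while preserving the rate hierarchy).
    """
    if not 0 < scale <= 1:
        raise ValueError("scale must be in (0, 1]")
    d = duration * scale
    emg = 1000.0 if emg_rate is None else float(emg_rate)
    return [
        SensorSpec("mocap", 120.0, 18, d),
        SensorSpec("emg", emg, 8, d),
        SensorSpec("accel", 200.0, 6, d),
        SensorSpec("gyro", 200.0, 3, d),
        SensorSpec("force", 500.0, 3, d),
    ]


def desk_specs(duration: float = 3.0) -> list[SensorSpec]:
    """Reduced-rate, short-trial specs used for fast tests and demos.

    Rates are scaled so the hierarchy of the full setup is preserved
    (EMG remains the highest-rate modality and hence the reference clock).
    """
    return [
        SensorSpec("mocap", 60.0, 18, duration),
        SensorSpec("emg", 200.0, 8, duration),
        SensorSpec("accel", 100.0, 6, duration),
        SensorSpec("gyro", 100.0, 3, duration),
        SensorSpec("force", 125.0, 3, duration),
    ]


@dataclass
class GroundTruth:
    """Latent curves on the reference clock (highest-rate sensor)."""

    action_label: str
    times: np.ndarray  # reference clock (s)
    load_envelope: np.ndarray  # (T,) nonnegative
    velocity_curve: np.ndarray  # (T, 3) m/s
    pose_trajectory: np.ndarray  # (T, n_joint_coords)

    def validate(self) -> None:
        T = len(self.times)
        assert self.load_envelope.shape[0] == T
        assert self.velocity_curve.shape[0] == T
        assert self.pose_trajectory.shape[0] == T
        assert np.all(self.load_envelope >= 0)


@dataclass
class MultimodalRecording:
    """One synthetic trial: per-sensor series plus the generating latents."""

    subject_id: str
    group_id: str
    specs: list[SensorSpec]
    series: dict[str, np.ndarray]  # name -> (n_samples, dim)
    clean: dict[str, np.ndarray]  # name -> noise-free series on nominal clock
    injected_offsets: dict[str, float]  # name -> clock offset (ms)
    seed: int
    ground_truth: GroundTruth

    def spec(self, name: str) -> SensorSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)

    def timestamps(self, name: str) -> np.ndarray:
        return self.spec(name).timestamps()


# ----------------------------------------------------------------- templates

#: nominal length of one action repetition (s); trials repeat cyclically,
#: emulating continuous sampling of training movements
CYCLE_S = 2.5


def _phase_profile(t: np.ndarray, duration: float, center: float, width: float,
                   tempo: float, rng: np.random.Generator,
                   variability: float, cycle_s: float = CYCLE_S) -> np.ndarray:
    """Smooth cyclic preparation/execution/recovery activation in [0, ~1].

    Trials contain repeated executions (one per ~CYCLE_S), as in continuous
    sampling of training movements, so every chronological segment of a
    trial carries full action dynamics.  Per-cycle timing/width jitter
    scales with the subject's variability.
    """
    n_cycles = max(1, int(round(duration / cycle_s)))
    period = duration / n_cycles
    prof = np.full_like(t, 0.05)
    for k in range(n_cycles):
        c = (k + center + variability * rng.normal(0, 0.03)) * period
        w = width * period * (1 + variability * rng.normal(0, 0.15))
        w = max(w, 1e-3)
        prof = prof + np.exp(-0.5 * ((t - c) / w) ** 2)
        prof = prof + 0.25 * np.exp(-0.5 * ((t - (c - 3 * w)) / (2 * w)) ** 2)
    # slow oscillation gives the profile a tempo signature per action
    osc = 0.08 * np.sin(2 * np.pi * tempo * t / period)
    return np.clip(prof + osc, 0.0, None)


def _pose_template(t: np.ndarray, period: float, n_coords: int,
                   profile: np.ndarray, amplitude: float,
                   rng: np.random.Generator, variability: float) -> np.ndarray:
    """Joint coordinates: per-joint sinusoids gated by the phase profile.

    Joint oscillations cycle with the action period so repeated executions
    produce repeated (warped) pose dynamics.
    """
    T = len(t)
    pose = np.empty((T, n_coords))
    base = rng.normal(0, 0.2, size=n_coords)
    for j in range(n_coords):
        f = 0.5 + 0.25 * (j % 6)  # cycles per action period, per joint
        ph = rng.uniform(0, 2 * np.pi) if variability else (j * 0.7)
        gain = amplitude * (0.5 + 0.5 * np.cos(j))
        pose[:, j] = base[j] + gain * profile * np.sin(
            2 * np.pi * f * t / period + ph)
    return pose


def _bandlimited_noise(n: int, rate: float, band: tuple[float, float],
                       rng: np.random.Generator) -> np.ndarray:
    """Zero-mean Gaussian noise bandpassed to `band` (Hz)."""
    x = rng.standard_normal(n)
    if n < 40:  # too short for a stable forward-backward pass
        return x
    lo, hi = band
    nyq = rate / 2
    hi = min(hi, 0.95 * nyq)
    lo = min(lo, 0.5 * hi)
    sos = butter(4, [lo / nyq, hi / nyq], btype="band", output="sos")
    y = sosfiltfilt(sos, x)
    return y / (y.std() + 1e-12)


# ---------------------------------------------------------------- generation

def generate_recording(specs: list[SensorSpec], action: str,
                       subject_params: dict | None = None,
                       noise: dict | None = None,
                       seed: int = 0,
                       subject_id: str = "S00", group_id: str = "G1",
                       cycle_s: float = CYCLE_S,
                       ) -> MultimodalRecording:
    """Simulate one multimodal trial of `action`.

    `subject_params` keys: ``variability`` (0..1 scale of template warps),
    ``strength`` (EMG gain).  `cycle_s` sets the nominal action-repetition
    period; shorter desk-scale trials use a proportionally shorter cycle so
    every chronological segment still spans full executions.  `noise` keys: ``amplitude`` (additive
    measurement-noise std, in units of each clean signal's std),
    ``offset_ms`` (dict or scalar: per-sensor clock offsets, bounded to
    +-10 ms by default), ``drift_rate`` (amplitude drift per second).
    """
    if action not in ACTIONS:
        raise ValueError(f"unknown action {action!r}; one of {sorted(ACTIONS)}")
    if not specs:
        raise ValueError("specs must be nonempty")
    sp = dict(subject_params or {})
    nz = dict(noise or {})
    variability = float(sp.get("variability", 0.3))
    strength = float(sp.get("strength", 1.0))
    noise_amp = float(nz.get("amplitude", 0.05))
    drift_rate = float(nz.get("drift_rate", 0.0))
    offset_spec = nz.get("offset_ms", 0.0)

    rng = np.random.default_rng(seed)
    duration = max(s.duration for s in specs)
    master_rate = 2 * max(s.rate for s in specs)
    tm = np.arange(int(round(master_rate * duration)) + 1) / master_rate

    center, width, amplitude, tempo = ACTIONS[action]
    profile = _phase_profile(tm, duration, center, width, tempo, rng,
                             variability, cycle_s)
    period = duration / max(1, int(round(duration / cycle_s)))

    mocap_dim = next((s.dim for s in specs if s.name == "mocap"), 18)
    pose_m = _pose_template(tm, period, mocap_dim, profile, amplitude, rng,
                            variability)

    # velocity: smooth, profile-driven; fixed unit load envelope override
    if nz.get("unit_envelope", False):
        envelope_m = np.ones_like(tm)
    else:
        envelope_m = profile ** 2 / (np.max(profile) ** 2 + 1e-12)
    direction = rng.normal(0, 1, size=3)
    direction /= np.linalg.norm(direction)
    speed = 2.8 * amplitude / 1.4  # peak speed scales with action amplitude
    vel_m = speed * np.outer(profile / (profile.max() + 1e-12), direction)
    vel_m += 0.1 * np.column_stack([
        np.sin(2 * np.pi * (1.5 + k) * tm / period) for k in range(3)])
    acc_m = np.gradient(vel_m, tm, axis=0)

    master: dict[str, np.ndarray] = {}
    for s in specs:
        if s.name == "mocap":
            master[s.name] = pose_m[:, :s.dim]
        elif s.name == "emg":
            band = (20.0, 450.0)
            carriers = np.column_stack([
                _bandlimited_noise(len(tm), master_rate, band, rng)
                for _ in range(s.dim)])
            gains = strength * (0.6 + 0.8 * rng.random(s.dim))
            # physiological-private dynamics: slow per-channel recruitment
            # modulation, independent of the kinematic latents, so muscle
            # load carries information the kinematic block does not
            if nz.get("unit_envelope", False):
                recruit = np.ones((len(tm), s.dim))
            else:
                slow = np.column_stack([
                    _bandlimited_noise(len(tm), master_rate,
                                       (0.3 / duration * 30.0,
                                        2.0 / duration * 30.0), rng)
                    for _ in range(s.dim)])
                recruit = np.clip(1.0 + 0.5 * slow, 0.2, None)
            master[s.name] = (np.abs(carriers) * envelope_m[:, None]
                              * recruit * gains)
        elif s.name == "accel":
            half = s.dim // 2
            master[s.name] = np.column_stack(
                [vel_m[:, :half], acc_m[:, :s.dim - half]])
        elif s.name == "gyro":
            ang = np.gradient(pose_m[:, :s.dim], tm, axis=0)
            master[s.name] = ang
        elif s.name == "force":
            grf = 700.0 + 600.0 * envelope_m  # body weight + loading, N
            lateral = 80.0 * np.gradient(envelope_m, tm)
            master[s.name] = np.column_stack(
                [grf, lateral, 0.5 * lateral])[:, :s.dim]
        else:
            master[s.name] = np.column_stack([
                _bandlimited_noise(len(tm), master_rate, (0.5, 20.0), rng)
                for _ in range(s.dim)])

    series: dict[str, np.ndarray] = {}
    clean: dict[str, np.ndarray] = {}
    offsets: dict[str, float] = {}
    for s in specs:
        ts = s.timestamps()
        if isinstance(offset_spec, dict):
            off_ms = float(offset_spec.get(s.name, 0.0))
        else:
            off_ms = float(offset_spec)
        off_ms = float(np.clip(off_ms, -10.0, 10.0))
        offsets[s.name] = off_ms
        cl = np.column_stack([
            np.interp(ts, tm, master[s.name][:, c])
            for c in range(s.dim)])
        obs = np.column_stack([
            np.interp(ts + off_ms / 1000.0, tm, master[s.name][:, c])
            for c in range(s.dim)])
        if noise_amp > 0:
            sd = cl.std(axis=0, keepdims=True) + 1e-12
            obs = obs + noise_amp * sd * rng.standard_normal(obs.shape)
        if drift_rate != 0.0:
            obs = obs + drift_rate * ts[:, None] * cl.std(axis=0, keepdims=True)
        series[s.name] = obs
        clean[s.name] = cl

    ref = max(specs, key=lambda s: s.rate)
    tr = ref.timestamps()
    gt = GroundTruth(
        action_label=action,
        times=tr,
        load_envelope=np.interp(tr, tm, envelope_m),
        velocity_curve=np.column_stack(
            [np.interp(tr, tm, vel_m[:, k]) for k in range(3)]),
        pose_trajectory=np.column_stack(
            [np.interp(tr, tm, pose_m[:, j]) for j in range(mocap_dim)]),
    )
    gt.validate()
    return MultimodalRecording(
        subject_id=subject_id, group_id=group_id, specs=list(specs),
        series=series, clean=clean, injected_offsets=offsets,
        seed=seed, ground_truth=gt)


#: cohort structure: (group_id, n_participants, actions, total_minutes)
DEFAULT_GROUP_TABLE: list[tuple[str, int, list[str], float]] = [
    ("G1", 10, ["spike", "block", "approach_run"], 320),
    ("G2", 8, ["serve", "dig", "set"], 260),
    ("G3", 12, ["approach_run", "spike", "block"], 340),
    ("G4", 6, ["set", "serve", "block"], 210),
    ("G5", 9, ["serve", "spike", "block", "dig"], 370),
]


def generate_cohort(group_table: list[tuple] | None = None,
                    scale: float = 1.0, seed: int = 0,
                    specs: list[SensorSpec] | None = None,
                    trials_per_action: int = 1,
                    cycle_s: float = CYCLE_S,
                    ) -> list[MultimodalRecording]:
    """Generate one cohort of recordings following a group table.

    Each row is ``(group_id, n_participants, actions, total_minutes)``.
    ``scale`` in (0, 1] multiplies every trial duration (desk-scale runs);
    sample counts are recomputed from the scaled durations.
    """
    if group_table is None:
        group_table = DEFAULT_GROUP_TABLE
    if not group_table:
        raise ValueError("group table must be nonempty")
    if not 0 < scale <= 1:
        raise ValueError("scale must be in (0, 1]")
    base = specs if specs is not None else default_specs()
    scaled = [replace(s, duration=s.duration * scale) for s in base]
    ss = np.random.SeedSequence(seed)
    out: list[MultimodalRecording] = []
    sid = 0
    for group_id, n_part, actions, _minutes in group_table:
        for _ in range(int(n_part)):
            subject_id = f"S{sid:03d}"
            child = np.random.SeedSequence(entropy=ss.entropy,
                                           spawn_key=(sid,))
            subj_rng = np.random.default_rng(child)
            sp = {"variability": 0.2 + 0.3 * subj_rng.random(),
                  "strength": 0.7 + 0.6 * subj_rng.random()}
            for a_i, action in enumerate(actions):
                for trial in range(trials_per_action):
                    trial_seed = int(subj_rng.integers(0, 2 ** 31 - 1))
                    out.append(generate_recording(
                        scaled, action, subject_params=sp,
                        seed=trial_seed, subject_id=subject_id,
                        group_id=group_id, cycle_s=cycle_s))
            sid += 1
    return out


def measure_snr_db(observed: np.ndarray, clean: np.ndarray) -> float:
    """SNR in dB of `observed` against the known clean signal."""
    noise = observed - clean
    p_sig = float(np.mean(clean ** 2))
    p_noise = float(np.mean(noise ** 2))
    if p_noise == 0:
        return np.inf
    return 10.0 * np.log10(p_sig / p_noise)


def inject_noise(recording: MultimodalRecording, snr_db: float,
                 drift_rate: float = 0.0, jitter_ms: float = 0.0,
                 seed: int = 0) -> MultimodalRecording:
    """Return a copy with additive noise at an exact realized SNR.

    White Gaussian noise is scaled per channel group so that the realized
    signal-to-noise ratio equals `snr_db` (power-ratio construction, so the
    error is far below 0.5 dB).  Linear amplitude drift (`drift_rate` per
    second, in units of each series' std) and timestamp jitter
    (`jitter_ms` std, applied by resampling) are optional.  Ground truth
    and the clean series are left untouched; `snr_db = inf` with zero
    drift and jitter returns an identical copy.
    """
    if not np.isfinite(snr_db) and not (drift_rate or jitter_ms):
        return replace(recording, series={k: v.copy()
                                          for k, v in recording.series.items()})
    rng = np.random.default_rng(seed)
    new_series: dict[str, np.ndarray] = {}
    for s in recording.specs:
        x = recording.series[s.name].copy()
        ts = s.timestamps()
        if jitter_ms:
            jt = ts + rng.normal(0, jitter_ms / 1000.0, size=len(ts))
            x = np.column_stack([
                np.interp(np.clip(jt, ts[0], ts[-1]), ts, x[:, c])
                for c in range(x.shape[1])])
        if drift_rate:
            x = x + drift_rate * ts[:, None] * x.std(axis=0, keepdims=True)
        if np.isfinite(snr_db):
            p_sig = np.mean(x ** 2)
            w = rng.standard_normal(x.shape)
            w_scale = np.sqrt(p_sig / 10 ** (snr_db / 10.0) / np.mean(w ** 2))
            x = x + w_scale * w
        new_series[s.name] = x
    return replace(recording, series=new_series)
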