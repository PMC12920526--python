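import numpy as np
import pytest

from dsfusion import dsnet, pipeline, synthgen
from dsfusion.objectives import TaskTargets


@pytest.fixture(scope="session")
def desk_recording():
    """One short, reduced-rate recording with mild noise."""
    return synthgen.generate_recording(
        synthgen.desk_specs(duration=2.0), "spike", seed=42)


@pytest.fixture(scope="session")
def clean_recording():
    """Noise-free desk-scale recording (degenerate-case oracles)."""
    return synthgen.generate_recording(
        synthgen.desk_specs(duration=2.0), "serve",
        noise={"amplitude": 0.0}, seed=7)


@pytest.fixture(scope="session")
def tiny_model():
    """A small dual-stream model plus a random sequence and targets."""
    rng = np.random.default_rng(0)
    cfg = dsnet.ModelConfig(kinematic_dim=3, physiological_dim=4,
                            n_joints=2, n_emg=2, vel_dim=2,
                            hidden_size=5, attention_dim=4, fusion_dim=4)
    params = dsnet.init_params(cfg, seed=1)
    T = 7
    Xk = rng.normal(size=(T, 3))
    Xp = rng.normal(size=(T, 4))
    targets = TaskTargets(y_pose=rng.normal(size=(T, 6)),
                          y_emg=rng.normal(size=(T, 2)),
                          y_vel=rng.normal(size=(T, 2)), action=0)
    return cfg, params, Xk, Xp, targets


@pytest.fixture(scope="session")
def desk_dataset():
    """Small preprocessed cohort split chronologically (train/val/test)."""
    specs = synthgen.desk_specs(duration=2.5)
    table = [("G1", 2, ["spike", "serve"], 5.0),
             ("G2", 2, ["block", "set"], 5.0)]
    recs = synthgen.generate_cohort(table, specs=specs, seed=11,
                                    trials_per_action=2)
    seqs = pipeline.build_sequences(recs, model_rate=40.0)
    return pipeline.standardize_and_split(seqs)
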