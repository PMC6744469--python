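import numpy as np
import pytest
from hypothesis import settings

from oxinet import PatientProfile, simulate_record
from oxinet.experiment import RunConfig

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def clean_profile():
    """Noise-free, artifact-free profile where every event desaturates."""
    return PatientProfile(
        target_ahi=30.0, noise_sd=0.0, artifact_rate=0.0, desat_yield=1.0,
        event_duration_s=30.0, resat_duration_s=20.0,
        recording_duration_s=14400.0,
    )


@pytest.fixture
def clean_record(clean_profile):
    return simulate_record(clean_profile, seed=3)


def tiny_run_config(seed: int = 5) -> RunConfig:
    """A minutes-scale experiment configuration for workflow tests."""
    from oxinet.ann import TrainingConfig

    return RunConfig(
        n_train=6, n_val=2, n_test=3, seed=seed, epoch_subsample=100,
        training=TrainingConfig(max_iterations=25, max_val_failures=100),
    )


def constant_output_model(c: float, n_in: int = 300):
    """An MLP whose prediction is the constant c, with identity norms."""
    from oxinet.ann import MinMaxNorm, init_model

    m = init_model((n_in, 4, 1), seed=0)
    for w in m.weights:
        w[...] = 0.0
    for b in m.biases:
        b[...] = 0.0
    m.biases[-1][...] = c
    m.input_norm = MinMaxNorm(lo=np.full(n_in, -1.0), hi=np.full(n_in, 1.0))
    m.target_norm = MinMaxNorm(lo=np.array([-1.0]), hi=np.array([1.0]))
    return m
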