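import numpy as np
import pytest

from proprioadapt import DEFAULT_PROTOCOL, ParticipantParams


@pytest.fixture(scope="session")
def protocol():
    return DEFAULT_PROTOCOL


@pytest.fixture
def rng():
    return np.random.default_rng(20240518)


def make_params(**overrides) -> ParticipantParams:
    """A noiseless perfect matcher / fast learner; override per test."""
    base = dict(
        group="control",
        age=60.0,
        sex="F",
        handedness="R",
        apm_noise_sd=0.0,
        apm_contraction=1.0,
        apm_shift=(0.0, 0.0),
        amm_latency=0.0,
        amm_speed_ratio=1.0,
        amm_dir_error_sd=0.0,
        amm_path_ratio=1.0,
        learner_retention=1.0,
        learner_rate=0.5,
        baseline_dir_sd=0.0,
        tlt=0,
        rng_seed=12345,
    )
    base.update(overrides)
    return ParticipantParams(**base)


@pytest.fixture
def perfect_params():
    return make_params()
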