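import numpy as np
import pytest

from gaitdyn import synthetic as syn


@pytest.fixture(scope="session")
def small_session():
    """A modest two-condition session shared across read-only tests."""
    cfg = syn.GroundTruthConfig(
        n_units=16,
        latent_dim=4,
        n_trials_per_condition=15,
        conditions=[("TRM", 4.0), ("CORR", 3.2)],
        gait_period_range=(0.5, 0.7),
        base_log_rate_range=(-1.5, -0.3),
        loading_scale=0.45,
        kinematic_noise_sd=0.002,
        missing_kinematics_fraction=0.2,
        seed=11,
    )
    return syn.generate_session(cfg)


@pytest.fixture(scope="session")
def noise_free_session():
    cfg = syn.GroundTruthConfig(
        n_units=12,
        latent_dim=4,
        n_trials_per_condition=12,
        conditions=[("TRM", 4.0)],
        gait_period_range=(0.5, 0.7),
        kinematic_noise_sd=0.0,
        seed=5,
    )
    return syn.generate_session(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
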