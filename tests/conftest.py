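import numpy as np
import pytest

from alphanft.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    """A slow-path-sized study: 2 subjects, 4 sessions, short recordings."""
    return SimulationConfig(
        n_subjects=2, n_sessions=4, trials_per_session=2,
        trial_duration_s=60.0, baseline_duration_s=30.0, ecrs_duration_s=30.0,
        artifact_rate_per_min=0.0, seed=11,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One default fast-path cohort (46 subjects x 12 sessions x 6 trials)."""
    return generate_cohort(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Fast-path cohort with every measurement-noise source switched off."""
    cfg = SimulationConfig(
        seed=2, baseline_day_cv=0.0, trial_noise_cv=0.0,
        ecrs_noise_cv=0.0, spectrum_bin_cv=0.0,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
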