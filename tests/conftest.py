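import pytest

from turnwork import SimConfig, simulate_still, simulate_trial

#: generator overrides that remove every stochastic disturbance, so that
#: downstream stages can be checked against the closed-form ground truth
NOISELESS = dict(
    acc_noise_sd=0.0, gyro_noise_sd=0.0, baro_noise_sd=0.0,
    acc_bias=(0.0, 0.0, 0.0), gyro_bias=(0.0, 0.0, 0.0),
    gyro_drift_rate=0.0, impact_amplitude=0.0, clock_offset=0.0,
)


@pytest.fixture(scope="session")
def quiet_cfg():
    return SimConfig(n_turns=8, seed=1, **NOISELESS)


@pytest.fixture(scope="session")
def quiet_pair(quiet_cfg):
    return simulate_trial(quiet_cfg)


@pytest.fixture(scope="session")
def noisy_cfg():
    # default noise/bias/drift, but a known clock so event times are comparable
    return SimConfig(n_turns=12, seed=3, clock_offset=0.0)


@pytest.fixture(scope="session")
def noisy_pair(noisy_cfg):
    return simulate_trial(noisy_cfg)


@pytest.fixture(scope="session")
def noisy_still(noisy_cfg):
    return simulate_still(noisy_cfg, duration=120.0)
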