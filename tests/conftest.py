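import numpy as np
import pytest

from emcscreen import observer, preprocess, stimulus


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_clean_trials(obs, mode, n_trials=6, seed=0, **config_kwargs):
    """Simulate and preprocess one session for a given observer."""
    cfg = stimulus.SessionConfig(n_trials=n_trials, seed=seed, **config_kwargs)
    rng = np.random.default_rng(seed)
    trials = []
    for traj in stimulus.generate_session(cfg, mode, rng):
        gaze = observer.simulate_gaze(traj, obs, rng=rng)
        trials.append(preprocess.preprocess_trial(gaze, traj))
    return trials


@pytest.fixture(scope="session")
def quiet_observer():
    """Low-noise observer with a known 0.2 s pursuit lag, no blinks."""
    return observer.ObserverModel(
        lag=0.2, noise_sd=0.3, blink_rate=0.0, blink_duration=0.0,
    )


@pytest.fixture(scope="session")
def identity_observer():
    return observer.ObserverModel(
        lag=0.0, gain=1.0, noise_sd=0.0, blink_rate=0.0, blink_duration=0.0,
        motor_smoothing=0.0, reacquisition_jitter=0.0,
    )
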