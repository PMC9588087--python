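import numpy as np
import pytest

from attnsal import (BehaviorParams, TaskConfig, generate_population,
                     generate_trial_schedule, simulate_session_behavior)


def make_session(paradigm, n_trials, n_neurons, profile, seed, p_single=0.0):
    config = TaskConfig(paradigm=paradigm, p_single=p_single, rng_seed=seed)
    trials = generate_trial_schedule(config, n_trials, seed)
    trials = simulate_session_behavior(trials, BehaviorParams(paradigm=paradigm), seed + 1)
    session = generate_population(profile, n_neurons, trials, seed + 2, config=config)
    return session


@pytest.fixture(scope="session")
def ofc_session():
    """150 OFC-like neurons, 600 double-stimulus trials (value-coding recovery)."""
    return make_session("D", 600, 150, "OFC-like", seed=101)


@pytest.fixture(scope="session")
def dlpfc_session():
    """100 DLPFC-like neurons with the pre/post cue-coding sign flip."""
    return make_session("D", 600, 100, "DLPFC-like", seed=202)


@pytest.fixture(scope="session")
def small_session():
    """Cheap mixed session (with single-stimulus trials) for I/O and smoke tests."""
    return make_session("D", 240, 8, "OFC-like", seed=303, p_single=0.071)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
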