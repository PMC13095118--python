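import numpy as np
import pandas as pd
import pytest

from seqsleep.preprocess import EpochSet
from seqsleep.synthdata import (
    SleepGenParams,
    WakeGenParams,
    make_layer_features,
    make_sequence_design,
    simulate_sleep_record,
    simulate_wake_session,
)


@pytest.fixture(scope="session")
def design():
    return make_sequence_design(order_variant="letter-scene-object-face", seed=7)


@pytest.fixture(scope="session")
def features(design):
    return make_layer_features(design, seed=8)


@pytest.fixture(scope="session")
def small_wake(design, features):
    """A small pre/post session pair with a strong, late successor leak."""
    params = WakeGenParams(
        n_trials_per_image=2, n_channels=24, successor_amp=0.0, noise_sd=1.5, seed=9
    )
    pre = simulate_wake_session(design, features, params, "pre")
    from dataclasses import replace

    post = simulate_wake_session(
        design, features, replace(params, successor_amp=2.0), "post"
    )
    return pre, post


@pytest.fixture(scope="session")
def sleep_record():
    """Synthetic nap with amplitude ratio >= 4 over background in-band."""
    params = SleepGenParams(
        duration=420.0, so_amp=225.0, spindle_amp=60.0, noise_amp=15.0,
        p_coupled=0.6, coupling_mu=0.3, coupling_kappa=5.0, seed=13,
    )
    record, truth = simulate_sleep_record(params)
    return record, truth, params


def toy_epochs(data, sample_rate=250.0, t0=-0.5):
    """Wrap a raw array as an EpochSet with minimal metadata."""
    data = np.asarray(data, dtype=float)
    n_trials = data.shape[0]
    times = t0 + np.arange(data.shape[2]) / sample_rate
    trials = pd.DataFrame(
        {
            "image": [f"img{i}" for i in range(n_trials)],
            "category": ["object"] * n_trials,
            "subcategory": ["animate"] * n_trials,
            "session": ["pre"] * n_trials,
            "correct": [True] * n_trials,
            "is_target": [False] * n_trials,
        }
    )
    return EpochSet(data=data, times=times, sample_rate=sample_rate, trials=trials)
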