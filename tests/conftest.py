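import numpy as np
import pytest

from eegoverlap import (
    BehaviourConfig,
    EEGSimConfig,
    EventTable,
    Recording,
    simulate_recording,
    simulate_trial_measures,
)

import pandas as pd


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def line_positions():
    """Eight channels on a line, unit spacing (chain adjacency at 1.5)."""
    return np.column_stack([np.arange(8.0), np.zeros(8), np.zeros(8)])


@pytest.fixture
def small_recording(rng):
    data = rng.standard_normal((3, 5000))
    return Recording(
        data=data,
        srate=500.0,
        channel_labels=["C1", "C2", "C3"],
        channel_positions=np.column_stack([np.arange(3.0), np.zeros(3), np.zeros(3)]),
    )


@pytest.fixture
def small_events():
    frame = pd.DataFrame(
        {
            "participant_id": "p01",
            "stimulus_sample": [1000, 2200, 3400],
            "response_sample": [1400.0, 2600.0, 4000.0],
        }
    )
    return EventTable(frame, 500.0)


@pytest.fixture(scope="session")
def overlap_dataset():
    """Small overlap-only synthetic dataset shared across read-only tests."""
    beh = BehaviourConfig(
        n_trials=120, rt_shift=0.15, rt_mu0=-0.25, rt_sigma=0.35, seed=77
    )
    measures, latents = simulate_trial_measures(beh)
    eeg = EEGSimConfig(
        stim_base_amp=5.0,
        stim_gain_appraisal=0.0,
        resp_base_amp=0.0,
        noise_white_sd=1.0,
        seed=78,
    )
    recording, events, truth = simulate_recording(measures, latents, eeg)
    return recording, events, truth
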