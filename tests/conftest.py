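import numpy as np
import pytest

from optodetect.behavior import TrialRecord
from optodetect.synthetic_data import PsychTruth, SimConfig, simulate_session


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        n_neurons=120,
        trial_type_set=(0, 5, 10, 25, 50),
        trial_ratios=(0.25, 0.25, 0.2, 0.15, 0.15),
        n_trials=80,
        warmup_trials=5,
        psych_truth=PsychTruth(np.log(21.0), 1.35, 0.05, 0.1),
        seed=11,
    )


@pytest.fixture(scope="session")
def session(small_config):
    return simulate_session(small_config)


def make_trial(idx, trial_type, onset, licks=(), autoreward=None):
    return TrialRecord(
        trial_index=idx,
        trial_type=trial_type,
        onset_s=onset,
        lick_times_s=np.asarray(licks, dtype=float),
        autoreward_s=autoreward,
    )
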