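import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import landsyn as ls

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sg_cohort():
    """Small stable-ground cohort shared across unit tests."""
    return ls.make_cohort(5, condition="SG", seed=1234)


@pytest.fixture(scope="session")
def conditioned_trial(sg_cohort):
    """One segmented, conditioned, cycle-normalized trial."""
    trial = sg_cohort[0]
    seg = ls.segment_landing(trial.vgrf, trial.bodyweight)
    env = ls.condition_emg(trial.emg_raw)
    emg300 = ls.time_normalize_channels(env.values, seg)
    return trial, seg, emg300


def gaussian_bump(center, width, n=300):
    t = np.arange(1, n + 1, dtype=float)
    sigma = width / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return np.exp(-0.5 * ((t - center) / sigma) ** 2)
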