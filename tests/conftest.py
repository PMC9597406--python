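import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from gaitcosts.emg import MUSCLES
from gaitcosts.synthetic import ParticipantProfile

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def profile() -> ParticipantProfile:
    """One deterministic participant with round-number ground truth."""
    return ParticipantProfile(
        participant_id="T01",
        mass=70.0,
        height=1.70,
        baseline_gains=pd.Series(1e-4, index=list(MUSCLES)),
        incline_slope=pd.Series(0.05, index=list(MUSCLES)),
        crouch_gains=pd.Series(
            [1.3, 1.3, 3.0, 3.0, 1.5, 1.5, 1.2], index=list(MUSCLES)
        ),
        vo2_baseline=0.0143,
        vo2_per_grade=0.0745 * 0.0143,
        vo2_crouch=1.81 * 0.0143,
        rer=0.85,
        stride_time_mean=1.1,
        stride_time_cv=0.03,
        seed=7,
    )


@pytest.fixture
def half_sine_grf():
    """GRF with half-sine stances of 0.7 s starting at 1.0, 2.1, 3.2 s."""
    fs = 2000.0
    t = np.arange(int(5 * fs)) / fs
    grf = np.zeros_like(t)
    for tc in (1.0, 2.1, 3.2):
        m = (t >= tc) & (t < tc + 0.7)
        grf[m] = 800.0 * np.sin(np.pi * (t[m] - tc) / 0.7)
    return np.clip(grf, 0, None), fs
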