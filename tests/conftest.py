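import numpy as np
import pytest

from cardiothought.synthetic import CohortConfig


@pytest.fixture
def clean_config():
    """Small cohort without exclusion-triggering participant types."""
    return CohortConfig(
        n_participants=8,
        seed=123,
        n_bad_pulse=0,
        n_noticed=0,
        n_low_response=0,
        n_no_core=0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def integrate_rr(rr_of_t, duration_s, t0=0.0):
    """Beat times from an RR(t) process in ms (helper for cardiac/HRV tests)."""
    t, times = t0, [t0]
    while t < t0 + duration_s:
        t += rr_of_t(t) / 1000.0
        times.append(t)
    return np.asarray(times)
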