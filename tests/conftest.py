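import numpy as np
import pytest

from foragedyn.dual_state import DualStateParams, simulate_dual_state
from foragedyn.event_model import EventLog


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(173)


@pytest.fixture
def tiny_log():
    """Three events, two intervals, default 08:00-light schedule."""
    return EventLog(
        timestamps=np.array([0.0, 10.0, 30.0]),
        options=np.array([0, 1, 0]),
    )


@pytest.fixture(scope="session")
def two_week_sim():
    """One 14-day dual-state simulation at the default (dark-weighted) profile.

    Session-scoped: several temporal tests reuse it read-only.
    """
    return simulate_dual_state(DualStateParams(), duration=14 * 86400.0, seed=7)


@pytest.fixture(scope="session")
def persistent_sequence():
    """A strongly persistent 4-option sequence (repeat probability 0.9)."""
    rng = np.random.default_rng(11)
    seq = np.empty(2000, dtype=np.int64)
    seq[0] = 0
    for t in range(1, 2000):
        if rng.random() < 0.9:
            seq[t] = seq[t - 1]
        else:
            seq[t] = rng.integers(0, 4)
    return seq
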