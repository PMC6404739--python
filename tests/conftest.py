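import numpy as np
import pytest

from efmt.config import TrialConfig
from efmt.trial import apply_locf, run_trial


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_trial():
    """One seeded default-configuration trial (51 participants), sessions
    simulated through the task engine, LOCF variant attached."""
    cfg = TrialConfig()
    ds = run_trial(cfg, np.random.default_rng(2024), seed=2024)
    return apply_locf(ds)


@pytest.fixture(scope="session")
def small_trial():
    """A small, fast trial (no task-engine sessions) for I/O and analysis tests."""
    cfg = TrialConfig(n_participants=24, simulate_sessions=False)
    ds = run_trial(cfg, np.random.default_rng(7), seed=7)
    return apply_locf(ds)
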