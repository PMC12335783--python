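import numpy as np
import pytest

from qeyed.sim import SimConfig, simulate_cohort, simulate_recording


@pytest.fixture(scope="session")
def small_cohort():
    """Two simulated participants, three shots each — enough structure for
    windowing/preprocessing tests without noticeable runtime."""
    cfg = SimConfig(n_shots=3, seed=42)
    return simulate_cohort(cfg, 2)


@pytest.fixture(scope="session")
def one_recording():
    # 5 shots make the recording long enough for a 10-level decomposition
    return simulate_recording(SimConfig(n_shots=5, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
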