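import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from ciderev.room import simulate_rir, study_room


@pytest.fixture(scope="session")
def ir_rt60_1():
    """Calibrated study-room impulse response at RT60 = 1.0 s (left ear)."""
    return simulate_rir(study_room(1.0), "left")


@pytest.fixture(scope="session")
def sentences():
    """Eight deterministic pseudo-sentences shared across tests."""
    from ciderev.stimuli import generate_pseudo_sentence
    return [generate_pseudo_sentence(seed) for seed in range(8)]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
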