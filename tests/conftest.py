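import sys
from pathlib import Path

import hypothesis
import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracle importable

from ffhs import SimulationConfig

hypothesis.settings.register_profile(
    "suite", deadline=None, max_examples=60, derandomize=True)
hypothesis.settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A quick two-semester cohort for integration-style tests."""
    return SimulationConfig(seed=7, n_items=400, n_students=600,
                            semesters=("fall2016", "spring2017"))
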