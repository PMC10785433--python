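import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from meioflow import EventTable, MisclassParams


@pytest.fixture
def rng():
    return np.random.default_rng(20240112)


@pytest.fixture
def example_params():
    """Well-separated misclassification triples used across model tests."""
    return MisclassParams(p=(0.9, 0.05, 0.05), q=(0.01, 0.90, 0.09))


@pytest.fixture
def small_table():
    """Four hand-picked events, one per class under the default gates."""
    channels = ["FITC.A", "PE.CF594.A"]
    events = np.array([
        [2_000.0, 500.0],    # GFP
        [200.0, 5_000.0],    # RFP
        [2_000.0, 5_000.0],  # GFP_RFP
        [100.0, 100.0],      # WT
    ])
    return EventTable("four", channels, events)
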