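import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/oracles.py

from zsustain.event_model import EventGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def grid3():
    """3 regions x one threshold: E = 3, six valid sequences."""
    return EventGrid.from_defaults(["a", "b", "c"], thresholds=(1.0,), z_max=5.0)


@pytest.fixture
def grid22():
    """2 regions x thresholds {1,2}: E = 4, six valid sequences."""
    return EventGrid.from_defaults(["a", "b"], thresholds=(1.0, 2.0), z_max=5.0)


@pytest.fixture
def grid_default10():
    """10 regions x one threshold: the test-scale recovery grid."""
    return EventGrid.from_defaults(
        [f"r{i:02d}" for i in range(10)], thresholds=(1.0,), z_max=5.0
    )
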