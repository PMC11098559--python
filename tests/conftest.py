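import numpy as np
import pytest

from myostates.types import DecayTruth


@pytest.fixture
def time_grid():
    """Standard acquisition grid: frames every 5 s for 300 s."""
    return np.arange(0.0, 305.0, 5.0)


@pytest.fixture
def reference_truth():
    """A physiologically typical fiber: 25% DRX at 15 s, 50% SRX at 200 s."""
    return DecayTruth(p1_frac=0.25, t1_s=15.0, p2_frac=0.50, t2_s=200.0)
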