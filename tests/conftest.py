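import numpy as np
import pytest

from urwave import TimeSeriesTrace, TraceModel


@pytest.fixture(scope="session")
def times_72h():
    """Default recording grid: 72 h at 30-min sampling (145 points)."""
    return 0.5 * np.arange(145)


@pytest.fixture(scope="session")
def times_expr():
    """Default expression sampling: 16 points, 19-26.5 h, 30-min steps."""
    return 19.0 + 0.5 * np.arange(16)


@pytest.fixture
def cosine_trace(times_72h):
    def make(period_h, amplitude=1.0, phase=0.0, sample_id="cos"):
        values = amplitude * np.cos(2 * np.pi * times_72h / period_h + phase)
        return TimeSeriesTrace(sample_id, times_72h, values)

    return make


@pytest.fixture
def default_model():
    return TraceModel(seed=1)
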