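import numpy as np
import pytest

from cardiokit.synth import APShapeParams, generate_ap_trace


@pytest.fixture(scope="session")
def clean_shape():
    """Default AP morphology without noise."""
    return APShapeParams(noise_sd=0.0)


@pytest.fixture(scope="session")
def regular_trace(clean_shape):
    """Noiseless 62-s recording with 60 beats at a constant 1-s IBI."""
    trace, gt = generate_ap_trace(
        clean_shape, np.full(59, 1.0), fs=5000.0, duration_s=62.0, start_offset=0.5
    )
    return trace, gt


@pytest.fixture(scope="session")
def slow_trace(clean_shape):
    """Noiseless recording with 20 beats at a constant 3-s IBI."""
    trace, gt = generate_ap_trace(
        clean_shape, np.full(19, 3.0), fs=5000.0
    )
    return trace, gt
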