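import numpy as np
import pytest

from dcecs import phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_gt():
    """Small phantom ground truth shared across tests."""
    return phantom.make_ground_truth(shape=(24, 16), d=20,
                                     tumor_spec=phantom.TumorSpec(radius=4.0),
                                     seed=7, dt=0.15, injection_index=4)


@pytest.fixture(scope="session")
def small_image(small_gt):
    return phantom.synthesize_dynamic_image(small_gt)
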