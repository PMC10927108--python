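import numpy as np
import pytest

from mitotime.networks import BackboneSpec, FrameSpec
from mitotime.synthetic_mitosis import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def desk_sim_config():
    """30-frame, 64x64 three-class regime used throughout the fast tests."""
    return SimConfig.desk()


@pytest.fixture
def tiny_frame_spec():
    return FrameSpec(64, 64, 3)


@pytest.fixture
def reduced_backbone():
    return BackboneSpec.reduced()
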