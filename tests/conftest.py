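import numpy as np
import pytest

from phytomc import ChannelParams, LeafParams, SlotScheme, default_alphabet
from phytomc.experiments import fig_detection_setup


@pytest.fixture
def fast_channel():
    """Windy short-range channel used throughout the absorption study."""
    return ChannelParams(d=1.0, v=3.0, D=0.008, R=0.15, omega=2.0)


@pytest.fixture
def still_channel():
    """Still-air channel with the source one radius away from the sphere."""
    return ChannelParams(d=0.15, v=0.0, D=0.008, R=0.15, omega=2.0)


@pytest.fixture
def leaf_si():
    return LeafParams()


@pytest.fixture
def leaf_printed():
    return LeafParams(conductance_mode="as_printed")


@pytest.fixture
def scheme():
    return SlotScheme(T_s=2.0)


@pytest.fixture
def alphabet():
    return default_alphabet()


@pytest.fixture(scope="session")
def detection_setup():
    """Shared two-molecule detection configuration (session-scoped: read-only)."""
    return fig_detection_setup()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250929)
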