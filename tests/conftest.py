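import numpy as np
import pytest

import eegdot as ed
from eegdot.scenarios import build_assets


@pytest.fixture(scope="session")
def head_sources():
    return ed.build_spherical_head(resolution=1000)


@pytest.fixture(scope="session")
def assets():
    """Default phantom with eeg32 + regular DOT grid and forward models."""
    return build_assets("eeg32", "dot_regular", 1000)


@pytest.fixture(scope="session")
def small_head():
    head, sources = ed.build_spherical_head(resolution=500)
    return head, sources
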