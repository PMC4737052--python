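import numpy as np
import pytest

from phasemotion import synthetic, video_core


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def edge_video():
    """Rightward ON edge at 40 px/s, full contrast."""
    return synthetic.moving_edge_video("on", (40.0, 0.0), (64, 64), 0.3, 50.0)


@pytest.fixture(scope="session")
def static_video():
    return synthetic.moving_edge_video("on", (0.0, 0.0), (64, 64), 0.2, 50.0)


@pytest.fixture(scope="session")
def small_grid():
    return video_core.make_block_grid(64, 64, 6, 32)


@pytest.fixture(scope="session")
def small_window():
    return video_core.make_gaussian_window(4.0, 32)
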