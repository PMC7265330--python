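import numpy as np
import pytest

from kinetocoloc import SyntheticParams, generate_movie


@pytest.fixture(scope="session")
def small_params():
    """Compact noise-free generator settings for fast unit tests."""
    return SyntheticParams(
        nucleus_radius=4.0,
        n_spots=10,
        shape=(24, 48, 48),
        n_frames=2,
        nebd_frame=0,
        recruit_t50=-100.0,   # plateau from frame 0
        enrichment_ratio=3.0,
        recruit_fmax=0.8,
        noise=False,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_movie(small_params):
    return generate_movie(small_params)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
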