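import numpy as np
import pytest

from cherenkov_polarimetry.synthetic import Scenario


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quiet_scenario():
    """Small noiseless 6 MeV scenario without vignetting or background."""
    return Scenario(beam="6MeV", noise=False, vignette_f=None,
                    background_counts=0.0, image_shape=(60, 44),
                    pixel_scale=3.25, n_frames=1, n_background_frames=1)


@pytest.fixture
def noisy_scenario():
    """Small 6 MeV scenario with the full noise model."""
    return Scenario(beam="6MeV", image_shape=(60, 44), pixel_scale=3.25,
                    n_frames=5, n_background_frames=5, seed=7)
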