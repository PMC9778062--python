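import numpy as np
import pytest

from amoxquant import synthetic


@pytest.fixture()
def clean_render():
    """Noise-free, jitter-free rendering: disk color is exact."""
    return synthetic.RenderParams(
        pixel_noise_sd=0.0, lighting_gain_sd=0.0, vignette_strength=0.0,
        well_radius_jitter=0.0, center_jitter=0.0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
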