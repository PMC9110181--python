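import numpy as np
import pytest

import neurec as nr
from neurec.model import ModelConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_geometry():
    """5 angles, 23 detectors over a 16x16 grid: fits the dense-matrix oracle."""
    return nr.CTGeometry(tuple(np.arange(5) * 36.0), 23)


@pytest.fixture
def tiny_model_config():
    """Width-8 two-block config: cheap enough for finite-difference checks."""
    return ModelConfig(n_blocks=2, hidden_width=8, latent_dim=4, sine_omega=30.0)


@pytest.fixture
def desk_model_config():
    """Reduced-width architecture used for desk-scale training runs."""
    return ModelConfig(n_blocks=4, hidden_width=64, latent_dim=16, sine_omega=8.0)
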