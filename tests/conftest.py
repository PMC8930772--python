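import numpy as np
import pytest

from dropseg.scenes import ARCHETYPES, Calibration, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    """Ten-cell field with sparse, bright, disjoint droplets."""
    return generate_scene(
        ARCHETYPES["bright_sparse"], 10, (160, 160), Calibration(), seed=42,
        border_fraction=0.0, disjoint_droplets=True,
    )


@pytest.fixture(scope="session")
def border_scene():
    """Field in which some cells intentionally touch the image border."""
    return generate_scene(
        ARCHETYPES["wt_like"], 12, (192, 192), Calibration(), seed=7,
        border_fraction=0.3,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
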