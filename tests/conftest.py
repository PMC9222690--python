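import numpy as np
import pytest

from discswarm import (
    SwarmConfig,
    SyntheticFundusSpec,
    build_exploration_area,
    generate,
    standardize_roi,
)

TRUE_CENTER = (128.0, 128.0)
TRUE_RADIUS = 60.0


@pytest.fixture(scope="session")
def clean_disc():
    """Noise-free, vessel-free circular disc of radius 60 centered at (128,128)."""
    spec = SyntheticFundusSpec(
        axes=(TRUE_RADIUS, TRUE_RADIUS), noise_sigma=0.0, vessel_count=0, seed=1
    )
    rgb, mask, _ = generate(spec)
    return spec, rgb, mask


@pytest.fixture(scope="session")
def clean_area(clean_disc):
    """Exploration area over the clean disc with the default 50 sectors."""
    _, rgb, _ = clean_disc
    roi = standardize_roi(rgb)
    return build_exploration_area(roi, center=TRUE_CENTER, n_subgroups=50)


@pytest.fixture(scope="session")
def small_area(clean_disc):
    """Same field partitioned into 4 sectors (for exhaustive-search oracles)."""
    _, rgb, _ = clean_disc
    roi = standardize_roi(rgb)
    return build_exploration_area(roi, center=TRUE_CENTER, n_subgroups=4)


@pytest.fixture
def small_config():
    return SwarmConfig(n_subgroups=4, n_particles=10, iterations=50)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
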