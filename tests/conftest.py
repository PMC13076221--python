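import numpy as np
import pytest

from lipidspec.core import WavenumberGrid
from lipidspec.simulate import ScenarioConfig, generate_phantom_cube


@pytest.fixture(scope="session")
def fingerprint_grid():
    return WavenumberGrid.fingerprint(2.0)


def small_phantom_config(**overrides):
    """A 48x48 phantom config: fast but with real wells (radius 11)."""
    kwargs = dict(
        scenario="phantom2d", seed=7, image_size=48, well_radius=11
    )
    kwargs.update(overrides)
    return ScenarioConfig(**kwargs)


@pytest.fixture(scope="session")
def small_phantom():
    return generate_phantom_cube(small_phantom_config())


@pytest.fixture(scope="session")
def clean_phantom():
    """Noiseless, drift-free small phantom."""
    return generate_phantom_cube(
        small_phantom_config(noise_sigma=0.0, drift_range=(1.0, 1.0))
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
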