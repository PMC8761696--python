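import numpy as np
import pytest

from swellmd import synthetic_data as sd


@pytest.fixture(scope="session")
def small_well_spec():
    """Small, fast well used by most segmentation tests."""
    return sd.SyntheticWellSpec(
        image_shape=(384, 384),
        n_organoids=6,
        noise_sigma=0.01,
        seed=11,
    )


@pytest.fixture(scope="session")
def chain10():
    """10-residue linear CA chain, 3.8 A spacing."""
    return sd.generate_reference_structure(10, spacing=3.8)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
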