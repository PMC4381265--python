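import numpy as np
import pytest

from smnrisk.phantom import PhantomConfig, generate_case

#: Coarse grid covering the same 256 x 256 x 720 mm patient volume as the
#: default phantom — identical geometry, 8x fewer voxels, fast tests.
SMALL_SHAPE = (32, 32, 80)
SMALL_SPACING = (8.0, 8.0, 9.0)


def small_config(**kwargs) -> PhantomConfig:
    kwargs.setdefault("shape", SMALL_SHAPE)
    kwargs.setdefault("spacing", SMALL_SPACING)
    return PhantomConfig(**kwargs)


@pytest.fixture(scope="session")
def photon_case_exact():
    """Zero-noise photon case: out-of-field doses are exact model values."""
    return generate_case(small_config(modality="photon", noise_sigma=0.0, seed=11))


@pytest.fixture(scope="session")
def photon_case_noisy():
    return generate_case(small_config(modality="photon", noise_sigma=0.05, seed=12))


@pytest.fixture(scope="session")
def proton_case_exact():
    return generate_case(small_config(modality="proton", noise_sigma=0.0, seed=13))


@pytest.fixture(scope="session")
def proton_case_noisy():
    return generate_case(small_config(modality="proton", noise_sigma=0.05, seed=14))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
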