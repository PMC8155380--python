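import numpy as np
import pytest

from refrase import PhantomSpec, build_geometry, simulate_phantom


@pytest.fixture(scope="session")
def spec48():
    """Small phantom spec used by geometry/signal unit tests."""
    return PhantomSpec.scaled(grid=48, rng_seed=7)


@pytest.fixture(scope="session")
def phantom48(spec48):
    """Noisy 48^3 phantom instance (series, ground truth)."""
    return simulate_phantom(spec48)


@pytest.fixture(scope="session")
def phantom48_clean(spec48):
    """Noise-free companion of phantom48 (same geometry and fields)."""
    return simulate_phantom(spec48, add_noise=False)


@pytest.fixture(scope="session")
def labels48(spec48):
    return build_geometry(spec48)


@pytest.fixture()
def ball_mask_32():
    """Connected spherical mask inside a 32^3 grid."""
    g = np.ogrid[:32, :32, :32]
    r2 = sum((gi - 15.5) ** 2 for gi in g)
    return r2 <= 13.0**2
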