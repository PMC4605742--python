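import numpy as np
import pytest

from se3fod import (
    BundleGeometry,
    CSDConfig,
    NoiseModel,
    csd_fit_volume,
    default_response,
    make_phantom,
    simulate_dwi,
)
from se3fod.kernel import EnhancementParams, build_kernel_lut
from se3fod.sphere import SHBasis, cached_icosphere
from se3fod.synthetic import uniform_gradients


@pytest.fixture(scope="session")
def icosphere3():
    return cached_icosphere(3)


@pytest.fixture(scope="session")
def icosphere4():
    return cached_icosphere(4)


@pytest.fixture(scope="session")
def icosphere16():
    return cached_icosphere(16)


@pytest.fixture(scope="session")
def basis8():
    return SHBasis(8)


@pytest.fixture(scope="session")
def gradients64():
    return uniform_gradients(64)


@pytest.fixture(scope="session")
def response():
    return default_response(3000.0)


@pytest.fixture(scope="session")
def small_lut(icosphere3):
    """Compact enhancement kernel LUT for fast convolution tests."""
    return build_kernel_lut(
        EnhancementParams(1.0, 0.02, 1.0), icosphere3,
        half_width=3, mass_tolerance=0.2,
    )


@pytest.fixture(scope="session")
def crossing45_truth():
    """45-degree two-bundle crossing phantom on a 13^3 mm grid."""
    c, s = np.cos(np.radians(45)), np.sin(np.radians(45))
    g1 = BundleGeometry(kind="straight", radius=2.0, start=(0, 6, 6), end=(12, 6, 6))
    g2 = BundleGeometry(
        kind="straight", radius=2.0,
        start=(6 - 6 * c, 6 - 6 * s, 6), end=(6 + 6 * c, 6 + 6 * s, 6),
    )
    return make_phantom([g1, g2], (13, 13, 13), (1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def straight_truth():
    geo = BundleGeometry(kind="straight", radius=2.0, start=(2, 8, 8), end=(28, 8, 8))
    return make_phantom([geo], (31, 17, 17), (1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def straight_fod(straight_truth, gradients64, response):
    dw = simulate_dwi(
        straight_truth, response, gradients64, 3000.0, NoiseModel(snr=np.inf)
    )
    return csd_fit_volume(dw, response, CSDConfig(l_max=8))
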