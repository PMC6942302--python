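"""Shared fixtures: phantoms and their pipeline results, computed once."""

import numpy as np
import pytest

from stemsect.phantom import PhantomSpec, generate_phantom
from stemsect.vbdetect import detect_vascular_bundles
from stemsect.zones import detect_function_zones


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, unfused phantom: the exact-recovery reference."""
    return generate_phantom(PhantomSpec(seed=3, noise_sd=0,
                                        fusion_fraction=0.0))


@pytest.fixture(scope="session")
def clean_zones(clean_phantom):
    return detect_function_zones(clean_phantom.image)


@pytest.fixture(scope="session")
def clean_bundles(clean_phantom, clean_zones):
    return detect_vascular_bundles(clean_phantom.image, clean_zones)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default-noise phantom with deliberate fusions."""
    return generate_phantom(PhantomSpec(seed=5, noise_sd=10,
                                        fusion_fraction=0.05))


@pytest.fixture(scope="session")
def noisy_zones(noisy_phantom):
    return detect_function_zones(noisy_phantom.image)


@pytest.fixture(scope="session")
def noisy_bundles(noisy_phantom, noisy_zones):
    return detect_vascular_bundles(noisy_phantom.image, noisy_zones)


@pytest.fixture(scope="session")
def small_phantom():
    """Reduced-size phantom for cheap store/pipeline tests."""
    return generate_phantom(PhantomSpec(seed=11, image_size=512,
                                        outer_radius=245, inner_radius=140,
                                        n_periphery=60, n_inner=10))


def disk_mask(shape, center, radius):
    yy, xx = np.indices(shape)
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2
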