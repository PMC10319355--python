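"""Shared synthetic fixtures (session-scoped: rendering is the costly step)."""

import numpy as np
import pytest

from wormquant import LumenBand, WormSpec, generate_worm_image
from wormquant.synthetic import tapered_radius


@pytest.fixture(scope="session")
def cylinder_worm():
    """Straight constant-radius worm: every truth value has a closed form."""
    spec = WormSpec(length_um=1000.0, radius_um=25.0, pixels_per_um=5.0, seed=1)
    image, truth = generate_worm_image(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def tapered_worm():
    """Realistic smoothly tapered, gently bent worm."""
    spec = WormSpec(
        length_um=1000.0,
        radius_um=tapered_radius(25.0),
        bend_amplitude_um=60.0,
        pixels_per_um=5.0,
        seed=2,
    )
    image, truth = generate_worm_image(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def lumen_worm():
    """Constant-radius worm with a 5-µm posterior lumen band."""
    spec = WormSpec(
        length_um=1000.0,
        radius_um=25.0,
        pixels_per_um=5.0,
        seed=3,
        lumen=LumenBand(width_fraction=0.10, contrast=12000.0),
    )
    image, truth = generate_worm_image(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def small_worm():
    """Small, quick-to-measure worm for pipeline-level tests."""
    spec = WormSpec(
        length_um=500.0,
        radius_um=tapered_radius(20.0),
        bend_amplitude_um=25.0,
        pixels_per_um=2.0,
        seed=11,
    )
    image, truth = generate_worm_image(spec)
    return spec, image, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
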