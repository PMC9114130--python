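import logging

import numpy as np
import pytest

from colonymorph.synthetic_colony import GrowthSpec, generate_ensemble, texture_preset

logging.getLogger("colonymorph").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def tiny_growth():
    """Coarse, fast cadence for structural tests (not the study conditions)."""
    return GrowthSpec(
        initial_radius_px=30,
        final_radius_px=70,
        duration_hours=24,
        sampling_median_minutes=360,
        sampling_jitter=0.2,
        dropout_prob=0.0,
    )


@pytest.fixture(scope="session")
def tiny_ensemble(tiny_growth):
    """2 texture classes x 2 colonies, ~5 frames each."""
    specs = [(texture_preset("smooth"), 2), (texture_preset("ridged"), 2)]
    return generate_ensemble(specs, tiny_growth, seed=11)


def disk_image(size=200, radius=60, inside=0.9, outside=0.1, noise=0.0, seed=0):
    c = (size - 1) / 2
    yy, xx = np.mgrid[0:size, 0:size]
    img = np.where((yy - c) ** 2 + (xx - c) ** 2 <= radius**2, inside, outside).astype(float)
    if noise:
        img += np.random.default_rng(seed).normal(0, noise, img.shape)
    return img
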