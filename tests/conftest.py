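import numpy as np
import pytest

import ndvigap as ng


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale scene used by unit tests (full default size is exercised
    by the end-to-end acceptance test)."""
    return ng.SceneConfig(fine_shape=(96, 96), blob_scale=8, seed=11)


@pytest.fixture(scope="session")
def small_scene(small_config):
    return ng.generate_scene(small_config, 12)


@pytest.fixture(scope="session")
def power_law_pairs():
    """1000 synthetic pairs from the monotone distortion y = x^0.85 with
    additive noise sigma = 0.02."""
    gen = np.random.default_rng(2024)
    x = gen.uniform(0, 1, 1000)
    y = np.clip(x**0.85 + gen.normal(0, 0.02, 1000), 0, 1)
    return ng.pairs_from_arrays(x, y, provenance={"sampling": "power-law"})


@pytest.fixture(scope="session")
def trained_model(power_law_pairs):
    return ng.train(power_law_pairs, seed=0).model


def random_grid(gen, shape=(16, 16), nodata_fraction=0.0, low=0.0, high=1.0):
    vals = gen.uniform(low, high, shape)
    nodata = gen.random(shape) < nodata_fraction
    return ng.RasterGrid(values=vals, nodata=nodata)
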