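import numpy as np
import pytest

from splintleaf.synthetic import GeneratorParams, generate_leaf


@pytest.fixture(scope="session")
def small_params() -> GeneratorParams:
    """64x64 frame at 0.5 mm/px: cheap samples for unit tests."""
    return GeneratorParams(image_height=64, image_width=64, mm_per_pixel=0.5,
                           leaf_area_range_mm2=(100.0, 250.0), seed=11)


@pytest.fixture(scope="session")
def small_sample(small_params):
    return generate_leaf(small_params)


@pytest.fixture(scope="session")
def default_sample():
    return generate_leaf(GeneratorParams(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
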