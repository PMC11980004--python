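import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_quantized(rng, shape=(8, 8), n_levels=4, mask_fraction=0.8):
    """Random small quantized ROI with a random mask (at least 4 pixels)."""
    from lge_radiomics.core import QuantizedROI

    while True:
        mask = rng.random(shape) < mask_fraction
        if mask.sum() >= 4:
            break
    levels = np.zeros(shape, dtype=np.int64)
    levels[mask] = rng.integers(1, n_levels + 1, int(mask.sum()))
    return QuantizedROI(levels, mask, n_levels)
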