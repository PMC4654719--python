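import numpy as np
import pytest

from thyrotex import CohortConfig, ROIMask, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_masked_raster(rng):
    """Factory: an 8x8 float raster with a random (>= 8 px) mask."""

    def make(seed=None):
        g = np.random.default_rng(seed) if seed is not None else rng
        raster = g.normal(size=(8, 8))
        while True:
            mask = g.random((8, 8)) < 0.6
            if mask.sum() >= 8:
                return raster, ROIMask(mask=mask)

    return make


def small_config(seed=0, **kw):
    """A scaled-down cohort config for fast pipeline tests."""
    defaults = dict(n_benign=6, n_malignant=6, matrix=96, fov=82.5,
                    max_slices=4, seed=seed)
    defaults.update(kw)
    return CohortConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete two-site synthetic cohort (shared, read-only)."""
    cfg = CohortConfig(n_benign=6, n_malignant=6, matrix=96, fov=82.5,
                       max_slices=4, seed=7)
    return generate_cohort(cfg, n_benign_test=4, n_malignant_test=4)
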