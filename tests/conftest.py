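"""Shared fixtures: small synthetic slides sized for fast unit tests."""

import numpy as np
import pytest

from histosample import synthetic_wsi

SMALL = dict(height=320, width=320, n_invasive_blobs=1,
             target_invasive_fraction=0.25, tissue_fraction=0.6)
SMALL_TILE = 41


@pytest.fixture(scope="session")
def small_spec():
    return synthetic_wsi.SyntheticSlideSpec(seed=7, **SMALL)


@pytest.fixture(scope="session")
def small_slide(small_spec):
    return synthetic_wsi.generate_slide(small_spec)


@pytest.fixture(scope="session")
def oracle(small_slide):
    return synthetic_wsi.make_noisy_oracle(small_slide, label_noise=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def default_slide():
    """Full-scale slide at the generator's default study conditions."""
    return synthetic_wsi.generate_slide(synthetic_wsi.SyntheticSlideSpec(seed=0))
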