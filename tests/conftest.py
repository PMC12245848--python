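import numpy as np
import pytest

from hmburden import synthetic
from hmburden.valuation import VslParams


@pytest.fixture(scope="session")
def small_world():
    """A 12-country world spanning the full 1990-2021 panel."""
    cfg = synthetic.WorldConfig(n_countries=12, years=(1990, 2021), seed=1)
    return synthetic.gen_world(cfg)


@pytest.fixture(scope="session")
def params():
    return VslParams()


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
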