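import numpy as np
import pytest

import elevgrad as eg


@pytest.fixture(scope="session")
def default_dataset():
    """The packaged two-slope survey, generated once per session."""
    return eg.generate_dataset(eg.default_config(seed=42))


@pytest.fixture(scope="session")
def ranges_by_slope(default_dataset):
    bands = default_dataset.config.bands
    ranges = eg.build_ranges(default_dataset.captures, bands)
    return {s: [r for r in ranges if r.slope == s]
            for s in default_dataset.config.slopes}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
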