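import numpy as np
import pytest

import fplselect as fp


@pytest.fixture(scope="session")
def tiny_net():
    """Small architecture used to keep training-based tests fast."""
    return fp.BaseNetConfig(hidden_sizes=(32, 16))


@pytest.fixture(scope="session")
def planted_small():
    """Planted table at reduced scale for unit tests (scaled down from the
    selection benchmark's 2000-sample default)."""
    fm, planted = fp.make_tabular(
        fp.TabularSpec(n_samples=400, d0=40, k_informative=6, seed=7))
    return fm, planted


@pytest.fixture(scope="session")
def tiny_segments():
    return fp.make_segments(fp.SignalSpec(n_segments=12, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
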