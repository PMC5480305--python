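import numpy as np
import pytest

from switchlock.design import DesignParams, build_switch_lock


@pytest.fixture
def rng():
    return np.random.default_rng(20170103)


@pytest.fixture(scope="session")
def tiny_design():
    """The smallest 8-letter design (k=1, A=2, B=2), n = 20."""
    params = DesignParams(1, 2, 2)
    seq, rmap = build_switch_lock(params)
    return params, seq, rmap


#: small grid exercised by structural property tests
SMALL_GRID = [(1, 2, 2), (1, 4, 2), (2, 2, 4), (2, 4, 2), (3, 4, 4), (2, 6, 2)]
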