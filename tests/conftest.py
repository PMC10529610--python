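import numpy as np
import pytest

from sensolearn.designs import gen_swi_design


@pytest.fixture(scope="session")
def swi_designs():
    """The three fixed SWI test orders."""
    return [gen_swi_design(order_id=i) for i in (1, 2, 3)]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230911)
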