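import numpy as np
import pytest

import swdcontrol as sw


@pytest.fixture(scope="session")
def params():
    return sw.DEFAULT_PARAMETERS


@pytest.fixture(scope="session")
def focus(params):
    return sw.background_state(params)


@pytest.fixture(scope="session")
def cycle(params):
    """SWD limit cycle in the default bistable regime (expensive; shared)."""
    return sw.extract_limit_cycle(params, sw.default_seed_state(params))


@pytest.fixture(scope="session")
def default_design(params):
    """Default abatement control design (expensive; shared)."""
    return sw.design_default_control(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
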