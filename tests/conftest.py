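import numpy as np
import pytest
from hypothesis import settings

from petct_cea import Conventions, LifeTable, ParameterSet

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def params():
    return ParameterSet()


@pytest.fixture
def conventions():
    return Conventions()


@pytest.fixture
def zero_mortality_table():
    return LifeTable(ages=np.array([0.0]), q_annual=np.array([0.0]))


@pytest.fixture
def flat_table():
    """Constant 2% annual background mortality at every age."""
    return LifeTable(ages=np.array([0.0]), q_annual=np.array([0.02]))
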