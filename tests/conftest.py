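import numpy as np
import pytest

from lckphos.network import build_network, build_validation_network
from lckphos.params import RateParameterSet, table1_median


def uniform_params(value: float = 1.0, **overrides) -> RateParameterSet:
    """A rate set with every entry equal (convenient for structural tests)."""
    base = RateParameterSet(
        k_on=value, k_on_csk=value,
        k_off=np.full(16, value), k_cat=np.full(16, value),
        k_off_csk=np.full(2, value), k_cat_csk=np.full(2, value),
    )
    return base.replace(**overrides) if overrides else base


@pytest.fixture(scope="session")
def active_network():
    return build_network()


@pytest.fixture(scope="session")
def validation_network():
    return build_validation_network()


@pytest.fixture(scope="session")
def median_params():
    return table1_median()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
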