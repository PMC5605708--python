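import numpy as np
import pytest
from hypothesis import settings

# property tests must behave identically on every machine and run
settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from rpcidnp.chain import MotionModel, distance_distribution
from rpcidnp.liouville import RDModelParams, ReactionModel, RelaxationModel
from rpcidnp.spin_system import ExchangeModel
from rpcidnp.synthetic import fixture


@pytest.fixture(scope="session")
def table_params():
    """Fitted parameter set on the default 40-cell grid."""
    return fixture("table1_params")


@pytest.fixture(scope="session")
def f10t():
    return fixture("f10t_reduced")


@pytest.fixture(scope="session")
def toy_system():
    return fixture("one_nucleus_toy")


@pytest.fixture(scope="session")
def small_grid():
    """8-cell grid from smooth synthetic samples, for oracle-sized runs."""
    rng = np.random.default_rng(0)
    return distance_distribution(rng.uniform(9.2, 16.0, 5000), 9.14, 16.0, 8)


@pytest.fixture(scope="session")
def small_params(small_grid):
    """Table-1 rates on the small grid."""
    return RDModelParams(
        exchange=ExchangeModel(-1.6e9, 2.14),
        motion=MotionModel(2.5e-6, small_grid),
        reaction=ReactionModel(4.7e7, 1.0e4),
        relaxation=RelaxationModel(0.3, 5e-11, True),
    )
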