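import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cfdiamond.coalescent import NetworkParameters
from cfdiamond.network import make_partition
from cfdiamond.simulate import true_cf_table

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def study_params() -> NetworkParameters:
    """The simulation study's conditions: all internal branches 1.0, gamma 0.3."""
    return NetworkParameters()


@pytest.fixture(scope="session")
def n2222():
    """The eight-taxon reference network with two taxa per clade."""
    return make_partition(["A", "B"], ["C", "D"], ["E", "F"], ["G", "H"])


@pytest.fixture(scope="session")
def n2222_table(n2222, study_params):
    """Exact 70-row CF table of the reference network."""
    return true_cf_table(n2222, study_params)


def random_z_gamma(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random parameter rows (z..., gamma): t ~ U(0.05,3), gamma ~ U(0.05,0.95)."""
    t = rng.uniform(0.05, 3.0, size=(n, 8))
    return np.hstack([np.exp(-t), rng.uniform(0.05, 0.95, size=(n, 1))])
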