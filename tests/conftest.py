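import numpy as np
import pytest

from isoniche import SpeciesParams, generate_species, table1_defaults


@pytest.fixture(scope="session")
def table1_cfg():
    """The published three-species study design with identity correlation."""
    return table1_defaults(seed=0)


@pytest.fixture(scope="session")
def small_params():
    """A compact trivariate species for fast posterior tests."""
    sigma = np.array([[1.5, 0.3, 0.1], [0.3, 2.0, -0.2], [0.1, -0.2, 1.0]])
    return SpeciesParams("toy", np.array([-15.0, 7.0, 8.0]), sigma, 60)


@pytest.fixture(scope="session")
def small_dataset(small_params):
    return generate_species(small_params, seed=123)


def random_spd(rng, d, scale=1.0):
    """Random symmetric positive-definite matrix (well conditioned)."""
    A = rng.standard_normal((d, d))
    return scale * (A @ A.T + d * np.eye(d))
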