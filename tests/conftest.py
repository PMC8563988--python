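import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from gpsmcap import Alphabet, MSA, reduced_alphabet
from gpsmcap.bench import random_potts
from gpsmcap.potts import enumerate_distribution


@pytest.fixture(scope="session")
def ab2():
    return Alphabet("AB")


@pytest.fixture(scope="session")
def toy_msa(ab2):
    """The {AB, AB, BA, BA} toy used throughout the worked examples."""
    return MSA.from_sequences(["AB", "AB", "BA", "BA"], ab2)


@pytest.fixture(scope="session")
def small_potts():
    """An enumerable coupled Potts target (L=5, q=3) with its exact table."""
    model = random_potts(5, 3, coupling_density=0.5, coupling_scale=0.8,
                         field_scale=0.3, seed=1)
    return model, enumerate_distribution(model)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
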