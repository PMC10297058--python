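import numpy as np
import pytest
from hypothesis import settings

from prevchain import fixtures

settings.register_profile("prevchain", deadline=None, derandomize=True)
settings.load_profile("prevchain")


@pytest.fixture(scope="session")
def rwanda_matrix():
    return fixtures.reference_matrix()


@pytest.fixture(scope="session")
def start_2015():
    return fixtures.start_2015()


@pytest.fixture(scope="session")
def survey_profile():
    return fixtures.survey_profile()


@pytest.fixture(scope="session")
def reference_series():
    """Freshly projected 2015-2025 grid from the fixture inputs."""
    return fixtures.reference_forecast(10)


def random_row_stochastic(k: int, rng: np.random.Generator) -> np.ndarray:
    m = rng.random((k, k)) + 1e-3
    return m / m.sum(axis=1, keepdims=True)
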