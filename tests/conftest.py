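import numpy as np
import pytest
from hypothesis import settings

from carescape.config import StudyConfig
from carescape.synthetic import generate_study

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study, shared read-only across tests."""
    return generate_study(StudyConfig(seed=12345))


@pytest.fixture(scope="session")
def survey(default_study):
    return default_study.survey


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def exact_corr_sample(n: int, R: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Sample whose *sample* correlation and covariance equal R exactly.

    Whitens a random draw to exact identity sample covariance, then colors
    it with chol(R); used to pin closed-form psychometric values.
    """
    k = R.shape[0]
    X = rng.standard_normal((n, k))
    X = X - X.mean(axis=0)
    L = np.linalg.cholesky(np.cov(X, rowvar=False))
    X = X @ np.linalg.inv(L).T
    return X @ np.linalg.cholesky(R).T
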