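import numpy as np
import pytest

from ebrm.cohort import CohortConfig, simulate_cohort


class LinearLearner:
    """Least-squares weak-learner test double (unit tests only)."""

    def __init__(self, coef: np.ndarray):
        self.coef = coef  # (n_features + 1, 2), last row is the intercept

    def predict(self, U: np.ndarray) -> np.ndarray:
        U = np.atleast_2d(np.asarray(U, dtype=float))
        return np.column_stack([U, np.ones(len(U))]) @ self.coef


def linear_factory(U, T, seed):
    A = np.column_stack([np.atleast_2d(U), np.ones(len(U))])
    coef, *_ = np.linalg.lstsq(A, np.atleast_2d(T), rcond=None)
    return LinearLearner(coef)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(CohortConfig(n_subjects=10, seed=42))


@pytest.fixture(scope="session")
def noisefree_config():
    return CohortConfig(
        n_subjects=8,
        within_subject_sd=0.0,
        observer_sd=0.0,
        feature_noise_sd=0.0,
        seed=5,
    )
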