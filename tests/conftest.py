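import numpy as np
import pytest

from lifemr import default_truth, generate_cohort


@pytest.fixture(scope="session")
def small_truth():
    """Disjoint-support two-period model, small enough for fast unit tests."""
    return default_truth(n_individuals=4000, n_early=10, n_late=10, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_truth):
    return generate_cohort(small_truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def oracle_scores(cohort):
    """True-weight period-specific polygenic scores (bypasses discovery)."""
    g = cohort.genotypes.astype(float)
    t = cohort.truth
    return g @ t.alpha1, g @ t.alpha2


def tsls_oracle(z, x, y):
    """Naive two-stage least squares, coded independently of the package.

    First stage: OLS of each exposure on [1, Z]; second stage: OLS of y on
    [1, fitted exposures]; returns the exposure coefficients.
    """
    z = np.atleast_2d(np.asarray(z, float).T).T
    x = np.atleast_2d(np.asarray(x, float).T).T
    n = z.shape[0]
    d1 = np.column_stack([np.ones(n), z])
    xhat = d1 @ np.linalg.lstsq(d1, x, rcond=None)[0]
    d2 = np.column_stack([np.ones(n), xhat])
    coef = np.linalg.lstsq(d2, np.asarray(y, float), rcond=None)[0]
    return coef[1:]
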