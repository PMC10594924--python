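import numpy as np
import pytest
from hypothesis import settings

import ptsdcfa as pc
from ptsdcfa import dataprep, simulate

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def hybrid_spec():
    return pc.get_model("hybrid")


@pytest.fixture(scope="session")
def reference():
    return pc.catalog.reference_estimates()


@pytest.fixture(scope="session")
def paper_dataset():
    """One dataset at the study conditions: N=641, Likert, MCAR holes."""
    ds, truth = simulate.generate(simulate.preset("paper", seed=20230641))
    return ds, truth


@pytest.fixture(scope="session")
def paper_imputed(paper_dataset):
    ds, truth = paper_dataset
    return dataprep.em_impute(ds), truth


@pytest.fixture(scope="session")
def continuous_dataset():
    """Complete continuous data at N=641 (no discretization/missingness)."""
    ds, truth = simulate.generate(simulate.preset("continuous", seed=77))
    return ds, truth


@pytest.fixture(scope="session")
def hybrid_fit_with_se(continuous_dataset):
    ds, _ = continuous_dataset
    result, moments = simulate.fit_on_dataset(
        ds, pc.get_model("hybrid"), robust=True, indices=True, se=True)
    return result, moments


def exact_moments_sample(mean, cov, n, seed=0):
    """Data whose sample mean/covariance equal `mean`/`cov` exactly.

    Whitens a random draw and recolors it, so population-level identities
    can be asserted without Monte-Carlo slack.
    """
    rng = np.random.default_rng(seed)
    mean = np.asarray(mean, float)
    cov = np.asarray(cov, float)
    p = len(mean)
    z = rng.standard_normal((n, p))
    z -= z.mean(axis=0)
    chol_s = np.linalg.cholesky(np.atleast_2d(np.cov(z, rowvar=False,
                                                     ddof=1)))
    white = z @ np.linalg.inv(chol_s).T
    return white @ np.linalg.cholesky(cov).T + mean
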