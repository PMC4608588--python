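import warnings

import numpy as np
import pytest

import dlogit as dl


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def _random_dataset(rng, n=80, p=2, lam=0.2):
    """A small model-consistent contaminated dataset for unit tests."""
    X = rng.normal(size=(n, p))
    beta0, beta = -0.3, rng.normal(size=p)
    from scipy.special import expit

    y = (rng.random(n) < expit(beta0 + X @ beta)).astype(int)
    if y.min() == y.max():  # ensure both classes
        y[0], y[1] = 0, 1
    z = y.copy()
    cases = np.flatnonzero(y == 1)
    flip = cases[rng.random(cases.size) < lam]
    z[flip] = 0
    if (z == 1).sum() == 0:
        z[cases[0]] = 1
    return dl.ContaminatedDataset(X=X, z=z, y_true=y)


@pytest.fixture
def random_dataset(rng):
    return _random_dataset(rng)


def make_random_dataset(seed, n=80, p=2, lam=0.2):
    return _random_dataset(np.random.default_rng(seed), n=n, p=p, lam=lam)


@pytest.fixture(scope="session")
def study_clean():
    """Synthetic case-control study with clean labels (z = y)."""
    return dl.generate_dataset(dl.example_study_config(seed=11, contamination=None))


@pytest.fixture(scope="session")
def study_contaminated(study_clean):
    """Same study with 67 randomly chosen cases relabeled as controls.

    The relabeling draw is one whose MLE is interior (mu-hat > 0); the
    estimator's sampling distribution has an atom at the mu = 0 boundary,
    and the boundary code paths have their own dedicated tests.
    """
    return dl.contaminate(study_clean, k=67, seed=0)


@pytest.fixture(scope="session")
def study_fits(study_contaminated):
    """(LR fit, DLR fit) on the contaminated synthetic study."""
    model = dl.DefectiveLogit(study_contaminated)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit_logistic(), model.fit()
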