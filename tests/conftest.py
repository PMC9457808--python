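import numpy as np
import pytest

from qstrtox.synthetic_data import gen_table1_fixture, toy_carbamate_set


@pytest.fixture(scope="session")
def toys():
    """Hand-authored fixture molecules keyed by id."""
    return {t.id: t for t in toy_carbamate_set()}


@pytest.fixture(scope="session")
def table1():
    """(descriptor table, responses, set labels) of the worked-example rows."""
    return gen_table1_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(20220828)


def random_regression(rng, n, p, noise_sd=0.3):
    """A generic well-conditioned OLS instance for identity checks."""
    X = rng.standard_normal((n, p))
    beta = rng.uniform(-1.0, 1.0, size=p)
    y = 0.5 + X @ beta + rng.normal(0, noise_sd, size=n)
    return X, y
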