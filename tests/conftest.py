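import numpy as np
import pytest

from pirodyn import generate_pirouette_cohort, generate_reference_signal, prepare_trials


@pytest.fixture(scope="session")
def lorenz_xyz():
    """A 5000-sample Lorenz trajectory (dt = 0.01), shared across tests."""
    return generate_reference_signal("lorenz", 5000, {"dt": 0.01}, seed=0).values


@pytest.fixture(scope="session")
def lorenz_x(lorenz_xyz):
    return lorenz_xyz[:, 0]


@pytest.fixture(scope="session")
def small_cohort():
    """A 5-subject jazz/LKNE cohort, resampled and normalized."""
    trials = generate_pirouette_cohort(5, "jazz", "LKNE", (101, 250), 0.002, seed=7)
    return prepare_trials(trials)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
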