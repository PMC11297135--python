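import numpy as np
import pytest

from riacarb.world import SyntheticWorldSpec, generate_world


@pytest.fixture(scope="session")
def small_spec():
    """A scaled-down world: 3 stations, short training table, full weekly
    prediction coverage over a 6-year window."""
    return SyntheticWorldSpec(
        seed=7, n_stations=3, years=(2000, 2005),
        n_train_ph=400, n_train_ta=300,
    )


@pytest.fixture(scope="session")
def small_world(small_spec):
    return generate_world(small_spec, with_truth=True)


@pytest.fixture(scope="session")
def linear_regression_data():
    """Targets exactly linear in one feature, plus small iid noise."""
    rng = np.random.default_rng(123)
    X = rng.normal(size=(200, 3))
    y = 2.0 * X[:, 0] + 0.5 + rng.normal(0, 0.1, 200)
    return X, y
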