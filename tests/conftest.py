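import numpy as np
import pytest

from qpirbc import PhantomSpec, train_classifier
from qpirbc.classify import SplitPlan, split_dataset
from qpirbc.pipeline import build_population_tables


@pytest.fixture(scope="session")
def classic_spec():
    """The classic biconcave discocyte with closed-form volume 94.1 um^3."""
    return PhantomSpec(
        cell_class="healthy",
        radius=3.91,
        shape_coeffs=(0.81, 7.83, -4.39),
        delta_n=0.06,
        wavelength=0.532,
    )


@pytest.fixture(scope="session")
def population_table():
    """Default phantom population (400 per class) with imaging effects."""
    return build_population_tables(400, seed=11)


@pytest.fixture(scope="session")
def split_tables(population_table):
    plan = SplitPlan(ratios=(0.8, 0.2), seed=7)
    train, test = split_dataset(population_table, plan)
    return train, test


@pytest.fixture(scope="session")
def trained_model(split_tables):
    train, _ = split_tables
    return train_classifier(train, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
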