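import numpy as np
import pandas as pd
import pytest

from crmsur import SyntheticConfig, fieldprep, simulate_dataset
from crmsur.model import EquationParams
from crmsur.records import SYSTEM_COMPONENTS
from crmsur.sur import SystemData


@pytest.fixture
def reference_params():
    """(beta0, beta1) of the reference linear-dbh fit per component."""
    return {
        "stem": EquationParams("stem", 0.6790, -0.0188),
        "branch": EquationParams("branch", 0.1437, 0.0222),
        "twig": EquationParams("twig", 0.1441, -0.0045),
    }


@pytest.fixture(scope="session")
def default_config():
    return SyntheticConfig(seed=1)


@pytest.fixture(scope="session")
def study_tables(default_config):
    """Census, destructive sample and biomass tables at study conditions."""
    return simulate_dataset(default_config)


@pytest.fixture(scope="session")
def ratios_12(study_tables):
    """Per-tree ratio table of the 12-tree destructive sample."""
    _, _, biomass = study_tables
    return fieldprep.prepare_ratios(biomass)


def make_system(n=50, seed=0, config=None, dbh_range=(3.0, 20.0)):
    """Linear-truth system data on a uniform dbh grid, for estimator tests."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(seed)
    dbh = rng.uniform(*dbh_range, size=n)
    cov = config.error_cov()
    eps = rng.multivariate_normal(np.zeros(3), cov, size=n)
    y = np.column_stack(
        [
            config.true_beta[c][0] + config.true_beta[c][1] * dbh + eps[:, j]
            for j, c in enumerate(SYSTEM_COMPONENTS)
        ]
    )
    y = np.clip(y, 1e-6, 1.0)
    return SystemData(x=dbh, y=y)


@pytest.fixture
def linear_system():
    return make_system(n=50, seed=0)
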