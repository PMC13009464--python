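import numpy as np
import pandas as pd
import pytest

from lfmckit import synthetic


@pytest.fixture(scope="session")
def grid():
    return synthetic.generate_domain(8, 8, seed=7)


@pytest.fixture(scope="session")
def forcing(grid):
    """Two years of daily forcing on the session grid."""
    return synthetic.generate_forcing(grid, "2001-01-01", "2002-12-31", seed=11)


@pytest.fixture(scope="session")
def predictor_cube(forcing):
    from lfmckit.features import predictor_fields

    return predictor_fields(forcing)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def obs_table():
    """A small observation table with duplicates and mixed labels."""
    return pd.DataFrame(
        {
            "site_id": ["a", "a", "a", "b", "b", "c"],
            "date": pd.to_datetime(
                ["2001-01-01", "2001-01-01", "2001-02-01", "2001-01-01", "2001-03-15", "2001-01-01"]
            ),
            "fuel_type": [
                "chamise new growth", "chamise new growth", "chamise",
                "chamise old growth", "black sage", "chamise",
            ],
            "lfmc_percent": [80.0, 90.0, 100.0, 70.0, 120.0, 95.0],
        }
    )
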