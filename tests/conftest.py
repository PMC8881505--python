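import numpy as np
import pytest

from forestsdm.synthetic import (
    ClimateFieldParams,
    LandscapeConfig,
    generate_landscape,
)
from forestsdm.forest_variables import plot_variables_table


@pytest.fixture(scope="session")
def small_landscape():
    """A 12-km fully-forested landscape shared by read-only tests."""
    cfg = LandscapeConfig(
        extent_km=12.0,
        forest_fraction=1.0,
        mature_fraction=0.4,
        climate_field_params={
            "elevation": ClimateFieldParams(800.0, 300.0, 4.0),
            "annual_precip": ClimateFieldParams(600.0, 150.0, 5.0),
            "tmax_warmest": ClimateFieldParams(32.0, 2.5, 3.5),
            "temp_seasonality": ClimateFieldParams(550.0, 80.0, 5.5),
        },
        seed=7,
    )
    return generate_landscape(cfg)


@pytest.fixture(scope="session")
def small_plot_vars(small_landscape):
    return plot_variables_table(small_landscape).dropna().reset_index(drop=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
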