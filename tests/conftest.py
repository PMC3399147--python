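import warnings

import numpy as np
import pytest
import xarray as xr

from dvmuq import (
    GridSpec,
    default_parameter_table,
    generate_scenario,
    get_scenario,
)
from dvmuq.climate_synth import generate_spinup


@pytest.fixture(scope="session")
def param_specs():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # k_mort1 repair notice
        return default_parameter_table()


@pytest.fixture(scope="session")
def small_grid():
    """3 latitude bands x 4 longitudes over 45-90N."""
    return GridSpec.regular(15.0, lon_bounds=(-180.0, -120.0))


@pytest.fixture(scope="session")
def a1fi_cube(small_grid):
    spec = get_scenario("A1FI").with_noise_scale(0.0)
    return generate_scenario(spec, small_grid, range(2001, 2101), seed=7)


@pytest.fixture(scope="session")
def forcing_cube(small_grid):
    """Spin-up (60 yr) + 1971-2100 transient under zero-noise A1FI."""
    spec = get_scenario("A1FI").with_noise_scale(0.0)
    cube = generate_scenario(spec, small_grid, range(1971, 2101), seed=7)
    return xr.concat([generate_spinup(cube, 60), cube], dim="year")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)
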