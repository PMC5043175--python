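import numpy as np
import pytest
import xarray as xr

from medseas.config import ScenarioConfig


def tiny_config(**overrides) -> ScenarioConfig:
    """Small, fast scenario; Adriatic box widened so it stays non-empty on
    coarse grids."""
    defaults = dict(
        seed=7,
        noise_sd=0.0,
        spatial_amp=0.0,
        nlat=6,
        nlon=12,
        n_land_rows=2,
        adriatic_lat=(38.0, 46.0),
        n_lau=4,
        hauls_per_basin=10,
        eastern_sparse=False,
    )
    defaults.update(overrides)
    return ScenarioConfig(**defaults)


@pytest.fixture
def flat_config():
    """Zero-noise, zero-trend, spatially flat scenario."""
    zero = {k: 0.0 for k in ScenarioConfig().trend_spec}
    return tiny_config(trend_spec=zero)


def grid_field(values, times=None) -> xr.DataArray:
    """(time, lat, lon) DataArray with fractional-year time coordinate."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 2:
        arr = arr[None, ...]
    if times is None:
        times = np.arange(arr.shape[0], dtype=float)
    return xr.DataArray(
        arr,
        dims=("time", "lat", "lon"),
        coords={
            "time": np.asarray(times, dtype=float),
            "lat": np.arange(arr.shape[1], dtype=float),
            "lon": np.arange(arr.shape[2], dtype=float),
        },
    )
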