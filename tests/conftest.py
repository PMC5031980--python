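import numpy as np
import pandas as pd
import pytest
import xarray as xr

from bluefinhab import synthetic
from bluefinhab.fields import EnvFieldStack
from bluefinhab.tracks import Track


@pytest.fixture(scope="session")
def small_env() -> EnvFieldStack:
    """A small but fully featured synthetic covariate stack."""
    dates = pd.date_range("2010-04-01", "2010-07-01", freq="7D")
    return synthetic.gen_env_fields(dates=dates, seed=11)


@pytest.fixture(scope="session")
def uniform_env() -> EnvFieldStack:
    """Spatially constant fields (all structure and noise amplitudes zero)."""
    params = synthetic.EnvFieldParams(
        sst_mean=24.0, sst_lat_gradient=0.0, loop_sst_amp=0.0, loop_eke_amp=0.0,
        sst_noise=0.0, sst_sd_noise=0.0, chl_log_noise=0.0, chl_shelf_boost=0.0,
        ssha_noise=0.0, ssha_sd_noise=0.0, eke_log_noise=0.0,
        wekman_noise=0.0, uy10_noise=0.0,
    )
    dates = pd.date_range("2010-04-01", periods=3, freq="7D")
    return synthetic.gen_env_fields(dates=dates, params=params, seed=0)


def make_env_from_layers(lons, lats, dates, **layers) -> EnvFieldStack:
    """Build a stack from explicit per-variable constants or arrays."""
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    dates = pd.DatetimeIndex(pd.to_datetime(dates))
    T, ny, nx = len(dates), len(lats), len(lons)
    defaults = dict(
        sst=24.0, sst_sd=0.5, chl=1.0, ssha=0.0, ssha_sd=4.0, eke=0.01,
        wekman=0.0, uy10=-2.0, bathy=-1000.0, bathy_sd=5.0,
    )
    defaults.update(layers)
    data = {}
    for var, val in defaults.items():
        if var in ("bathy", "bathy_sd"):
            arr = np.broadcast_to(np.asarray(val, dtype=float), (ny, nx)).copy()
            data[var] = (("lat", "lon"), arr)
        else:
            arr = np.broadcast_to(np.asarray(val, dtype=float), (T, ny, nx)).copy()
            data[var] = (("time", "lat", "lon"), arr)
    ds = xr.Dataset(data, coords={"time": dates, "lat": lats, "lon": lons})
    return EnvFieldStack(ds)


def make_track(lons, lats, tag_id="t1", start="2010-04-01", radii=0.0) -> Track:
    lons = np.asarray(lons, dtype=float)
    n = len(lons)
    return Track(
        tag_id,
        pd.DataFrame(
            {
                "date": pd.date_range(start, periods=n, freq="D"),
                "lon": lons,
                "lat": np.asarray(lats, dtype=float),
                "error_radius_deg": np.broadcast_to(radii, n).astype(float),
            }
        ),
    )
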