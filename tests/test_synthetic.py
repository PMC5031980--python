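import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bluefinhab import synthetic
from bluefinhab.crw import fit_step_distribution
from bluefinhab.spawning import count_night_oscillations
from bluefinhab.astro import sun_altitude


DATES = pd.date_range("2010-04-01", "2010-06-01", freq="7D")


# ---------------------------------------------------------------------------
# Environmental fields
# ---------------------------------------------------------------------------

def test_env_fields_deterministic_given_seed():
    a = synthetic.gen_env_fields(dates=DATES, seed=42)
    b = synthetic.gen_env_fields(dates=DATES, seed=42)
    assert a.data.identical(b.data)
    c = synthetic.gen_env_fields(dates=DATES, seed=43)
    assert not np.allclose(a.data["sst"].values, c.data["sst"].values)


def test_env_degenerate_params_give_constant_sst():
    params = synthetic.EnvFieldParams(
        sst_mean=24.0, sst_lat_gradient=0.0, loop_sst_amp=0.0, sst_noise=0.0
    )
    env = synthetic.gen_env_fields(dates=DATES[:1], params=params, seed=0)
    np.testing.assert_allclose(env.data["sst"].values, 24.0)


def test_env_log_transformed_covariates_strictly_positive():
    env = synthetic.gen_env_fields(dates=DATES, seed=3)
    assert (env.data["chl"].values > 0).all()
    assert (env.data["eke"].values > 0).all()


def test_env_bathymetry_negative_over_water_positive_on_land():
    env = synthetic.gen_env_fields(dates=DATES[:1], seed=3)
    bathy = env.data["bathy"].values
    assert (bathy[env.water_mask] < 0).all()
    assert (~env.water_mask).any()  # a coastal rim exists


def test_env_spatial_autocorrelation_decays_with_lag():
    params = synthetic.EnvFieldParams(corr_len_deg=2.0)
    env = synthetic.gen_env_fields(dates=DATES[:1], params=params, seed=9)
    layer = env.data["sst"].values[0]
    resid = layer - layer.mean(axis=1, keepdims=True)  # remove lat gradient

    def lag_corr(lag):
        a = resid[:, :-lag].ravel()
        b = resid[:, lag:].ravel()
        return np.corrcoef(a, b)[0, 1]

    assert lag_corr(1) > lag_corr(10)
    assert lag_corr(1) > 0.8


def test_env_empty_dates_and_bad_corr_length_raise():
    with pytest.raises(ValueError):
        synthetic.gen_env_fields(dates=[], seed=0)
    with pytest.raises(ValueError):
        synthetic.gen_env_fields(
            dates=DATES, params=synthetic.EnvFieldParams(corr_len_deg=0.0), seed=0
        )


def test_env_netcdf_round_trip(tmp_path, small_env):
    p = tmp_path / "env.nc"
    small_env.to_netcdf(p)
    from bluefinhab.fields import EnvFieldStack

    back = EnvFieldStack.from_netcdf(p)
    np.testing.assert_allclose(
        back.data["sst"].values, small_env.data["sst"].values, rtol=1e-6
    )
    assert len(back.dates) == len(small_env.dates)


# ---------------------------------------------------------------------------
# Tracks
# ---------------------------------------------------------------------------

def test_gen_tracks_zero_fish_gives_empty_list(small_env):
    assert synthetic.gen_tracks(0, small_env, seed=0) == []


def test_gen_tracks_entry_date_outside_env_range_raises(small_env):
    with pytest.raises(ValueError, match="entry date"):
        synthetic.gen_tracks(1, small_env, entry_dates=["1999-01-01"], seed=0)


def test_gen_tracks_deterministic_and_over_water(small_env):
    pref = synthetic.default_preference()
    a = synthetic.gen_tracks(
        2, small_env, pref, ["2010-04-01"] * 2, seed=5,
        params=synthetic.TrackGenParams(n_days=40),
    )
    b = synthetic.gen_tracks(
        2, small_env, pref, ["2010-04-01"] * 2, seed=5,
        params=synthetic.TrackGenParams(n_days=40),
    )
    for ta, tb in zip(a, b):
        np.testing.assert_array_equal(ta.lons, tb.lons)
    for t in a:
        for lon, lat in zip(t.lons, t.lats):
            assert small_env.is_water(lon, lat)


def test_gen_tracks_null_preference_step_lengths_match_generating_gamma():
    env = synthetic.gen_env_fields(dates=DATES, seed=1)
    params = synthetic.TrackGenParams(n_days=151)
    t = synthetic.gen_tracks(
        1, env, synthetic.PreferenceSpec(strength=0.0),
        ["2010-04-01"], seed=2, params=params,
    )[0]
    steps = fit_step_distribution(t).step_lengths_km
    p = stats.kstest(
        steps, stats.gamma(a=params.step_shape, scale=params.step_scale_km).cdf
    ).pvalue
    assert p > 0.01


def test_gen_tracks_thermal_preference_pulls_usage_toward_optimum():
    # Monte-Carlo: mean SST at used positions is closer to the 24 degC
    # optimum than the watery domain mean, across 20 seeds
    wins = 0
    for seed in range(20):
        env = synthetic.gen_env_fields(dates=DATES, seed=seed)
        t = synthetic.gen_tracks(
            1, env, synthetic.default_preference(), ["2010-04-01"], seed=seed,
            params=synthetic.TrackGenParams(n_days=40),
        )[0]
        used = np.array(
            [env.value_at("sst", lon, lat, d)
             for lon, lat, d in zip(t.lons, t.lats, t.dates)]
        )
        domain = env.layer("sst", "2010-05-01")[env.water_mask]
        if abs(used.mean() - 24.0) < abs(domain.mean() - 24.0):
            wins += 1
    assert wins >= 16


# ---------------------------------------------------------------------------
# Dive series
# ---------------------------------------------------------------------------

def _dive_setup(seed=1, with_window=True):
    env = synthetic.gen_env_fields(dates=DATES, seed=seed)
    track = synthetic.gen_tracks(
        1, env, synthetic.default_preference(), ["2010-04-01"], seed=seed,
        params=synthetic.TrackGenParams(n_days=20),
    )[0]
    windows = {track.tag_id: [(track.dates[8], track.dates[12])]} if with_window else {}
    return track, synthetic.SpawnScenario(windows=windows)


def test_dive_series_deterministic_given_seed():
    track, scenario = _dive_setup()
    a = synthetic.gen_dive_series(track, scenario, seed=4)
    b = synthetic.gen_dive_series(track, scenario, seed=4)
    pd.testing.assert_frame_equal(a.df, b.df)


def test_dive_series_deep_transit_dives_on_entry_and_exit_days():
    track, scenario = _dive_setup()
    d = synthetic.gen_dive_series(track, scenario, seed=4).df
    days = d["timestamp_utc"].dt.normalize()
    assert d.loc[days == track.dates[0], "depth_m"].max() > 500
    assert d.loc[days == track.dates[-1], "depth_m"].max() > 500
    assert d.loc[days == track.dates[5], "depth_m"].max() < 500


def test_dive_series_window_night_oscillation_count_matches_period():
    track, scenario = _dive_setup()
    d = synthetic.gen_dive_series(track, scenario, seed=4).df
    day = track.dates[10]
    sub = d[d["timestamp_utc"].dt.normalize() == day]
    lon, lat = track.lons[10], track.lats[10]
    night = sun_altitude(lon, lat, sub["timestamp_utc"]) < 0
    depth = sub["depth_m"].to_numpy()[night]
    count, period = count_night_oscillations(depth, scenario.sampling_interval_s)
    night_minutes = night.sum() * scenario.sampling_interval_s / 60.0
    assert count >= night_minutes / scenario.oscillation_period_min - 1
    assert period == pytest.approx(scenario.oscillation_period_min, rel=0.15)


def test_dive_series_no_window_nights_are_flat():
    track, scenario = _dive_setup(with_window=False)
    d = synthetic.gen_dive_series(track, scenario, seed=4).df
    for i in range(2, 8):
        day = track.dates[i]
        sub = d[d["timestamp_utc"].dt.normalize() == day]
        night = sun_altitude(track.lons[i], track.lats[i], sub["timestamp_utc"]) < 0
        depth = sub["depth_m"].to_numpy()[night]
        count, _ = count_night_oscillations(depth, scenario.sampling_interval_s)
        assert count == 0


def test_dive_series_window_outside_track_raises():
    track, _ = _dive_setup(with_window=False)
    bad = synthetic.SpawnScenario(
        windows={track.tag_id: [(pd.Timestamp("2009-01-01"), pd.Timestamp("2009-01-05"))]}
    )
    with pytest.raises(ValueError, match="outside track span"):
        synthetic.gen_dive_series(track, bad, seed=0)


# ---------------------------------------------------------------------------
# Oil polygons
# ---------------------------------------------------------------------------

def _planar_area_km2(poly, well=synthetic.DEFAULT_WELL):
    xs, ys = np.asarray(poly.exterior.coords.xy)
    kx = 110.57 * np.cos(np.radians(well[1]))
    x = (xs - well[0]) * kx
    y = (ys - well[1]) * 110.57
    return 0.5 * abs(np.dot(x[:-1], y[1:]) - np.dot(y[:-1], x[1:]))


def test_oil_polygon_empty_before_spill_start_and_when_growth_zero():
    dates = ["2010-03-01", "2010-05-15", "2010-09-01"]
    polys = synthetic.gen_oil_extent(dates, seed=1)
    assert polys[0][1].is_empty
    assert not polys[1][1].is_empty
    assert polys[2][1].is_empty
    all_zero = synthetic.gen_oil_extent(dates, growth=lambda d: 0.0, seed=1)
    assert all(p.is_empty for _, p in all_zero)


def test_oil_polygon_area_tracks_constant_growth_curve():
    # shoelace area on locally projected coordinates, independent oracle
    dates = pd.date_range("2010-05-01", periods=5, freq="7D")
    target = 12000.0
    polys = synthetic.gen_oil_extent(dates, growth=lambda d: target, seed=2)
    for _, poly in polys:
        assert _planar_area_km2(poly) == pytest.approx(target, rel=0.10)


def test_oil_polygon_well_outside_domain_raises():
    with pytest.raises(ValueError, match="well outside domain"):
        synthetic.gen_oil_extent(["2010-05-01"], well=(0.0, 0.0), seed=0)


def test_oil_geojson_round_trip(tmp_path):
    dates = pd.date_range("2010-04-15", periods=4, freq="7D")
    polys = synthetic.gen_oil_extent(dates, seed=3)
    p = tmp_path / "oil.geojson"
    synthetic.write_polygons_geojson(polys, p)
    back = synthetic.read_polygons_geojson(p)
    assert len(back) == len(polys)
    for (d0, g0), (d1, g1) in zip(polys, back):
        assert d0 == d1
        assert g0.is_empty == g1.is_empty
        if not g0.is_empty:
            assert g1.area == pytest.approx(g0.area, rel=1e-6)
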