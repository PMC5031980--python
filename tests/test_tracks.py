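import math

import numpy as np
import pandas as pd
import pytest

from bluefinhab.tracks import (
    OutOfDomainError,
    Track,
    TrackFormatError,
    TrackValidationError,
    detect_gom_occupancy,
    extract_covariates,
    read_tracks,
    write_tracks,
)

from conftest import make_env_from_layers, make_track


# ---------------------------------------------------------------------------
# CSV IO and validation
# ---------------------------------------------------------------------------

def test_read_tracks_empty_file_with_header(tmp_path):
    p = tmp_path / "t.csv"
    p.write_text("tag_id,date,lon,lat,error_radius_deg\n")
    assert read_tracks(p) == []


def test_read_tracks_groups_and_sorts_by_tag(tmp_path):
    p = tmp_path / "t.csv"
    p.write_text(
        "tag_id,date,lon,lat,error_radius_deg\n"
        "a,2010-04-02,-88,25,0.5\n"
        "b,2010-04-01,-87,26,0.5\n"
        "a,2010-04-01,-88.5,25.1,0.5\n"
    )
    tracks = read_tracks(p)
    assert [t.tag_id for t in tracks] == ["a", "b"]
    assert [len(t) for t in tracks] == [2, 1]
    assert tracks[0].dates.is_monotonic_increasing


def test_read_tracks_missing_column_is_format_error(tmp_path):
    p = tmp_path / "t.csv"
    p.write_text("tag_id,date,lon,lat\na,2010-04-01,-88,25\n")
    with pytest.raises(TrackFormatError, match="error_radius_deg"):
        read_tracks(p)


def test_read_tracks_out_of_bounds_latitude_names_the_row(tmp_path):
    p = tmp_path / "t.csv"
    p.write_text(
        "tag_id,date,lon,lat,error_radius_deg\na,2010-04-01,-88,95,0.5\n"
    )
    with pytest.raises(TrackValidationError, match="out of bounds"):
        read_tracks(p)


def test_duplicate_tag_date_is_validation_error():
    df = pd.DataFrame(
        {
            "date": ["2010-04-01", "2010-04-01"],
            "lon": [-88.0, -88.1],
            "lat": [25.0, 25.1],
            "error_radius_deg": [0.5, 0.5],
        }
    )
    with pytest.raises(TrackValidationError, match="duplicate"):
        Track("a", df)


def test_track_csv_round_trip(tmp_path):
    t = make_track([-88, -87.5, -87], [25, 25.2, 25.4], radii=0.4)
    p = tmp_path / "out.csv"
    write_tracks([t], p)
    back = read_tracks(p)[0]
    np.testing.assert_allclose(back.lons, t.lons)
    np.testing.assert_allclose(back.error_radii, t.error_radii)
    assert (back.dates == t.dates).all()


# ---------------------------------------------------------------------------
# Gulf occupancy rule
# ---------------------------------------------------------------------------

def _track_from_lons(lons):
    return make_track(lons, [25.0] * len(lons))


def test_occupancy_interval_opens_and_closes_on_run_west_of_meridian():
    # days 0-9 east, days 10-16 west, then east again
    lons = [-79.0] * 10 + [-85.0] * 7 + [-79.0] * 3
    t = _track_from_lons(lons)
    intervals = detect_gom_occupancy(t)
    assert len(intervals) == 1
    entry, exit_ = intervals[0]
    assert entry == t.dates[10]
    assert exit_ == t.dates[16]


def test_occupancy_never_west_yields_empty():
    t = _track_from_lons([-79.5] * 12)
    assert detect_gom_occupancy(t) == []


def test_occupancy_three_day_run_fails_six_day_rule():
    # manual application of the 6-day rule to a constructed 8-day track
    lons = [-79.0, -79.0, -79.0, -85.0, -85.0, -85.0, -79.0, -79.0]
    t = _track_from_lons(lons)
    assert detect_gom_occupancy(t) == []
    assert detect_gom_occupancy(t, min_days=3) == [(t.dates[3], t.dates[5])]


def test_occupancy_intervals_disjoint_and_long_enough():
    rng = np.random.default_rng(5)
    lons = np.where(rng.uniform(size=80) < 0.5, -85.0, -79.0)
    t = _track_from_lons(lons)
    intervals = detect_gom_occupancy(t, min_days=4)
    prev_exit = None
    for entry, exit_ in intervals:
        assert (exit_ - entry).days >= 3  # >= min_days consecutive days
        if prev_exit is not None:
            assert entry > prev_exit
        prev_exit = exit_


# ---------------------------------------------------------------------------
# Covariate extraction
# ---------------------------------------------------------------------------

def _grid_env(**layers):
    lons = np.arange(-90.0 + 0.125, -86.0, 0.25)
    lats = np.arange(24.0 + 0.125, 27.0, 0.25)
    return make_env_from_layers(lons, lats, ["2010-04-01"], **layers)


def test_zero_radius_returns_containing_cell_value():
    env = _grid_env()
    sst = env.data["sst"].values
    sst[0, 3, 4] = 26.5
    out = extract_covariates(env.lons[4], env.lats[3], "2010-04-01", 0.0, env)
    assert out["sst"] == pytest.approx(26.5)


def test_uniform_field_mean_is_constant_for_any_radius():
    env = _grid_env(sst=22.5)
    for r in (0.0, 0.3, 1.0):
        out = extract_covariates(-88.0, 25.5, "2010-04-01", r, env)
        assert out["sst"] == pytest.approx(22.5)


def test_two_cell_average_log_transforms_after_averaging():
    env = _grid_env()
    chl = env.data["chl"].values
    chl[:] = np.nan
    i, j = env.cell_index(-88.0, 25.5)
    chl[0, i, j] = 1.0
    chl[0, i, j + 1] = 3.0
    # position between the two centers; radius covers exactly those two
    lon_mid = (env.lons[j] + env.lons[j + 1]) / 2
    lat = env.lats[i]
    # brute-force enumeration of centers within the radius
    radius = 0.2
    lon_g, lat_g = np.meshgrid(env.lons, env.lats)
    inside = (lon_g - lon_mid) ** 2 + (lat_g - lat) ** 2 <= radius**2
    assert inside.sum() == 2
    out = extract_covariates(lon_mid, lat, "2010-04-01", radius, env)
    assert out["log_chl"] == pytest.approx(math.log(2.0))


def test_extraction_mean_is_bounded_by_cell_extremes():
    rng = np.random.default_rng(3)
    env = _grid_env()
    env.data["sst"].values[:] = rng.uniform(20, 30, env.data["sst"].shape)
    for r in (0.2, 0.5, 1.2):
        out = extract_covariates(-88.0, 25.5, "2010-04-01", r, env)
        lon_g, lat_g = np.meshgrid(env.lons, env.lats)
        sel = (lon_g + 88.0) ** 2 + (lat_g - 25.5) ** 2 <= r**2
        vals = env.data["sst"].values[0][sel]
        assert vals.min() <= out["sst"] <= vals.max()


def test_position_outside_grid_raises():
    env = _grid_env()
    with pytest.raises(OutOfDomainError):
        extract_covariates(-120.0, 25.0, "2010-04-01", 0.5, env)


def test_moon_covariate_depends_only_on_date():
    env = _grid_env()
    a = extract_covariates(-88.0, 25.0, "2010-04-01", 0.3, env)
    b = extract_covariates(-87.0, 26.0, "2010-04-01", 0.0, env)
    assert a["moon"] == b["moon"]
    assert 0.0 <= a["moon"] <= 1.0
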