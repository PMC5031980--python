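"""Synthetic study-condition generators.

The real inputs (66 tagged bluefin tuna, remotely sensed covariate rasters,
NRDA surface-oil polygons) are not publicly deposited, so every downstream
stage is exercised on synthetic data generated here with the statistical
structure the analysis assumes:

* smooth, spatially correlated covariate fields over a Gulf-of-Mexico-like
  basin, with a warm high-EKE Loop-Current-like tongue and shelf/slope
  bathymetry;
* daily tracks whose movement is a step-selection walk biased by a known
  habitat preference (the ground truth for parameter-recovery tests);
* dive/internal-temperature series with injected nocturnal oscillatory
  diving during known spawning windows;
* a growing/shrinking irregular oil polygon around a fixed well location.

Every generator is a pure function of its parameters and a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import Polygon, mapping, shape

from ._seeding import substream
from .astro import sun_altitude
from .fields import EnvFieldStack
from .geo import dead_reckon, wrap_angle
from .tracks import DiveSeries, Track

import xarray as xr

#: Default Gulf-of-Mexico-like domain: (lon_w, lon_e, lat_s, lat_n).
GOM_BOUNDS = (-98.0, -80.0, 18.0, 31.0)
#: Synthetic well location for the default oil scenario, placed on the
#: northern edge of the modeled thermal habitat band so the spill borders
#: spawning habitat (as the real well bordered the northern slope grounds).
DEFAULT_WELL = (-88.37, 26.2)
#: Default surface-oil activity window (the 2010 spill timeline).
OIL_START = pd.Timestamp("2010-04-21")
OIL_END = pd.Timestamp("2010-07-28")


# ---------------------------------------------------------------------------
# Environmental fields
# ---------------------------------------------------------------------------

@dataclass
class EnvFieldParams:
    """Means, noise scales and correlation lengths of the generated fields.

    Noise scales are standard deviations of the spatially correlated residual
    added to each field's deterministic mean structure.  Setting a noise
    scale, the latitudinal gradient and the loop amplitude to zero makes the
    corresponding field spatially constant.
    """

    resolution: float = 0.25
    corr_len_deg: float = 1.5
    corr_len_steps: float = 1.0  # temporal smoothing, in layers
    sst_mean: float = 24.5
    sst_lat_gradient: float = -0.6  # degC per degree latitude (cooler north)
    loop_sst_amp: float = 2.0  # warm tongue amplitude, degC
    loop_eke_amp: float = 2.0  # tongue boost on log-EKE
    sst_noise: float = 0.8
    sst_sd_base: float = 0.4
    sst_sd_noise: float = 0.25
    chl_log_mean: float = np.log(0.15)  # mg m^-3 offshore
    chl_shelf_boost: float = 1.8  # log-units where bathy > -200 m
    chl_log_noise: float = 0.5
    ssha_noise: float = 6.0  # cm
    ssha_sd_base: float = 4.0
    ssha_sd_noise: float = 1.5
    eke_log_mean: float = np.log(0.01)  # m^2 s^-2 background
    eke_log_noise: float = 0.7
    wekman_noise: float = 2.0e-6  # m s^-1
    uy10_mean: float = -2.0  # m s^-1 (prevailing northerly component)
    uy10_noise: float = 2.0
    depth_max: float = 3800.0  # m, central basin
    shelf_depth: float = 30.0  # m at the coastal rim


def _basin_shape(lon_g: np.ndarray, lat_g: np.ndarray, bounds) -> np.ndarray:
    """Smooth 0..1 basin function: 0 at the west/north/south rim, ~1 mid-basin.

    The eastern boundary stays open (positive) between ~20 and ~29 deg N so
    tracks can enter at the 80.5 deg W meridian.
    """
    w, e, s, n = bounds
    u = np.clip((lon_g - w) / (e - w + 2.0), 0.0, 1.0)
    v = np.clip((lat_g - s) / (n - s), 0.0, 1.0)
    return np.sin(np.pi * u) * np.sin(np.pi * v)


_LOOP_PATH = np.array(
    [(-86.8, 19.0), (-86.5, 22.0), (-85.5, 25.5), (-83.5, 25.0), (-81.5, 23.8)]
)


def _loop_ridge(lon_g: np.ndarray, lat_g: np.ndarray, width: float = 1.3) -> np.ndarray:
    """Gaussian ridge along a Loop-Current-like polyline, 0..1."""
    d2 = np.full(lon_g.shape, np.inf)
    for (x1, y1), (x2, y2) in zip(_LOOP_PATH[:-1], _LOOP_PATH[1:]):
        vx, vy = x2 - x1, y2 - y1
        t = np.clip(
            ((lon_g - x1) * vx + (lat_g - y1) * vy) / (vx * vx + vy * vy), 0.0, 1.0
        )
        d2 = np.minimum(d2, (lon_g - (x1 + t * vx)) ** 2 + (lat_g - (y1 + t * vy)) ** 2)
    return np.exp(-d2 / (2.0 * width**2))


def _correlated_noise(
    rng: np.random.Generator, shape, corr_cells: float, corr_steps: float
) -> np.ndarray:
    """Unit-variance Gaussian random field, smooth in space (and time if 3-D)."""
    z = rng.standard_normal(shape)
    sigma = (corr_steps, corr_cells, corr_cells) if len(shape) == 3 else (corr_cells,) * 2
    z = ndimage.gaussian_filter(z, sigma=sigma, mode="reflect")
    sd = z.std()
    return z / sd if sd > 0 else z


def gen_env_fields(
    bounds=GOM_BOUNDS,
    dates=None,
    params: EnvFieldParams | None = None,
    seed: int = 0,
) -> EnvFieldStack:
    """Generate a synthetic covariate stack over a GOM-like basin.

    Deterministic given ``seed``.  Raises on an empty date list or a
    non-positive correlation length.
    """
    params = params or EnvFieldParams()
    if dates is None or len(dates) == 0:
        raise ValueError("need at least one date")
    if params.corr_len_deg <= 0:
        raise ValueError("correlation length must be positive")
    dates = pd.DatetimeIndex(pd.to_datetime(list(dates)))
    w, e, s, n = bounds
    res = params.resolution
    lons = np.arange(w + res / 2, e, res)
    lats = np.arange(s + res / 2, n, res)
    lon_g, lat_g = np.meshgrid(lons, lats)
    T, ny, nx = len(dates), len(lats), len(lons)
    corr_cells = params.corr_len_deg / res

    basin = _basin_shape(lon_g, lat_g, bounds)
    ridge = _loop_ridge(lon_g, lat_g)
    water = basin > 0.18
    depth_frac = np.clip((basin - 0.18) / 0.82, 0.0, 1.0) ** 1.5
    bathy = np.where(
        water, -(params.shelf_depth + (params.depth_max - params.shelf_depth) * depth_frac), 50.0
    )
    gy, gx = np.gradient(bathy)
    rug_rng = substream(seed, "env", "bathy_sd")
    bathy_sd = np.hypot(gy, gx) * 0.5 + 2.0 + np.abs(
        _correlated_noise(rug_rng, (ny, nx), corr_cells, 0)
    )

    def noise(name: str, sd: float) -> np.ndarray:
        if sd == 0:
            return np.zeros((T, ny, nx))
        rng = substream(seed, "env", name)
        return sd * _correlated_noise(
            rng, (T, ny, nx), corr_cells, params.corr_len_steps
        )

    sst = (
        params.sst_mean
        + params.sst_lat_gradient * (lat_g - 24.5)
        + params.loop_sst_amp * ridge
    )[None] + noise("sst", params.sst_noise)
    sst_sd = np.maximum(
        params.sst_sd_base + noise("sst_sd", params.sst_sd_noise), 0.01
    )
    shelf = (bathy > -200.0) & water
    chl = np.exp(
        params.chl_log_mean
        + params.chl_shelf_boost * shelf[None]
        + noise("chl", params.chl_log_noise)
    )
    ssha = 4.0 * ridge[None] + noise("ssha", params.ssha_noise)
    ssha_sd = np.maximum(
        params.ssha_sd_base + 2.0 * ridge[None] + noise("ssha_sd", params.ssha_sd_noise),
        0.01,
    )
    eke = np.exp(
        params.eke_log_mean
        + params.loop_eke_amp * ridge[None]
        + noise("eke", params.eke_log_noise)
    )
    wekman = noise("wekman", params.wekman_noise)
    uy10 = params.uy10_mean + noise("uy10", params.uy10_noise)

    ds = xr.Dataset(
        {
            "sst": (("time", "lat", "lon"), sst),
            "sst_sd": (("time", "lat", "lon"), sst_sd),
            "chl": (("time", "lat", "lon"), chl),
            "ssha": (("time", "lat", "lon"), ssha),
            "ssha_sd": (("time", "lat", "lon"), ssha_sd),
            "eke": (("time", "lat", "lon"), eke),
            "wekman": (("time", "lat", "lon"), wekman),
            "uy10": (("time", "lat", "lon"), uy10),
            "bathy": (("lat", "lon"), bathy),
            "bathy_sd": (("lat", "lon"), bathy_sd),
        },
        coords={"time": dates, "lat": lats, "lon": lons},
    )
    return EnvFieldStack(ds)


# ---------------------------------------------------------------------------
# Tracks
# ---------------------------------------------------------------------------

@dataclass
class PreferenceSpec:
    """Ground-truth habitat preference for track generation.

    ``responses`` maps a raw covariate name (e.g. ``"sst"``) to a Gaussian
    selection response ``(optimum, width)``: the per-covariate preference
    score is the log of a Gaussian kernel, ``-(x - opt)^2 / (2 width^2)``,
    so the selection weight of a candidate step is Gaussian-shaped in each
    covariate, ``exp(strength * sum of scores)``.  ``strength = 0`` makes
    movement independent of the environment; the true log selection weight
    (the quantity a presence/pseudo-absence logit model estimates, up to a
    constant) is ``strength * score``.
    """

    responses: dict[str, tuple[float, float]] = field(default_factory=dict)
    strength: float = 0.0

    def score(self, values: dict[str, float]) -> float:
        total = 0.0
        for var, (opt, width) in self.responses.items():
            x = values.get(var)
            if x is not None and np.isfinite(x):
                total += float(-((x - opt) ** 2) / (2.0 * width**2))
        return total

    def log_preference(self, var: str, x) -> np.ndarray:
        """True log selection weight as a function of one covariate."""
        opt, width = self.responses[var]
        return self.strength * -((np.asarray(x, float) - opt) ** 2) / (2 * width**2)


@dataclass
class TrackGenParams:
    """Movement parameters of the synthetic step-selection walk."""

    n_days: int = 150
    step_shape: float = 2.0  # gamma shape of daily step length
    step_scale_km: float = 30.0  # gamma scale (mean = shape*scale = 60 km/day)
    turn_kappa: float = 1.5  # von Mises concentration of turning angles
    n_candidates: int = 24
    error_radius_median_deg: float = 0.25
    error_radius_sigma: float = 0.35  # lognormal sigma
    entry_lon: float = -81.0
    entry_lat_range: tuple[float, float] = (25.0, 27.5)


def default_preference() -> "PreferenceSpec":
    """The canonical strong thermal preference used as ground truth.

    A Gaussian selection response in SST centred on the 24 degC spawning-
    ground optimum with 1.5 degC width, at a selection strength that
    concentrates use strongly around the optimum while fish still sample
    the surrounding water.
    """
    return PreferenceSpec(responses={"sst": (24.0, 1.5)}, strength=4.5)


def gen_tracks(
    n_fish: int,
    env: EnvFieldStack,
    pref: PreferenceSpec | None = None,
    entry_dates=None,
    seed: int = 0,
    params: TrackGenParams | None = None,
) -> list[Track]:
    """Generate step-selection tracks biased by a known habitat preference.

    Each day one gamma step length is drawn; ``n_candidates`` headings are
    proposed (previous heading + von Mises turns) and one is sampled with
    probability proportional to ``exp(strength * preference score)`` at the
    candidate endpoint.  Candidates on land get weight zero; if all are on
    land the fish reverses heading.  With ``strength = 0`` the step-length
    and turning-angle marginals equal the generating distributions.
    """
    if n_fish < 0:
        raise ValueError("n_fish must be >= 0")
    pref = pref or PreferenceSpec()
    params = params or TrackGenParams()
    env_dates = env.dates
    if entry_dates is None:
        entry_dates = [env_dates[0]] * n_fish
    entry_dates = [pd.Timestamp(d) for d in entry_dates]
    for d in entry_dates:
        if d < env_dates.min() or d > env_dates.max():
            raise ValueError(f"entry date {d.date()} outside environment date range")
    if len(entry_dates) < n_fish:
        raise ValueError("need one entry date per fish")

    resp_vars = list(pref.responses)
    # fast regular-grid lookups (avoids per-candidate argmin scans)
    lon0, lat0 = env.lons[0], env.lats[0]
    res = env.resolution
    ny, nx = len(env.lats), len(env.lons)
    water = env.water_mask

    def cell_ij(lon_arr, lat_arr):
        j = np.round((np.asarray(lon_arr) - lon0) / res).astype(int)
        i = np.round((np.asarray(lat_arr) - lat0) / res).astype(int)
        ok = (i >= 0) & (i < ny) & (j >= 0) & (j < nx)
        return i, j, ok

    tracks = []
    for f in range(n_fish):
        rng = substream(seed, "track", f)
        dates = pd.date_range(entry_dates[f], periods=params.n_days, freq="D")
        lon = params.entry_lon
        lat = float(rng.uniform(*params.entry_lat_range))
        # nudge the release point to water if needed
        for _ in range(40):
            if env.is_water(lon, lat):
                break
            lat = float(rng.uniform(*params.entry_lat_range))
        heading = float(rng.uniform(-np.pi, np.pi))
        lons = np.empty(params.n_days)
        lats = np.empty(params.n_days)
        lons[0], lats[0] = lon, lat
        for i in range(1, params.n_days):
            date = dates[i]
            layers = {v: env.layer(v, date) for v in resp_vars}
            step = float(rng.gamma(params.step_shape, params.step_scale_km))
            turns = rng.vonmises(0.0, params.turn_kappa, size=params.n_candidates)
            cand_h = wrap_angle(heading + turns)
            clon, clat = dead_reckon(lon, lat, cand_h, step)
            ci, cj, ok = cell_ij(clon, clat)
            ok &= water[np.clip(ci, 0, ny - 1), np.clip(cj, 0, nx - 1)]
            weights = np.zeros(params.n_candidates)
            if pref.strength == 0.0 or not resp_vars:
                weights[ok] = 1.0
            else:
                score = np.zeros(params.n_candidates)
                for v in resp_vars:
                    opt, width = pref.responses[v]
                    x = layers[v][np.clip(ci, 0, ny - 1), np.clip(cj, 0, nx - 1)]
                    score += -((x - opt) ** 2) / (2.0 * width**2)
                weights[ok] = np.exp(np.clip(pref.strength * score[ok], -700.0, 50.0))
            cand_pts = list(zip(np.atleast_1d(clon), np.atleast_1d(clat)))
            if weights.sum() == 0:
                heading = float(wrap_angle(heading + np.pi))
                cand = dead_reckon(lon, lat, heading, step)
                if env.is_water(*cand):
                    lon, lat = cand
            else:
                c = int(rng.choice(params.n_candidates, p=weights / weights.sum()))
                lon, lat = cand_pts[c]
                heading = float(cand_h[c])
            lons[i], lats[i] = lon, lat
        radii = np.exp(
            np.log(params.error_radius_median_deg)
            + params.error_radius_sigma * rng.standard_normal(params.n_days)
        )
        df = pd.DataFrame(
            {"date": dates, "lon": lons, "lat": lats, "error_radius_deg": radii}
        )
        tracks.append(Track(f"sim{f:03d}", df))
    return tracks


# ---------------------------------------------------------------------------
# Dive series
# ---------------------------------------------------------------------------

@dataclass
class SpawnScenario:
    """Ground-truth spawning windows and the dive signature they imprint."""

    windows: dict[str, list[tuple[pd.Timestamp, pd.Timestamp]]] = field(
        default_factory=dict
    )
    oscillation_amp_m: float = 15.0
    oscillation_period_min: float = 30.0
    night_depth_range_m: tuple[float, float] = (5.0, 35.0)
    internal_temp_rise_c: float = 2.5
    surface_temp_c: float = 26.0
    sampling_interval_s: int = 120

    def __post_init__(self) -> None:
        if self.oscillation_period_min <= 0:
            raise ValueError("oscillation period must be positive")
        self.windows = {
            tag: [(pd.Timestamp(a), pd.Timestamp(b)) for a, b in wins]
            for tag, wins in self.windows.items()
        }

    def is_spawning_day(self, tag_id: str, date) -> bool:
        d = pd.Timestamp(date).normalize()
        return any(a <= d <= b for a, b in self.windows.get(tag_id, []))


def assign_spawning_windows(
    tracks: list[Track],
    seed: int = 0,
    p_spawner: float = 0.8,
    window_days: tuple[int, int] = (4, 9),
    **scenario_kwargs,
) -> SpawnScenario:
    """Draw one spawning window per fish (with probability ``p_spawner``).

    Windows are placed in the middle portion of each track so entry/exit
    transit days never overlap them.
    """
    windows: dict[str, list[tuple[pd.Timestamp, pd.Timestamp]]] = {}
    for t in tracks:
        rng = substream(seed, "spawn-window", t.tag_id)
        windows[t.tag_id] = []
        if len(t) < 12 or rng.uniform() > p_spawner:
            continue
        length = int(rng.integers(window_days[0], window_days[1] + 1))
        lo = 3
        hi = len(t) - 3 - length
        if hi <= lo:
            continue
        start = int(rng.integers(lo, hi))
        windows[t.tag_id].append(
            (t.dates[start].normalize(), t.dates[start + length - 1].normalize())
        )
    return SpawnScenario(windows=windows, **scenario_kwargs)


def gen_dive_series(
    track: Track, scenario: SpawnScenario, seed: int = 0
) -> DiveSeries:
    """Synthesize a dive / internal-temperature series for one track.

    Entry and exit days carry deep (> 500 m) transit dives; nights inside the
    fish's spawning windows carry shallow sinusoid-like oscillations with an
    internal-temperature rise; all other nights are flat and shallow, and
    days show irregular mid-depth diving.
    """
    for a, b in scenario.windows.get(track.tag_id, []):
        if a < track.dates.min() or b > track.dates.max():
            raise ValueError(
                f"spawning window {a.date()}..{b.date()} outside track span"
            )
    rng = substream(seed, "dive", track.tag_id)
    dt_s = scenario.sampling_interval_s
    per_day = int(86400 // dt_s)
    n_days = len(track)
    times = []
    depth = np.empty(n_days * per_day)
    t_int = np.empty_like(depth)
    t_ext = np.empty_like(depth)
    mid = float(np.mean(scenario.night_depth_range_m))
    amp = min(
        scenario.oscillation_amp_m,
        (scenario.night_depth_range_m[1] - scenario.night_depth_range_m[0]) / 2.0,
    )
    omega = 2.0 * np.pi / (scenario.oscillation_period_min * 60.0)
    for d in range(n_days):
        date = track.dates[d]
        lon, lat = float(track.lons[d]), float(track.lats[d])
        ts = pd.date_range(date, periods=per_day, freq=f"{dt_s}s")
        times.append(ts)
        night = sun_altitude(lon, lat, ts) < 0.0
        sl = slice(d * per_day, (d + 1) * per_day)
        smooth = ndimage.gaussian_filter1d(
            rng.standard_normal(per_day), sigma=8, mode="reflect"
        )
        smooth /= max(smooth.std(), 1e-9)
        day_depth = np.clip(45.0 + 35.0 * smooth, 2.0, None)
        dd = np.where(night, 4.0 + 0.4 * rng.standard_normal(per_day), day_depth)
        spawning = scenario.is_spawning_day(track.tag_id, date)
        if spawning and night.any():
            sec = (ts - ts[0]).total_seconds().to_numpy(dtype=float)
            osc = mid + amp * np.sin(omega * sec) + 0.3 * rng.standard_normal(per_day)
            dd = np.where(night, np.clip(osc, 1.0, 50.0), dd)
        if d == 0 or d == n_days - 1:
            # transit day: V-shaped deep dive over ~3 h around local noon
            center = int(per_day * 0.75)
            half = int(1.5 * 3600 / dt_s)
            idx = np.arange(per_day)
            vee = 650.0 * np.clip(1.0 - np.abs(idx - center) / half, 0.0, 1.0)
            dd = np.maximum(dd, vee)
        dd = np.clip(dd, 0.0, None)
        ext = scenario.surface_temp_c - 16.0 * (1.0 - np.exp(-dd / 180.0))
        rise = scenario.internal_temp_rise_c if spawning else 0.5
        ti = ext + np.where(night, rise, 0.5) + 0.1 * rng.standard_normal(per_day)
        depth[sl], t_ext[sl], t_int[sl] = dd, ext, ti
    df = pd.DataFrame(
        {
            "timestamp_utc": pd.DatetimeIndex(np.concatenate([t.values for t in times])),
            "depth_m": depth,
            "internal_temp_c": t_int,
            "external_temp_c": t_ext,
        }
    )
    return DiveSeries(track.tag_id, df)


# ---------------------------------------------------------------------------
# Oil polygons and masks
# ---------------------------------------------------------------------------

_KM_PER_DEG_LAT = 110.57


def default_oil_growth(date, peak_km2: float = 25000.0) -> float:
    """Smooth rise-and-fall areal footprint over the 2010 activity window."""
    d = pd.Timestamp(date).normalize()
    if d < OIL_START or d > OIL_END:
        return 0.0
    frac = (d - OIL_START) / (OIL_END - OIL_START)
    return float(peak_km2 * np.sin(np.pi * frac) ** 1.5)


def gen_oil_extent(
    dates,
    well: tuple[float, float] = DEFAULT_WELL,
    growth=default_oil_growth,
    seed: int = 0,
    n_vertices: int = 72,
    irregularity: float = 0.25,
    domain_bounds=GOM_BOUNDS,
) -> list[tuple[pd.Timestamp, Polygon]]:
    """One irregular surface-oil polygon per date, centred on the well.

    ``growth`` maps a date to a target area in km²; the polygon's planar
    (locally projected) area matches it exactly up to floating point.  Dates
    with zero target area yield empty polygons.
    """
    w, e, s, n = domain_bounds
    if not (w <= well[0] <= e and s <= well[1] <= n):
        raise ValueError("well outside domain")
    rng = substream(seed, "oil")
    harmonics = np.arange(2, 6)
    a = rng.normal(0.0, 1.0 / harmonics, size=harmonics.size)
    b = rng.normal(0.0, 1.0 / harmonics, size=harmonics.size)
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    km_per_deg_lon = _KM_PER_DEG_LAT * np.cos(np.radians(well[1]))
    out = []
    for k, date in enumerate(pd.to_datetime(list(dates))):
        area = float(growth(date)) if callable(growth) else float(growth[k])
        if area < 0:
            raise ValueError("growth curve must be >= 0")
        if area == 0.0:
            out.append((date, Polygon()))
            continue
        phase = 0.05 * k
        wobble = sum(
            a[m] * np.cos(h * theta + phase) + b[m] * np.sin(h * theta + phase)
            for m, h in enumerate(harmonics)
        )
        r = 1.0 + irregularity * wobble / max(np.abs(wobble).max(), 1e-9)
        x, y = r * np.cos(theta), r * np.sin(theta)
        raw_area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        scale = np.sqrt(area / raw_area)
        lon = well[0] + scale * x / km_per_deg_lon
        lat = well[1] + scale * y / _KM_PER_DEG_LAT
        out.append((date, Polygon(zip(lon, lat))))
    return out


def gen_gom_mask(env: EnvFieldStack) -> Polygon:
    """Convex hull of the water cells, as a whole-Gulf analysis mask."""
    from shapely.geometry import MultiPoint

    water = env.water_mask
    lon_g, lat_g = np.meshgrid(env.lons, env.lats)
    pts = MultiPoint(list(zip(lon_g[water], lat_g[water])))
    return pts.convex_hull.buffer(env.resolution / 2)


def gen_eez_mask(env: EnvFieldStack, south_lat: float = 25.0) -> Polygon:
    """Synthetic stand-in for the US EEZ: the Gulf mask north of ``south_lat``."""
    from shapely.geometry import box

    w, e, s, n = env.bounds
    return gen_gom_mask(env).intersection(box(w, south_lat, e, n))


# ---------------------------------------------------------------------------
# GeoJSON IO
# ---------------------------------------------------------------------------

def write_polygons_geojson(dated_polys, path) -> None:
    """Write (date, polygon) pairs as a FeatureCollection (ISO-8601 dates)."""
    features = []
    for date, poly in dated_polys:
        features.append(
            {
                "type": "Feature",
                "properties": {"date": pd.Timestamp(date).strftime("%Y-%m-%d")},
                "geometry": mapping(poly),
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_polygons_geojson(path) -> list[tuple[pd.Timestamp, Polygon]]:
    with open(path) as fh:
        gj = json.load(fh)
    out = []
    for feat in gj["features"]:
        geom = shape(feat["geometry"]) if feat["geometry"]["coordinates"] else Polygon()
        out.append((pd.Timestamp(feat["properties"]["date"]), geom))
    return out
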