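"""Track and dive-series containers, IO, Gulf occupancy, covariate extraction.

Tracks are daily geolocations with a per-day positional error radius (the
output of a light-level geolocation + state-space smoothing workflow, which
is upstream of this package).  Gulf-of-Mexico occupancy follows the tagging
convention: a fish has entered the Gulf once it passes the 80.5° W meridian
and stays west of it for at least six consecutive days.

Covariate extraction averages each gridded field over the cells whose centers
fall within the day's error radius of the position, then applies the log
transform to chl and EKE (transform of the mean), and appends the moon
illumination fraction computed from the date.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .astro import moon_fraction
from .fields import DYNAMIC_VARS, STATIC_VARS, EnvFieldStack

TRACK_COLUMNS = ["tag_id", "date", "lon", "lat", "error_radius_deg"]
DIVE_COLUMNS = ["tag_id", "timestamp_utc", "depth_m", "internal_temp_c", "external_temp_c"]

#: Covariate names after transformation, in canonical order.
COVARIATE_NAMES = (
    "sst", "sst_sd", "log_chl", "ssha", "ssha_sd", "log_eke",
    "wekman", "uy10", "bathy", "bathy_sd", "moon",
)

GOM_MERIDIAN = -80.5
GOM_MIN_DAYS = 6


class TrackFormatError(ValueError):
    """Malformed track file (missing columns, unparsable rows)."""


class TrackValidationError(ValueError):
    """Well-formed file with invalid content (bounds, duplicates)."""


@dataclass
class Track:
    """One fish's daily positions with error radii.

    ``df`` has columns date (datetime64), lon, lat, error_radius_deg; rows
    are sorted by date with one record per day.
    """

    tag_id: str
    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True).copy()
        df["date"] = pd.to_datetime(df["date"])
        if df["date"].duplicated().any():
            dup = df.loc[df["date"].duplicated(), "date"].iloc[0]
            raise TrackValidationError(
                f"duplicate (tag_id, date) for tag {self.tag_id!r} on {dup.date()}"
            )
        df = df.sort_values("date").reset_index(drop=True)
        if not ((df["lat"].abs() <= 90).all() and (df["lon"].abs() <= 180).all()):
            bad = df.index[(df["lat"].abs() > 90) | (df["lon"].abs() > 180)][0]
            raise TrackValidationError(
                f"tag {self.tag_id!r} row {bad}: lon/lat out of bounds"
            )
        if (df["error_radius_deg"] < 0).any():
            raise TrackValidationError(f"tag {self.tag_id!r}: negative error radius")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.df["date"])

    @property
    def lons(self) -> np.ndarray:
        return self.df["lon"].to_numpy(dtype=float)

    @property
    def lats(self) -> np.ndarray:
        return self.df["lat"].to_numpy(dtype=float)

    @property
    def error_radii(self) -> np.ndarray:
        return self.df["error_radius_deg"].to_numpy(dtype=float)


@dataclass
class DiveSeries:
    """Sub-daily depth / temperature record aligned to a track."""

    tag_id: str
    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True).copy()
        df["timestamp_utc"] = pd.to_datetime(df["timestamp_utc"])
        if not df["timestamp_utc"].is_monotonic_increasing:
            df = df.sort_values("timestamp_utc").reset_index(drop=True)
        if df["timestamp_utc"].duplicated().any():
            raise TrackValidationError(f"tag {self.tag_id!r}: duplicate timestamps")
        if (df["depth_m"] < 0).any():
            raise TrackValidationError(f"tag {self.tag_id!r}: negative depth")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# CSV IO
# ---------------------------------------------------------------------------

def read_tracks(path) -> list[Track]:
    """Read tracks from CSV, grouped by tag_id and sorted by date."""
    try:
        raw = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise TrackFormatError(f"{path}: empty file, expected header") from exc
    missing = [c for c in TRACK_COLUMNS if c not in raw.columns]
    if missing:
        raise TrackFormatError(f"{path}: missing columns {missing}")
    bad_rows = []
    for col in ("lon", "lat", "error_radius_deg"):
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad_rows.extend((int(i) + 2) for i in raw.index[coerced.isna() & raw[col].notna()])
        raw[col] = coerced
    if bad_rows:
        raise TrackFormatError(f"{path}: unparsable numeric values on lines {sorted(set(bad_rows))}")
    tracks = []
    for tag, grp in raw.groupby("tag_id", sort=True):
        tracks.append(Track(str(tag), grp[TRACK_COLUMNS[1:]].copy()))
    return tracks


def write_tracks(tracks: list[Track], path) -> None:
    frames = []
    for t in tracks:
        d = t.df.copy()
        d.insert(0, "tag_id", t.tag_id)
        frames.append(d)
    out = pd.concat(frames) if frames else pd.DataFrame(columns=TRACK_COLUMNS)
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_dive_series(path) -> list[DiveSeries]:
    raw = pd.read_csv(path)
    missing = [c for c in DIVE_COLUMNS if c not in raw.columns]
    if missing:
        raise TrackFormatError(f"{path}: missing columns {missing}")
    return [
        DiveSeries(str(tag), grp[DIVE_COLUMNS[1:]].copy())
        for tag, grp in raw.groupby("tag_id", sort=True)
    ]


def write_dive_series(series: list[DiveSeries], path) -> None:
    frames = []
    for s in series:
        d = s.df.copy()
        d.insert(0, "tag_id", s.tag_id)
        frames.append(d)
    out = pd.concat(frames) if frames else pd.DataFrame(columns=DIVE_COLUMNS)
    out["timestamp_utc"] = pd.to_datetime(out["timestamp_utc"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%S"
    )
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Gulf occupancy
# ---------------------------------------------------------------------------

def detect_gom_occupancy(
    track: Track, meridian: float = GOM_MERIDIAN, min_days: int = GOM_MIN_DAYS
) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """Occupancy intervals: runs of >= min_days consecutive days west of the meridian.

    Returns (entry_date, exit_date) pairs; exit is the last consecutive day
    west of the meridian.  A track that never satisfies the rule yields [].
    """
    if len(track) == 0:
        raise TrackValidationError("empty track")
    west = track.lons < meridian
    dates = track.dates
    intervals = []
    i = 0
    n = len(track)
    while i < n:
        if not west[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and west[j + 1]:
            j += 1
        if j - i + 1 >= min_days:
            intervals.append((dates[i], dates[j]))
        i = j + 1
    return intervals


# ---------------------------------------------------------------------------
# Covariate extraction
# ---------------------------------------------------------------------------

class OutOfDomainError(ValueError):
    """Position outside the environmental grid."""


class TransformError(ValueError):
    """Non-positive chl/EKE mean cannot be log-transformed."""


def extract_covariates(
    lon: float,
    lat: float,
    date,
    error_radius: float,
    env: EnvFieldStack,
) -> dict[str, float]:
    """Error-radius-averaged covariates at one daily position.

    Each field is averaged (unweighted) over grid cells whose centers lie
    within ``error_radius`` degrees (Euclidean in lon/lat) of the position;
    if no center falls inside, the containing cell's value is used.  chl and
    eke are log-transformed after averaging; cells over land (bathy >= 0) are
    excluded from the average.  The moon fraction depends on the date only.
    """
    if error_radius < 0:
        raise ValueError("error_radius must be >= 0")
    if not env.in_domain(lon, lat):
        raise OutOfDomainError(f"position ({lon}, {lat}) outside environment grid")
    lons, lats = env.lons, env.lats
    # window of rows/cols that can fall inside the radius (keeps the scan local)
    i0 = int(np.searchsorted(lats, lat - error_radius - env.resolution))
    i1 = int(np.searchsorted(lats, lat + error_radius + env.resolution)) + 1
    j0 = int(np.searchsorted(lons, lon - error_radius - env.resolution))
    j1 = int(np.searchsorted(lons, lon + error_radius + env.resolution)) + 1
    lon_w, lat_w = np.meshgrid(lons[j0:j1], lats[i0:i1])
    dist2 = (lon_w - lon) ** 2 + (lat_w - lat) ** 2
    inside = dist2 <= error_radius**2
    water = env.water_mask[i0:i1, j0:j1]
    sel = inside & water
    if not sel.any():
        i, j = env.cell_index(lon, lat)
        i0, i1, j0, j1 = i, i + 1, j, j + 1
        sel = np.ones((1, 1), dtype=bool)
    out: dict[str, float] = {}
    for var in DYNAMIC_VARS + STATIC_VARS:
        vals = env.layer(var, date)[i0:i1, j0:j1][sel]
        mean = float(np.nanmean(vals))
        if var in ("chl", "eke"):
            if mean <= 0:
                raise TransformError(f"non-positive {var} mean {mean} at ({lon}, {lat})")
            out[f"log_{var}"] = math.log(mean)
        else:
            out[var] = mean
    out["moon"] = moon_fraction(date)
    return {k: out[k] for k in COVARIATE_NAMES}


def extract_covariates_track(track: Track, env: EnvFieldStack) -> pd.DataFrame:
    """Covariate table for every day of a track (rows aligned to track days)."""
    rows = []
    for date, lon, lat, r in zip(
        track.dates, track.lons, track.lats, track.error_radii
    ):
        row = extract_covariates(lon, lat, date, r, env)
        row["tag_id"] = track.tag_id
        row["date"] = date
        rows.append(row)
    return pd.DataFrame(rows, columns=["tag_id", "date", *COVARIATE_NAMES])
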