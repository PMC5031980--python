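"""Solar altitude and lunar illumination.

The dive-data generator and the spawning detector must agree on what "night"
means, so both import :func:`sun_altitude` from here.  Accuracy requirements
are modest (day/night discrimination and a smooth moon covariate), so both
functions use standard low-precision astronomical approximations.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

SYNODIC_MONTH_DAYS = 29.530588
#: Reference new moon: 2000-01-06 18:14 UT.
NEW_MOON_EPOCH = dt.datetime(2000, 1, 6, 18, 14, tzinfo=dt.timezone.utc)
_J2000 = dt.datetime(2000, 1, 1, 12, 0, tzinfo=dt.timezone.utc)


def _to_utc_datetime(t) -> dt.datetime:
    ts = pd.Timestamp(t)
    if ts.tzinfo is None:
        ts = ts.tz_localize("UTC")
    return ts.to_pydatetime()


def _days_since(epoch: dt.datetime, times) -> np.ndarray:
    arr = pd.to_datetime(np.atleast_1d(np.asarray(times, dtype=object)))
    if arr.tz is None:
        arr = arr.tz_localize("UTC")
    ref = pd.Timestamp(epoch)
    return (arr - ref) / pd.Timedelta(days=1)


def sun_altitude(lon: float, lat: float, times) -> np.ndarray:
    """Solar altitude (degrees above horizon) at a fixed position.

    Uses the standard low-precision solar ephemeris (mean longitude / mean
    anomaly polynomial, good to ~0.01 deg) and sidereal time for the hour
    angle.  ``times`` may be a scalar or array of UTC timestamps.

    Parameters
    ----------
    lon, lat : float
        Position in decimal degrees, WGS84.
    times : datetime-like or sequence
        UTC instants.

    Returns
    -------
    ndarray of float, shape like ``times``.
    """
    n = np.asarray(_days_since(_J2000, times), dtype=float)
    L = np.deg2rad((280.460 + 0.9856474 * n) % 360.0)  # mean longitude
    g = np.deg2rad((357.528 + 0.9856003 * n) % 360.0)  # mean anomaly
    lam = L + np.deg2rad(1.915) * np.sin(g) + np.deg2rad(0.020) * np.sin(2 * g)
    eps = np.deg2rad(23.439 - 4.0e-7 * n)  # obliquity
    dec = np.arcsin(np.sin(eps) * np.sin(lam))
    ra = np.arctan2(np.cos(eps) * np.sin(lam), np.cos(lam))
    gmst_hours = (18.697374558 + 24.06570982441908 * n) % 24.0
    ha = np.deg2rad(gmst_hours * 15.0 + lon) - ra
    phi = np.deg2rad(lat)
    alt = np.arcsin(
        np.sin(phi) * np.sin(dec) + np.cos(phi) * np.cos(dec) * np.cos(ha)
    )
    return np.rad2deg(alt)


def is_night(lon: float, lat: float, times) -> np.ndarray:
    """Boolean night mask (sun below the horizon)."""
    return sun_altitude(lon, lat, times) < 0.0


import functools


@functools.lru_cache(maxsize=8192)
def _moon_fraction_cached(iso_date: str) -> float:
    return _moon_fraction_impl(iso_date)


def moon_fraction(date) -> float:
    """Fraction of the lunar disc illuminated, in [0, 1].

    Computed as ``(1 - cos(2*pi*age/P)) / 2`` with ``age`` the time since the
    reference new moon (2000-01-06 18:14 UT) modulo the synodic month
    ``P = 29.530588`` days.  Phase only; no ecliptic-latitude correction.
    """
    return _moon_fraction_cached(str(pd.Timestamp(date)))


def _moon_fraction_impl(iso_date: str) -> float:
    age = float(np.asarray(_days_since(NEW_MOON_EPOCH, iso_date))[0]) % SYNODIC_MONTH_DAYS
    return float((1.0 - np.cos(2.0 * np.pi * age / SYNODIC_MONTH_DAYS)) / 2.0)
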