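"""Spherical geometry helpers shared by the movement modules.

All distances are great-circle kilometres on a sphere of radius 6371 km;
bearings are radians clockwise from true north.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0


def gc_distance_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle (haversine) distance in km; accepts scalars or arrays."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return EARTH_RADIUS_KM * 2 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def initial_bearing(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Initial great-circle bearing from point 1 to point 2 (radians from north)."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    y = np.sin(dlon) * np.cos(lat2)
    x = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    return np.arctan2(y, x)


def dead_reckon(lon: float, lat: float, bearing: float, dist_km: float):
    """Local-tangent-plane step: move dist_km along bearing from (lon, lat)."""
    dlat = (dist_km / EARTH_RADIUS_KM) * np.cos(bearing)
    coslat = max(np.cos(np.radians(lat)), 1e-6)
    dlon = (dist_km / EARTH_RADIUS_KM) * np.sin(bearing) / coslat
    return lon + np.degrees(dlon), lat + np.degrees(dlat)


def wrap_angle(theta) -> np.ndarray:
    """Wrap angle(s) to (-pi, pi]."""
    out = np.mod(np.asarray(theta) + np.pi, 2 * np.pi) - np.pi
    return np.where(out == -np.pi, np.pi, out)
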