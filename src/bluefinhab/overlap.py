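"""Oil/habitat overlap metrics with spherical cell-area accounting.

Weekly binary habitat maps are intersected with the nearest-dated surface
oil polygon: the polygon is rasterized to a per-cell covered fraction, areas
are accumulated with the exact spherical cell area, and the two published
exposure percentages are computed per week — the share of habitat that was
oiled, and the share of the oiled extent that was habitat — whole-Gulf and
restricted to an EEZ mask.  The weekly oiled-habitat areas sum to the
cumulative exposure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import box
from shapely.validation import make_valid

EARTH_RADIUS_KM = 6371.0


def cell_area(
    lat_south: float, lat_north: float, dlon: float, radius_km: float = EARTH_RADIUS_KM
) -> float:
    """Spherical area (km²) of a lon/lat cell: R²·Δλ·(sin φ_N − sin φ_S)."""
    if not (-90.0 <= lat_south < lat_north <= 90.0):
        raise ValueError("need -90 <= lat_south < lat_north <= 90")
    if dlon <= 0:
        raise ValueError("dlon must be positive")
    return float(
        radius_km**2
        * np.radians(dlon)
        * (np.sin(np.radians(lat_north)) - np.sin(np.radians(lat_south)))
    )


def cell_area_rows(lats: np.ndarray, resolution: float) -> np.ndarray:
    """Per-latitude-row cell areas (km²) for a regular grid of cell centers."""
    lats = np.asarray(lats, dtype=float)
    half = resolution / 2.0
    return np.array([cell_area(la - half, la + half, resolution) for la in lats])


def rasterize_polygons(
    polygons, lons: np.ndarray, lats: np.ndarray, resolution: float
) -> np.ndarray:
    """Per-cell covered fraction in [0, 1] by exact polygon/cell clipping.

    ``polygons`` is a single (Multi)Polygon or an iterable; invalid
    geometries are cleaned with ``make_valid`` first.  Holes are respected.
    """
    from shapely.geometry.base import BaseGeometry
    from shapely.ops import unary_union

    if isinstance(polygons, BaseGeometry):
        geom = polygons
    else:
        geom = unary_union(list(polygons))
    frac = np.zeros((len(lats), len(lons)))
    if geom.is_empty:
        return frac
    if not geom.is_valid:
        geom = make_valid(geom)
        if not geom.is_valid:
            raise ValueError("invalid polygon could not be cleaned")
    half = resolution / 2.0
    minx, miny, maxx, maxy = geom.bounds
    jj = np.where((lons + half >= minx) & (lons - half <= maxx))[0]
    ii = np.where((lats + half >= miny) & (lats - half <= maxy))[0]
    cell_a = resolution * resolution
    for i in ii:
        for j in jj:
            cell = box(lons[j] - half, lats[i] - half, lons[j] + half, lats[i] + half)
            inter = geom.intersection(cell)
            if not inter.is_empty:
                frac[i, j] = inter.area / cell_a
    return np.clip(frac, 0.0, 1.0)


@dataclass
class OverlapRow:
    """One week's exposure metrics (areas km², percentages 0–100)."""

    week: pd.Timestamp
    habitat_km2: float
    oil_km2: float
    oiled_habitat_km2: float
    pct_habitat_oiled: float
    pct_oil_is_habitat: float
    habitat_km2_eez: float = np.nan
    oil_km2_eez: float = np.nan
    oiled_habitat_km2_eez: float = np.nan
    pct_habitat_oiled_eez: float = np.nan
    pct_oil_is_habitat_eez: float = np.nan
    zero_denominator: bool = False


def _metrics(habitat01, oiled_frac, areas_2d):
    hab = np.nan_to_num(habitat01, nan=0.0)
    habitat_area = float(np.sum(hab * areas_2d))
    oil_area = float(np.sum(oiled_frac * areas_2d))
    oiled_hab = float(np.sum(hab * oiled_frac * areas_2d))
    flag = False
    if habitat_area > 0:
        pct_hab = 100.0 * oiled_hab / habitat_area
    else:
        pct_hab, flag = 0.0, True
    if oil_area > 0:
        pct_oil = 100.0 * oiled_hab / oil_area
    else:
        pct_oil, flag = 0.0, True
    return habitat_area, oil_area, oiled_hab, pct_hab, pct_oil, flag


def overlap_metrics(
    habitat,
    oiled_fraction: np.ndarray,
    lats: np.ndarray,
    resolution: float,
    eez_mask: np.ndarray | None = None,
    week=None,
) -> OverlapRow:
    """Exposure metrics for one week from aligned habitat / oil-fraction grids.

    ``habitat`` is a BinaryHabitatGrid or a (lat, lon) 0/1 array (NaN =
    masked).  Zero-denominator percentages are reported as 0 with
    ``zero_denominator=True``.
    """
    hab_values = getattr(habitat, "values", habitat)
    week = week if week is not None else getattr(habitat, "week_start", pd.NaT)
    if hab_values.shape != oiled_fraction.shape:
        raise ValueError("habitat and oil grids do not match")
    areas = np.broadcast_to(
        cell_area_rows(lats, resolution)[:, None], hab_values.shape
    )
    h, o, oh, ph, po, flag = _metrics(hab_values, oiled_fraction, areas)
    row = OverlapRow(pd.Timestamp(week), h, o, oh, ph, po, zero_denominator=flag)
    if eez_mask is not None:
        m = eez_mask.astype(float)
        he, oe, ohe, phe, poe, flag_e = _metrics(
            np.nan_to_num(hab_values, nan=0.0) * m, oiled_fraction * m, areas
        )
        row.habitat_km2_eez = he
        row.oil_km2_eez = oe
        row.oiled_habitat_km2_eez = ohe
        row.pct_habitat_oiled_eez = phe
        row.pct_oil_is_habitat_eez = poe
        row.zero_denominator = row.zero_denominator or flag_e
    return row


def overlap_report(rows: list[OverlapRow]) -> pd.DataFrame:
    """Weekly exposure table, ordered by week."""
    df = pd.DataFrame([r.__dict__ for r in rows])
    return df.sort_values("week", ignore_index=True)


def cumulative_exposure(rows) -> float:
    """Cumulative oiled-habitat area: the sum of weekly oiled-habitat areas."""
    if isinstance(rows, pd.DataFrame):
        if len(rows) == 0:
            raise ValueError("need at least one weekly row")
        return float(rows["oiled_habitat_km2"].sum())
    rows = list(rows)
    if not rows:
        raise ValueError("need at least one weekly row")
    return float(sum(r.oiled_habitat_km2 for r in rows))


def nearest_oil_polygon(dated_polys, date):
    """The oil polygon whose date is nearest to ``date`` (no morphing)."""
    date = pd.Timestamp(date)
    diffs = [abs((pd.Timestamp(d) - date).total_seconds()) for d, _ in dated_polys]
    return dated_polys[int(np.argmin(diffs))][1]


def rasterize_mask(polygon, lons, lats, resolution, threshold: float = 0.5):
    """Boolean cell mask: cells at least half-covered by the polygon."""
    return rasterize_polygons(polygon, lons, lats, resolution) >= threshold
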