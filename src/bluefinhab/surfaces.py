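"""Weekly likelihood surfaces, ROC cutoffs and the spawning-habitat product.

Fitted models are evaluated on the environment grid (0.25° by default) in
weekly increments, the continuous likelihoods are binarized at a threshold
chosen to cap the false-positive rate (conservative habitat estimates), and
the habitat and spawning surfaces are multiplied cellwise to give total
spawning habitat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .astro import moon_fraction
from .fields import EnvFieldStack
from .tracks import COVARIATE_NAMES


@dataclass
class LikelihoodGrid:
    """Per-cell likelihood surface for one week on the environment grid."""

    week_start: pd.Timestamp
    lons: np.ndarray
    lats: np.ndarray
    values: np.ndarray  # (lat, lon), NaN on masked cells
    sd: np.ndarray | None = None
    provenance: str = "habitat"

    def __post_init__(self) -> None:
        ok = np.isfinite(self.values)
        if ok.any() and ((self.values[ok] < 0) | (self.values[ok] > 1)).any():
            raise ValueError("likelihood values must lie in [0, 1]")

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def binarize(self, threshold: float) -> "BinaryHabitatGrid":
        vals = np.where(
            self.valid_mask, (self.values >= threshold).astype(float), np.nan
        )
        return BinaryHabitatGrid(
            self.week_start, self.lons, self.lats, vals, threshold, self.provenance
        )


@dataclass
class BinaryHabitatGrid:
    """0/1 (or NaN-masked) habitat map with the threshold that produced it."""

    week_start: pd.Timestamp
    lons: np.ndarray
    lats: np.ndarray
    values: np.ndarray
    threshold: float
    provenance: str = "habitat"


def _covariate_table(env: EnvFieldStack, date, mask: np.ndarray) -> pd.DataFrame:
    """Per-cell covariate rows (transformed) for all unmasked water cells."""
    lon_g, lat_g = np.meshgrid(env.lons, env.lats)
    sel = mask
    data = {}
    for var in ("sst", "sst_sd", "chl", "ssha", "ssha_sd", "eke", "wekman", "uy10"):
        data[var] = env.layer(var, date)[sel]
    for var in ("bathy", "bathy_sd"):
        data[var] = env.layer(var)[sel]
    df = pd.DataFrame(data)
    with np.errstate(divide="ignore"):
        df["log_chl"] = np.log(df.pop("chl"))
        df["log_eke"] = np.log(df.pop("eke"))
    df["moon"] = moon_fraction(date)
    df["lon"] = lon_g[sel]
    df["lat"] = lat_g[sel]
    return df


def predict_surface(
    fit,
    env: EnvFieldStack,
    week_start,
    provenance: str = "habitat",
    mask: np.ndarray | None = None,
) -> LikelihoodGrid:
    """Evaluate a fitted model (or an ensemble of fits) on the weekly grid.

    Covariate layers are taken at the nearest date to the week midpoint.
    The random intercept is set to its population mean (zero on the link
    scale).  ``fit`` may be a single fitted model or a sequence; a sequence
    yields the cellwise ensemble mean with a per-cell sd layer.  ``mask``
    restricts evaluation (defaults to the water mask).
    """
    week_start = pd.Timestamp(week_start)
    midpoint = week_start + pd.Timedelta(days=3)
    valid = env.water_mask if mask is None else (mask & env.water_mask)
    ny, nx = len(env.lats), len(env.lons)
    if not valid.any():
        empty = np.full((ny, nx), np.nan)
        return LikelihoodGrid(week_start, env.lons, env.lats, empty, None, provenance)
    table = _covariate_table(env, midpoint, valid)
    missing = [c for c in COVARIATE_NAMES if c not in table.columns]
    if missing:
        raise ValueError(f"missing covariate layers {missing}")
    fits = fit if isinstance(fit, (list, tuple)) else [fit]
    preds = []
    for f in fits:
        est = getattr(f, "estimator", f)
        preds.append(est.predict_proba(table)[:, 1])
    pred = np.mean(preds, axis=0)
    values = np.full((ny, nx), np.nan)
    values[valid] = pred
    sd = None
    if len(preds) > 1:
        sd = np.full((ny, nx), np.nan)
        sd[valid] = np.std(preds, axis=0)
    return LikelihoodGrid(week_start, env.lons, env.lats, values, sd, provenance)


def choose_cutoff(scores, y, max_fpr: float = 0.05) -> float:
    """Smallest score threshold whose empirical FPR is <= ``max_fpr``.

    Classification is ``score >= threshold``; TPR is non-increasing in the
    threshold, so the smallest admissible threshold also maximizes TPR.  If
    even the largest observed score exceeds the FPR bound, the maximum score
    is returned with a warning (everything classified negative except ties
    at the maximum).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(int)
    if np.unique(y).size < 2:
        raise ValueError("cutoff selection needs both classes")
    s0 = scores[y == 0]
    candidates = np.unique(scores)
    admissible = [t for t in candidates if (s0 >= t).mean() <= max_fpr]
    if not admissible:
        warnings.warn(
            f"no threshold attains FPR <= {max_fpr}; returning the maximum score"
        )
        return float(candidates.max())
    return float(min(admissible))


def choose_cutoff_from_fit(fit, table: pd.DataFrame, max_fpr: float = 0.05) -> float:
    """Cutoff from a fitted model scored on a validation table."""
    est = getattr(fit, "estimator", fit)
    scores = est.predict_proba(table)[:, 1]
    return choose_cutoff(scores, table["response"].to_numpy(), max_fpr=max_fpr)


def spawning_habitat_product(
    habitat: LikelihoodGrid,
    spawning: LikelihoodGrid,
    threshold: float | None = None,
    mode: str = "product_then_threshold",
    habitat_threshold: float | None = None,
    spawning_threshold: float | None = None,
) -> tuple[LikelihoodGrid, BinaryHabitatGrid | None]:
    """Cellwise product of habitat and spawning likelihood, plus binary map.

    ``mode="product_then_threshold"`` thresholds the product at
    ``threshold``; ``mode="intersect"`` intersects the two individually
    binarized maps.  With no thresholds given only the continuous product is
    returned.
    """
    if habitat.values.shape != spawning.values.shape or not np.allclose(
        habitat.lons, spawning.lons
    ):
        raise ValueError("habitat and spawning grids do not match")
    if habitat.week_start != spawning.week_start:
        raise ValueError("habitat and spawning weeks do not match")
    prod = LikelihoodGrid(
        habitat.week_start,
        habitat.lons,
        habitat.lats,
        habitat.values * spawning.values,
        None,
        "product",
    )
    binary = None
    if mode == "product_then_threshold" and threshold is not None:
        binary = prod.binarize(threshold)
    elif mode == "intersect" and habitat_threshold is not None:
        bh = habitat.binarize(habitat_threshold)
        bs = spawning.binarize(spawning_threshold if spawning_threshold is not None else habitat_threshold)
        vals = bh.values * bs.values
        binary = BinaryHabitatGrid(
            habitat.week_start, habitat.lons, habitat.lats, vals,
            float(habitat_threshold), "product",
        )
    return prod, binary


def surfaces_to_dataset(grids: list[LikelihoodGrid]):
    """Stack weekly grids into an xarray Dataset (lon, lat, week)."""
    import xarray as xr

    weeks = [g.week_start for g in grids]
    values = np.stack([g.values for g in grids])
    ds = xr.Dataset(
        {"likelihood": (("week", "lat", "lon"), values)},
        coords={"week": weeks, "lat": grids[0].lats, "lon": grids[0].lons},
    )
    if all(g.sd is not None for g in grids):
        ds["ensemble_sd"] = (("week", "lat", "lon"), np.stack([g.sd for g in grids]))
    return ds
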