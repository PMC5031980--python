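"""Correlated-random-walk pseudo-absence ensembles.

Tracking data are presence-only; absences are unobservable.  Each observed
track is paired with correlated random walks (CRWs) built by resampling that
track's own empirical daily step lengths and turning angles, started at the
track's Gulf entry point with the track's initial heading.  A CRW keeps the
source's dates and per-day error radii, so presence and pseudo-absence are
sampled at identical spatiotemporal scales.  One CRW per track is drawn per
model run (100 CRWs per track, 60 runs by default downstream).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seeding import substream
from .fields import EnvFieldStack
from .geo import dead_reckon, gc_distance_km, initial_bearing, wrap_angle
from .tracks import Track


class InsufficientDataError(ValueError):
    """Track too short to estimate step/turn distributions."""


@dataclass
class StepDistribution:
    """Empirical daily step lengths (km) and turning angles (radians)."""

    step_lengths_km: np.ndarray
    turning_angles: np.ndarray
    initial_heading: float

    def __post_init__(self) -> None:
        self.step_lengths_km = np.asarray(self.step_lengths_km, dtype=float)
        self.turning_angles = np.asarray(self.turning_angles, dtype=float)
        if (self.step_lengths_km < 0).any():
            raise ValueError("negative step length")


@dataclass
class CRWEnsemble:
    """Simulated pseudo-absence tracks for one source track."""

    source_tag_id: str
    members: list[Track]

    def __len__(self) -> int:
        return len(self.members)


def fit_step_distribution(track: Track) -> StepDistribution:
    """Empirical step-length / turning-angle distributions of a track.

    Steps are great-circle daily displacements; turning angles are signed
    changes of heading at interior positions, wrapped to (-pi, pi].
    """
    if len(track) < 3:
        raise InsufficientDataError(
            f"track {track.tag_id!r} has {len(track)} positions; need >= 3"
        )
    lons, lats = track.lons, track.lats
    steps = gc_distance_km(lons[:-1], lats[:-1], lons[1:], lats[1:])
    headings = initial_bearing(lons[:-1], lats[:-1], lons[1:], lats[1:])
    turns = wrap_angle(np.diff(headings))
    return StepDistribution(steps, turns, float(headings[0]))


def _is_water(lon: float, lat: float, water_mask) -> bool:
    if water_mask is None:
        return True
    if isinstance(water_mask, EnvFieldStack):
        return water_mask.is_water(lon, lat)
    # shapely geometry
    from shapely.geometry import Point

    return bool(water_mask.contains(Point(lon, lat)))


def simulate_crw(
    source: Track,
    dist: StepDistribution,
    start: tuple[float, float],
    water_mask=None,
    seed: int | np.random.Generator = 0,
    joint: bool = False,
    max_attempts: int = 50,
) -> Track:
    """One CRW with the source's dates and error radii.

    The first heading equals the source's initial heading; each later step
    resamples a step length and turning angle (independently by default,
    jointly with ``joint=True``).  Steps landing outside the water mask are
    rejected and redrawn up to ``max_attempts`` times, after which the step
    is reflected (heading reversed); if even the reflected step is invalid
    the fish holds position for that day.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lon, lat = float(start[0]), float(start[1])
    if not _is_water(lon, lat, water_mask):
        raise ValueError(f"CRW start ({lon}, {lat}) is on land")
    n = len(source)
    lons = np.empty(n)
    lats = np.empty(n)
    lons[0], lats[0] = lon, lat
    heading = dist.initial_heading
    n_steps = len(dist.step_lengths_km)
    n_turns = len(dist.turning_angles)
    for i in range(1, n):
        placed = False
        for attempt in range(max_attempts):
            k = rng.integers(n_steps)
            if joint:
                turn = dist.turning_angles[min(k, n_turns - 1)] if n_turns else 0.0
            else:
                turn = dist.turning_angles[rng.integers(n_turns)] if n_turns else 0.0
            step = dist.step_lengths_km[k]
            h = heading if i == 1 else float(wrap_angle(heading + turn))
            cand = dead_reckon(lon, lat, h, step)
            if _is_water(cand[0], cand[1], water_mask):
                lon, lat = cand
                heading = h
                placed = True
                break
        if not placed:
            # reflect: reverse heading for this step
            h = float(wrap_angle(heading + np.pi))
            step = dist.step_lengths_km[rng.integers(n_steps)]
            cand = dead_reckon(lon, lat, h, step)
            if _is_water(cand[0], cand[1], water_mask):
                lon, lat = cand
                heading = h
        lons[i], lats[i] = lon, lat
    df = pd.DataFrame(
        {
            "date": source.dates,
            "lon": lons,
            "lat": lats,
            "error_radius_deg": source.error_radii,
        }
    )
    return Track(source.tag_id, df)


def build_ensemble(
    source: Track,
    n: int = 100,
    seed: int = 0,
    start: tuple[float, float] | None = None,
    water_mask=None,
    joint: bool = False,
) -> CRWEnsemble:
    """``n`` independent CRWs for one source track, reproducible given seed."""
    if n < 1:
        raise ValueError("ensemble size must be >= 1")
    dist = fit_step_distribution(source)
    if start is None:
        start = (float(source.lons[0]), float(source.lats[0]))
    members = [
        simulate_crw(
            source,
            dist,
            start,
            water_mask=water_mask,
            seed=substream(seed, "crw", source.tag_id, i),
            joint=joint,
        )
        for i in range(n)
    ]
    return CRWEnsemble(source.tag_id, members)


def sample_pseudo_absence(
    ensemble: CRWEnsemble, run_index: int, master_seed: int
) -> Track:
    """Uniform draw of one CRW, deterministic given (master_seed, run_index)."""
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    rng = substream(master_seed, "crw-sample", ensemble.source_tag_id, run_index)
    return ensemble.members[int(rng.integers(len(ensemble)))]


def ensemble_to_frame(ensemble: CRWEnsemble) -> pd.DataFrame:
    """Serialize an ensemble to the track CSV schema + source/index columns."""
    frames = []
    for idx, m in enumerate(ensemble.members):
        d = m.df.copy()
        d.insert(0, "crw_index", idx)
        d.insert(0, "source_tag_id", ensemble.source_tag_id)
        frames.append(d)
    return pd.concat(frames, ignore_index=True)
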