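"""End-to-end pipeline: simulate → occupancy → CRWs → spawning labels →
model fitting/CV/ensemble → weekly surfaces → oil overlap → movement scales.

Every stage draws randomness from named substreams of one master seed, so a
re-run with the same configuration reproduces all outputs.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import habitat, overlap, scales, spawning, surfaces, synthetic
from ._seeding import substream
from .crw import build_ensemble
from .gam import ModelSpec
from .tracks import (
    detect_gom_occupancy,
    write_dive_series,
    write_tracks,
)


@dataclass
class RunConfig:
    """Run-level constants and stage parameters.

    Defaults mirror the published analysis protocol: 100 CRWs per track,
    60 model runs, 0.25° weekly prediction over 2010-04-01..2010-08-26,
    Gulf entry at 80.5° W held for 6 days.
    """

    master_seed: int = 0
    output_dir: str = "run_output"
    # synthetic study conditions
    n_fish: int = 6
    n_days: int = 60
    entry_years: tuple[int, ...] = (2008, 2009, 2010)
    entry_month_day: str = "04-01"
    preference: dict = field(
        default_factory=lambda: {"sst": [24.0, 1.5]}
    )
    preference_strength: float = 4.5
    # analysis constants
    n_crw: int = 100
    n_runs: int = 60
    cv_k: int = 5
    cutoff_max_fpr: float = 0.05
    grid_resolution: float = 0.25
    prediction_start: str = "2010-04-01"
    prediction_end: str = "2010-08-26"
    candidate_models: dict = field(
        default_factory=lambda: {k: list(v) for k, v in habitat.DEFAULT_CANDIDATES.items()}
    )
    scale_radii_km: tuple[float, ...] = (25.0, 50.0, 75.0, 100.0, 150.0, 200.0)

    def __post_init__(self) -> None:
        self.entry_years = tuple(self.entry_years)
        self.scale_radii_km = tuple(float(r) for r in self.scale_radii_km)
        if self.n_crw < 1 or self.n_runs < 1 or self.n_fish < 0:
            raise ValueError("counts must be >= 1 (n_fish >= 0)")
        if pd.Timestamp(self.prediction_start) >= pd.Timestamp(self.prediction_end):
            raise ValueError("prediction window start must precede end")
        if self.grid_resolution <= 0:
            raise ValueError("grid resolution must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh)


def demo_config(output_dir: str = "run_output", master_seed: int = 0) -> RunConfig:
    """Small, fast configuration exercising every pipeline stage."""
    return RunConfig(
        master_seed=master_seed,
        output_dir=output_dir,
        n_fish=6,
        n_days=50,
        n_crw=15,
        n_runs=5,
        cv_k=3,
        scale_radii_km=(50.0, 100.0, 200.0),
    )


class _StageLogger:
    def __init__(self, path: Path, master_seed: int):
        self.path = path
        self.master_seed = master_seed
        self.path.write_text("")

    def stage(self, name: str):
        logger = self

        class _Ctx:
            def __enter__(ctx):
                ctx.t0 = time.time()
                return ctx

            def __exit__(ctx, exc_type, exc, tb):
                rec = {
                    "stage": name,
                    "seed": logger.master_seed,
                    "duration_s": round(time.time() - ctx.t0, 3),
                    "ok": exc_type is None,
                }
                if exc_type is not None:
                    rec["error"] = f"{exc_type.__name__}: {exc}"
                with open(logger.path, "a") as fh:
                    fh.write(json.dumps(rec) + "\n")
                return False

        return _Ctx()


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""


def _weekly_dates(start, end) -> pd.DatetimeIndex:
    return pd.date_range(pd.Timestamp(start), pd.Timestamp(end), freq="7D")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns a dict of the principal in-memory results.

    Writes inputs and outputs under ``config.output_dir``:
    ``inputs/`` (tracks.csv, dives.csv, env.nc, oil.geojson, eez.geojson),
    ``fits.json``, ``surfaces.nc``, ``overlap.csv``, ``scales.csv``,
    ``spawning_labels.csv``, ``log.jsonl``.
    """
    out = Path(config.output_dir)
    (out / "inputs").mkdir(parents=True, exist_ok=True)
    log = _StageLogger(out / "log.jsonl", config.master_seed)
    seed = config.master_seed
    results: dict = {}

    try:
        with log.stage("simulate"):
            env_dates = pd.DatetimeIndex(
                sorted(
                    set().union(
                        *[
                            _weekly_dates(f"{y}-03-01", f"{y}-09-15")
                            for y in config.entry_years
                        ]
                    )
                )
            )
            env = synthetic.gen_env_fields(
                dates=env_dates,
                params=synthetic.EnvFieldParams(resolution=config.grid_resolution),
                seed=seed,
            )
            pref = synthetic.PreferenceSpec(
                responses={k: tuple(v) for k, v in config.preference.items()},
                strength=config.preference_strength,
            )
            years = list(config.entry_years)
            entry_dates = [
                pd.Timestamp(f"{years[i % len(years)]}-{config.entry_month_day}")
                for i in range(config.n_fish)
            ]
            tracks = synthetic.gen_tracks(
                config.n_fish,
                env,
                pref,
                entry_dates,
                seed=seed,
                params=synthetic.TrackGenParams(n_days=config.n_days),
            )
            scenario = synthetic.assign_spawning_windows(
                tracks, seed=seed, p_spawner=1.0, window_days=(5, 9)
            )
            dives = [synthetic.gen_dive_series(t, scenario, seed=seed) for t in tracks]
            oil_dates = _weekly_dates(config.prediction_start, config.prediction_end)
            oil = synthetic.gen_oil_extent(oil_dates, seed=seed)
            eez = synthetic.gen_eez_mask(env)
            write_tracks(tracks, out / "inputs" / "tracks.csv")
            write_dive_series(dives, out / "inputs" / "dives.csv")
            env.to_netcdf(out / "inputs" / "env.nc")
            synthetic.write_polygons_geojson(oil, out / "inputs" / "oil.geojson")
            synthetic.write_polygons_geojson(
                [(oil_dates[0], eez)], out / "inputs" / "eez.geojson"
            )
            results.update(env=env, tracks=tracks, scenario=scenario, oil=oil)

        with log.stage("occupancy"):
            occupancy = {t.tag_id: detect_gom_occupancy(t) for t in tracks}
            results["occupancy"] = occupancy

        with log.stage("crw"):
            ensembles = [
                build_ensemble(t, n=config.n_crw, seed=seed, water_mask=env)
                for t in tracks
            ]
            results["ensembles"] = ensembles

        with log.stage("spawn_detect"):
            proxy_frames = [
                spawning.compute_proxies(d, t, env) for d, t in zip(dives, tracks)
            ]
            proxies = pd.concat(proxy_frames, ignore_index=True)
            truth = np.array(
                [
                    int(scenario.is_spawning_day(r.tag_id, r.date))
                    for r in proxies.itertuples()
                ]
            )
            # train on the archival-like subset (half the fish), score all days
            train_tags = {t.tag_id for t in tracks[: max(2, config.n_fish // 2)]}
            train_mask = proxies["tag_id"].isin(train_tags).to_numpy()
            model = spawning.fit_proxy_model(
                proxies[train_mask], truth[train_mask]
            )
            labels = spawning.classify_days(proxies, model)
            labels["truth"] = truth
            labels.to_csv(out / "spawning_labels.csv", index=False)
            results["spawning_labels"] = labels
            results["spawning_model"] = model

        with log.stage("fit"):
            candidate_specs = [
                ModelSpec(name=name, terms=tuple(terms), response="presence")
                for name, terms in config.candidate_models.items()
                if name != "spawning"
            ]
            cache: dict = {}
            pseudo0 = [
                habitat.sample_pseudo_absence(e, 0, seed) for e in ensembles
            ]
            table0 = habitat.assemble_design(
                tracks, pseudo0, env, covariate_cache=cache
            )
            best, comparison = habitat.select_model(table0, candidate_specs)
            report = habitat.run_ensemble(
                tracks, ensembles, env, best.spec,
                n_runs=config.n_runs, master_seed=seed,
            )
            cv_random = habitat.cross_validate(
                table0, best.spec, mode="random_splits", k=config.cv_k, seed=seed
            )
            years_present = pd.to_datetime(table0["date"]).dt.year.nunique()
            cv_year = (
                habitat.cross_validate(table0, best.spec, mode="by_year")
                if years_present >= 2
                else None
            )
            spawn_terms = tuple(
                config.candidate_models.get(
                    "spawning", habitat.DEFAULT_CANDIDATES["spawning"]
                )
            )
            spawn_spec = ModelSpec(
                name="spawning", terms=spawn_terms, response="spawning"
            )
            spawn_table = habitat.assemble_design(
                tracks, None, env,
                labels=results["spawning_labels"],
                response="spawning", covariate_cache=cache,
            )
            spawn_fit = habitat.fit_gamm(spawn_table, spawn_spec)
            cv_spawn = habitat.cross_validate(
                spawn_table, spawn_spec, mode="random_splits",
                k=config.cv_k, seed=seed,
            )
            fits_json = {
                "comparison": comparison.to_dict(orient="records"),
                "best": best.to_dict(),
                "ensemble": report.to_dict(),
                "cv_random": cv_random,
                "cv_by_year": cv_year,
                "spawning": spawn_fit.to_dict(),
                "cv_spawning": cv_spawn,
            }
            (out / "fits.json").write_text(json.dumps(fits_json, indent=2))
            results.update(
                best=best, report=report, spawn_fit=spawn_fit,
                table0=table0, spawn_table=spawn_table, fits_json=fits_json,
            )

        with log.stage("predict"):
            hab_cut = surfaces.choose_cutoff_from_fit(
                best, table0, max_fpr=config.cutoff_max_fpr
            )
            spawn_cut = surfaces.choose_cutoff_from_fit(
                spawn_fit, spawn_table, max_fpr=config.cutoff_max_fpr
            )
            weeks = _weekly_dates(config.prediction_start, config.prediction_end)
            hab_grids, spawn_grids, prod_grids, prod_binaries = [], [], [], []
            for wk in weeks:
                h = surfaces.predict_surface(report.fits, env, wk, "habitat")
                s = surfaces.predict_surface(spawn_fit, env, wk, "spawning")
                prod, binary = surfaces.spawning_habitat_product(
                    h, s, threshold=hab_cut * spawn_cut
                )
                hab_grids.append(h)
                spawn_grids.append(s)
                prod_grids.append(prod)
                prod_binaries.append(binary)
            ds = surfaces.surfaces_to_dataset(prod_grids)
            enc = {"week": {"dtype": "float64", "units": "days since 2000-01-01"}}
            ds.to_netcdf(out / "surfaces.nc", engine="scipy", encoding=enc)
            meta = {
                "habitat_cutoff": hab_cut,
                "spawning_cutoff": spawn_cut,
                "product_cutoff": hab_cut * spawn_cut,
                "max_fpr": config.cutoff_max_fpr,
            }
            (out / "cutoffs.json").write_text(json.dumps(meta, indent=2))
            results.update(
                hab_grids=hab_grids, spawn_grids=spawn_grids,
                prod_binaries=prod_binaries, cutoffs=meta,
            )

        with log.stage("overlap"):
            eez_frac = overlap.rasterize_mask(
                eez, env.lons, env.lats, config.grid_resolution
            )
            rows = []
            for wk, binary in zip(weeks, prod_binaries):
                poly = overlap.nearest_oil_polygon(oil, wk + pd.Timedelta(days=3))
                oiled = overlap.rasterize_polygons(
                    poly, env.lons, env.lats, config.grid_resolution
                )
                rows.append(
                    overlap.overlap_metrics(
                        binary, oiled, env.lats, config.grid_resolution,
                        eez_mask=eez_frac, week=wk,
                    )
                )
            report_df = overlap.overlap_report(rows)
            report_df.to_csv(out / "overlap.csv", index=False)
            results["overlap"] = report_df
            results["cumulative_km2"] = overlap.cumulative_exposure(report_df)

        with log.stage("scales"):
            profile = scales.scale_summary(tracks, config.scale_radii_km)
            profile.to_frame().to_csv(out / "scales.csv", index=False)
            results["scale_profile"] = profile
    except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
        raise StageError(f"pipeline failed: {exc}") from exc

    return results
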