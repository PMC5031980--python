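"""End-to-end validation experiments on synthetic study conditions.

The study's real inputs are not public, so the pipeline is validated by
properties: CRW resampling fidelity, null calibration (no-preference tracks
must yield chance-level cross-validated discrimination), recovery of a known
thermal preference, spawning-detector skill against generator truth, overlap
arithmetic against independent oracles, closed-form geometry checks,
ensemble term-stability behaviour, and bit-level reproducibility of the
pipeline.  Both the test suite and the results script drive these functions.

Problem sizes are scaled-down study conditions: 12 fish with 180-day Gulf
residences for signal recovery (the tagging study held 66 fish with tracks
of 7-193 days), 6-8 fish elsewhere.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import crw, habitat, overlap, pipeline, scales, spawning, synthetic
from ._seeding import substream
from .gam import ModelSpec
from .geo import dead_reckon
from .tracks import Track

FULL_TERMS = habitat.DEFAULT_CANDIDATES["full"]


from contextlib import contextmanager


@contextmanager
def _quiet():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


# ---------------------------------------------------------------------------
# CRW fidelity
# ---------------------------------------------------------------------------

def make_synthetic_source(seed: int, n_days: int = 151) -> Track:
    """A free-swimming synthetic source track (gamma steps, von Mises turns)."""
    rng = substream(seed, "source-track")
    lon, lat = -90.0, 25.0
    heading = float(rng.uniform(-np.pi, np.pi))
    lons, lats = [lon], [lat]
    for _ in range(n_days - 1):
        heading += float(rng.vonmises(0.0, 1.5))
        step = float(rng.gamma(2.0, 30.0))
        lon, lat = dead_reckon(lon, lat, heading, step)
        lons.append(lon)
        lats.append(lat)
    df = pd.DataFrame(
        {
            "date": pd.date_range("2010-04-01", periods=n_days, freq="D"),
            "lon": lons,
            "lat": lats,
            "error_radius_deg": np.exp(np.log(0.25) + 0.35 * rng.standard_normal(n_days)),
        }
    )
    return Track("src", df)


def crw_fidelity(seed: int, n_crw: int = 100) -> dict:
    """Pooled step-length KS vs the source and exact metadata preservation."""
    source = make_synthetic_source(seed)
    dist = crw.fit_step_distribution(source)
    ens = crw.build_ensemble(source, n=n_crw, seed=seed)
    pooled = np.concatenate(
        [crw.fit_step_distribution(m).step_lengths_km for m in ens.members]
    )
    ks = float(stats.ks_2samp(pooled, dist.step_lengths_km).statistic)
    dates_ok = all((m.dates == source.dates).all() for m in ens.members)
    radii_ok = all(
        np.array_equal(m.error_radii, source.error_radii) for m in ens.members
    )
    duration_ok = all(len(m) == len(source) for m in ens.members)
    return {
        "ks_statistic": ks,
        "n_crw": len(ens),
        "dates_preserved": bool(dates_ok),
        "radii_preserved": bool(radii_ok),
        "duration_preserved": bool(duration_ok),
    }


# ---------------------------------------------------------------------------
# Habitat model calibration and recovery
# ---------------------------------------------------------------------------

def _multi_year_dates(years=(2008, 2009, 2010)) -> pd.DatetimeIndex:
    return pd.DatetimeIndex(
        sorted(
            set().union(
                *[pd.date_range(f"{y}-03-01", f"{y}-09-15", freq="7D") for y in years]
            )
        )
    )


def null_calibration_auc(seed: int, n_fish: int = 6, n_days: int = 60) -> float:
    """By-year CV mean AUC for tracks with zero environmental preference."""
    with _quiet():
        years = (2008, 2009, 2010)
        env = synthetic.gen_env_fields(dates=_multi_year_dates(years), seed=seed)
        entries = [pd.Timestamp(f"{years[i % 3]}-04-01") for i in range(n_fish)]
        tracks = synthetic.gen_tracks(
            n_fish, env, synthetic.PreferenceSpec(strength=0.0), entries, seed=seed,
            params=synthetic.TrackGenParams(n_days=n_days),
        )
        ens = [crw.build_ensemble(t, n=5, seed=seed + 1, water_mask=env) for t in tracks]
        pseudo = [crw.sample_pseudo_absence(e, 0, seed + 2) for e in ens]
        table = habitat.assemble_design(tracks, pseudo, env)
        spec = ModelSpec("full", FULL_TERMS)
        cv = habitat.cross_validate(table, spec, mode="by_year")
    return float(cv["mean_auc"])


def signal_recovery(
    seed: int, n_fish: int = 12, n_days: int = 180, n_runs: int = 5
) -> dict:
    """Fit tracks with the canonical thermal preference; measure recovery.

    Returns the correlation between the ensemble-mean fitted SST partial
    effect and the true log selection weight over 18-30 degC, and the
    random-splits CV mean AUC.
    """
    with _quiet():
        dates = pd.date_range("2010-03-01", "2010-09-15", freq="7D")
        env = synthetic.gen_env_fields(dates=dates, seed=seed)
        pref = synthetic.default_preference()
        tracks = synthetic.gen_tracks(
            n_fish, env, pref, ["2010-04-01"] * n_fish, seed=seed,
            params=synthetic.TrackGenParams(n_days=n_days),
        )
        ens = [crw.build_ensemble(t, n=6, seed=seed + 1, water_mask=env) for t in tracks]
        spec = ModelSpec("sst_only", ("sst",))
        report = habitat.run_ensemble(
            tracks, ens, env, spec, n_runs=n_runs, master_seed=seed + 2
        )
        xs = np.linspace(18.0, 30.0, 50)
        partial = np.mean(
            [f.estimator.partial_effect("sst", xs) for f in report.fits], axis=0
        )
        corr = float(np.corrcoef(partial, pref.log_preference("sst", xs))[0, 1])
        pseudo = [crw.sample_pseudo_absence(e, 0, seed + 2) for e in ens]
        table = habitat.assemble_design(tracks, pseudo, env)
        cv = habitat.cross_validate(table, spec, mode="random_splits", k=3, seed=seed)
    return {"partial_effect_corr": corr, "cv_mean_auc": float(cv["mean_auc"])}


def ensemble_stability(
    seed: int, n_runs: int = 20, n_fish: int = 8, n_days: int = 120
) -> dict:
    """Term-significance fractions with a strong real effect + a noise term."""
    with _quiet():
        dates = pd.date_range("2010-03-01", "2010-09-15", freq="7D")
        env = synthetic.gen_env_fields(dates=dates, seed=seed)
        pref = synthetic.default_preference()
        tracks = synthetic.gen_tracks(
            n_fish, env, pref, ["2010-04-01"] * n_fish, seed=seed,
            params=synthetic.TrackGenParams(n_days=n_days),
        )
        ens = {
            t.tag_id: crw.build_ensemble(t, n=6, seed=seed + 1, water_mask=env)
            for t in tracks
        }
        cache: dict = {}
        spec = ModelSpec("with_noise", ("sst", "noise_cov"))
        sig_effect = sig_noise = 0
        for run in range(n_runs):
            pseudo = [
                crw.sample_pseudo_absence(ens[t.tag_id], run, seed + 2) for t in tracks
            ]
            table = habitat.assemble_design(
                tracks, pseudo, env, covariate_cache=cache
            )
            rng = substream(seed, "noise-cov", run)
            table["noise_cov"] = rng.standard_normal(len(table))
            fit = habitat.fit_gamm(table, spec)
            sig_effect += fit.pvalues["sst"] < 0.05
            sig_noise += fit.pvalues["noise_cov"] < 0.05
    return {
        "effect_significant_fraction": sig_effect / n_runs,
        "noise_significant_fraction": sig_noise / n_runs,
        "n_runs": n_runs,
    }


# ---------------------------------------------------------------------------
# Spawning detector
# ---------------------------------------------------------------------------

def spawning_detection_skill(seed: int, n_fish: int = 6, n_days: int = 60) -> dict:
    """Sensitivity/specificity vs generator truth on held-out fish.

    The detector is trained on labeled days from half the fish (the
    archival-validation analogue) and scored on the remaining fish.
    """
    with _quiet():
        dates = pd.date_range("2010-03-01", "2010-09-15", freq="7D")
        env = synthetic.gen_env_fields(dates=dates, seed=seed)
        tracks = synthetic.gen_tracks(
            n_fish, env, synthetic.default_preference(),
            ["2010-04-15"] * n_fish, seed=seed,
            params=synthetic.TrackGenParams(n_days=n_days),
        )
        scenario = synthetic.assign_spawning_windows(tracks, seed=seed, p_spawner=1.0)
        proxies = pd.concat(
            [
                spawning.compute_proxies(
                    synthetic.gen_dive_series(t, scenario, seed=seed), t, env
                )
                for t in tracks
            ],
            ignore_index=True,
        )
        truth = np.array(
            [
                int(scenario.is_spawning_day(r.tag_id, r.date))
                for r in proxies.itertuples()
            ]
        )
        train_tags = {t.tag_id for t in tracks[: n_fish // 2]}
        tr = proxies["tag_id"].isin(train_tags).to_numpy()
        model = spawning.fit_proxy_model(proxies[tr], truth[tr])
        labels = spawning.classify_days(proxies[~tr], model)["label"].to_numpy()
        y = truth[~tr]
        sens = float((labels[y == 1] == 1).mean())
        spec_ = float((labels[y == 0] == 0).mean())
        self_conc = spawning.concordance(labels, labels)
    return {
        "sensitivity": sens,
        "specificity": spec_,
        "self_concordance": self_conc,
        "n_eval_days": int((~tr).sum()),
        "n_spawning_days": int(y.sum()),
    }


def discrete_bayes_worked_case() -> dict:
    """8-day two-proxy discrete case vs a brute-force Bayes-rule oracle."""
    X = pd.DataFrame(
        {"p1": [0.0, 0.0, 1.0, 1.0, 0.0, 1.0, 1.0, 0.0],
         "p2": [2.0, 3.0, 2.0, 3.0, 3.0, 2.0, 3.0, 2.0]}
    )
    y = np.array([0, 0, 0, 0, 0, 1, 1, 1])
    model = spawning.ProxyNaiveBayes(density="categorical", min_per_class=3).fit(X, y)
    post = model.predict_proba(X)[:, 1]

    # independent enumeration of class-conditional frequencies
    prior = y.mean()
    oracle = []
    for _, row in X.iterrows():
        lik = {}
        for cls in (0, 1):
            sub = X[y == cls]
            p = 1.0
            for col in X.columns:
                p *= (sub[col] == row[col]).mean()
            lik[cls] = p
        denom = prior * lik[1] + (1 - prior) * lik[0]
        oracle.append(prior * lik[1] / denom if denom > 0 else prior)
    oracle = np.asarray(oracle)
    return {
        "max_abs_posterior_diff": float(np.max(np.abs(post - oracle))),
        "posteriors": post.tolist(),
    }


# ---------------------------------------------------------------------------
# Overlap and geometry oracles
# ---------------------------------------------------------------------------

def _subsample_fraction(poly, lons, lats, resolution, n=100) -> np.ndarray:
    """Point-in-polygon subsampling oracle for the rasterizer (n x n per cell)."""
    import shapely

    half = resolution / 2.0
    frac = np.zeros((len(lats), len(lons)))
    offs = (np.arange(n) + 0.5) / n
    minx, miny, maxx, maxy = poly.bounds
    for i, la in enumerate(lats):
        for j, lo in enumerate(lons):
            if lo + half < minx or lo - half > maxx or la + half < miny or la - half > maxy:
                continue
            xs = lo - half + offs * resolution
            ys = la - half + offs * resolution
            gx, gy = np.meshgrid(xs, ys)
            frac[i, j] = shapely.contains_xy(poly, gx.ravel(), gy.ravel()).mean()
    return frac


def rasterizer_vs_oracle(seed: int, n_polys: int = 3) -> dict:
    """Exact clipping vs 100x100 subsampling on random convex polygons."""
    from shapely.geometry import MultiPoint

    rng = substream(seed, "raster-oracle")
    res = 0.25
    lons = np.arange(-90.0 + res / 2, -86.0, res)
    lats = np.arange(24.0 + res / 2, 28.0, res)
    worst = 0.0
    for _ in range(n_polys):
        pts = np.column_stack(
            [rng.uniform(-89.5, -86.5, 12), rng.uniform(24.5, 27.5, 12)]
        )
        poly = MultiPoint(list(map(tuple, pts))).convex_hull
        exact = overlap.rasterize_polygons(poly, lons, lats, res)
        approx = _subsample_fraction(poly, lons, lats, res)
        rel = abs(exact.sum() - approx.sum()) / max(approx.sum(), 1e-12)
        worst = max(worst, float(rel))
    return {"max_relative_area_error": worst}


def overlap_conservation(seed: int) -> dict:
    """Conservation identity and the identical/disjoint exact cases."""
    rng = substream(seed, "overlap-cons")
    res = 0.25
    lats = np.arange(24.0 + res / 2, 28.0, res)
    lons = np.arange(-90.0 + res / 2, -86.0, res)
    hab = (rng.uniform(size=(len(lats), len(lons))) < 0.4).astype(float)
    oil = rng.uniform(size=hab.shape) * (rng.uniform(size=hab.shape) < 0.5)
    row = overlap.overlap_metrics(hab, oil, lats, res)
    conservation = abs(
        row.pct_habitat_oiled / 100.0 * row.habitat_km2 - row.oiled_habitat_km2
    )
    same = overlap.overlap_metrics(hab, hab, lats, res)
    disjoint = overlap.overlap_metrics(hab, 1.0 - hab, lats, res)
    # independent double-loop re-summation of the cumulative exposure
    areas = overlap.cell_area_rows(lats, res)
    rows = []
    brute = 0.0
    for wk in range(4):
        o = rng.uniform(size=hab.shape) * (rng.uniform(size=hab.shape) < 0.5)
        rows.append(overlap.overlap_metrics(hab, o, lats, res, week=f"2010-06-{wk+1:02d}"))
        for i in range(hab.shape[0]):
            for j in range(hab.shape[1]):
                brute += hab[i, j] * o[i, j] * areas[i]
    cum = overlap.cumulative_exposure(rows)
    return {
        "conservation_error_km2": float(conservation),
        "identical_pct": float(same.pct_habitat_oiled),
        "disjoint_pct": float(disjoint.pct_habitat_oiled),
        "cumulative_vs_bruteforce_km2": float(abs(cum - brute)),
    }


def geometry_checks() -> dict:
    """Closed-form spherical cell area and ballistic first-passage time."""
    R = 6371.0
    a = overlap.cell_area(0.0, 0.25, 0.25)
    closed = R**2 * np.radians(0.25) * (np.sin(np.radians(0.25)) - 0.0)
    lats = np.arange(-90.0, 90.0, 0.25)
    total = float(
        np.sum(
            [overlap.cell_area(la, la + 0.25, 0.25) * (360 / 0.25) for la in lats]
        )
    )
    sphere = 4.0 * np.pi * R**2
    # ballistic track: 100 km/day due east on the equator
    n = 21
    step_deg = 100.0 / (np.pi * R / 180.0)
    df = pd.DataFrame(
        {
            "date": pd.date_range("2010-04-01", periods=n, freq="D"),
            "lon": -90.0 + step_deg * np.arange(n),
            "lat": np.zeros(n),
            "error_radius_deg": np.zeros(n),
        }
    )
    fpt = scales.first_passage_time(Track("ballistic", df), 100.0)
    interior = fpt[5:-5]
    return {
        "equatorial_cell_area_km2": float(a),
        "cell_area_closed_form_diff": float(abs(a - closed)),
        "global_area_relative_error": float(abs(total - sphere) / sphere),
        "ballistic_fpt_days": float(np.nanmean(interior)),
        "ballistic_fpt_max_error_days": float(np.nanmax(np.abs(interior - 2.0))),
    }


# ---------------------------------------------------------------------------
# Pipeline reproducibility
# ---------------------------------------------------------------------------

def pipeline_reproducibility(seed: int, workdir) -> dict:
    """Run the demo pipeline twice with one master seed; diff the reports."""
    workdir = Path(workdir)
    outputs = {}
    with _quiet():
        for run in ("a", "b"):
            cfg = pipeline.demo_config(
                output_dir=str(workdir / f"run_{run}"), master_seed=seed
            )
            pipeline.run_pipeline(cfg)
            outputs[run] = {
                name: (workdir / f"run_{run}" / name).read_text()
                for name in ("overlap.csv", "scales.csv", "fits.json")
            }
    identical = all(outputs["a"][k] == outputs["b"][k] for k in outputs["a"])
    overlap_df = pd.read_csv(workdir / "run_a" / "overlap.csv")
    return {
        "reports_identical": bool(identical),
        "cumulative_oiled_habitat_km2": float(
            overlap.cumulative_exposure(overlap_df)
        ),
        "weekly_pct_habitat_oiled_mean": float(
            overlap_df["pct_habitat_oiled"].mean()
        ),
        "weekly_pct_habitat_oiled_max": float(
            overlap_df["pct_habitat_oiled"].max()
        ),
    }
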