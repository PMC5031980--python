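"""Habitat and spawning model workflows.

Assembles presence/pseudo-absence (and spawning/non-spawning) model tables,
fits candidate GAMMs, selects among them by AUC (ties broken by AIC), runs
the CRW-resampling ensemble that quantifies pseudo-absence selection error,
and cross-validates by random stratified splits or by calendar year.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedShuffleSplit

from ._seeding import substream
from .crw import CRWEnsemble, sample_pseudo_absence
from .fields import EnvFieldStack
from .gam import BinomialGAMM, ModelFit, ModelSpec
from .tracks import Track, extract_covariates_track

#: Candidate term sets mirroring the published full / reduced / spawning models.
DEFAULT_CANDIDATES = {
    "full": ("sst", "log_eke", "ssha", "sst_sd", "ssha_sd", "bathy"),
    "reduced": ("sst", "ssha", "log_eke"),
    "spawning": ("sst", "ssha", "log_chl", "uy10", "bathy", "bathy_sd", "moon"),
}


def assemble_design(
    tracks: list[Track],
    pseudo: list[Track] | None,
    env: EnvFieldStack,
    labels: pd.DataFrame | None = None,
    response: str = "presence",
    covariate_cache: dict | None = None,
) -> pd.DataFrame:
    """Model table: one row per day and source, with covariates and response.

    ``response="presence"``: real-track days get response 1, each paired CRW's
    days response 0 (a CRW carries its source's tag_id, dates and radii).
    ``response="spawning"``: real-track days only, response = the day's
    spawning label joined from ``labels`` (columns tag_id, date, label).
    """

    def covs(track: Track, key) -> pd.DataFrame:
        if covariate_cache is not None and key in covariate_cache:
            return covariate_cache[key]
        out = extract_covariates_track(track, env)
        if covariate_cache is not None:
            covariate_cache[key] = out
        return out

    frames = []
    if response == "presence":
        if pseudo is None:
            raise ValueError("presence table needs pseudo-absence tracks")
        real_tags = {t.tag_id for t in tracks}
        for p in pseudo:
            if p.tag_id not in real_tags:
                raise ValueError(f"pseudo track {p.tag_id!r} has no paired real track")
        for t in tracks:
            d = covs(t, ("real", t.tag_id)).copy()
            d["response"] = 1
            frames.append(d)
        for i, p in enumerate(pseudo):
            d = covs(p, ("pseudo", p.tag_id, i)).copy()
            d["response"] = 0
            frames.append(d)
    elif response == "spawning":
        if labels is None:
            raise ValueError("spawning table needs labels")
        lab = labels.copy()
        lab["date"] = pd.to_datetime(lab["date"])
        for t in tracks:
            d = covs(t, ("real", t.tag_id)).merge(
                lab[["tag_id", "date", "label"]], on=["tag_id", "date"], how="inner"
            )
            d = d.rename(columns={"label": "response"})
            frames.append(d)
    else:
        raise ValueError(f"unknown response kind {response!r}")
    table = pd.concat(frames, ignore_index=True)
    return table


def fit_gamm(table: pd.DataFrame, spec: ModelSpec, **overrides) -> ModelFit:
    """Fit one candidate GAMM on a model table."""
    est = spec.make_estimator(**overrides)
    est.fit(table, table["response"].to_numpy(), groups=table["tag_id"].to_numpy())
    return ModelFit.from_estimator(spec, est)


def select_model(
    table: pd.DataFrame, candidate_specs: list[ModelSpec]
) -> tuple[ModelFit, pd.DataFrame]:
    """Rank candidates by AUC (descending), ties broken by lower AIC."""
    if not candidate_specs:
        raise ValueError("need at least one candidate spec")
    fits = [fit_gamm(table, s) for s in candidate_specs]
    comparison = pd.DataFrame(
        {
            "name": [f.spec.name for f in fits],
            "auc": [f.auc for f in fits],
            "aic": [f.aic for f in fits],
            "deviance_explained": [f.deviance_explained for f in fits],
        }
    ).sort_values(["auc", "aic"], ascending=[False, True], ignore_index=True)
    best_name = comparison["name"].iloc[0]
    best = next(f for f in fits if f.spec.name == best_name)
    return best, comparison


@dataclass
class TermStabilityReport:
    """Per-term significance fractions over the CRW-resampling ensemble."""

    term_fractions: dict[str, float]
    n_runs: int
    aucs: list[float]
    alpha: float = 0.05
    fits: list[ModelFit] = field(default_factory=list, repr=False)

    @property
    def estimators(self) -> list[BinomialGAMM]:
        return [f.estimator for f in self.fits]

    def to_dict(self) -> dict:
        return {
            "n_runs": self.n_runs,
            "alpha": self.alpha,
            "term_significance_fraction": {
                k: float(v) for k, v in self.term_fractions.items()
            },
            "auc_mean": float(np.mean(self.aucs)),
            "auc_sd": float(np.std(self.aucs)),
        }


def run_ensemble(
    tracks: list[Track],
    ensembles: list[CRWEnsemble],
    env: EnvFieldStack,
    spec: ModelSpec,
    n_runs: int = 60,
    master_seed: int = 0,
    alpha: float = 0.05,
) -> TermStabilityReport:
    """Refit the model ``n_runs`` times with freshly drawn CRWs per track.

    Each run draws one CRW per track (deterministically from the master
    seed), assembles the presence table and fits the spec; the report
    aggregates how often each smooth stayed significant and the AUC spread.
    The fitted models are retained for ensemble-mean prediction.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    by_tag = {e.source_tag_id: e for e in ensembles}
    missing = [t.tag_id for t in tracks if t.tag_id not in by_tag]
    if missing:
        raise ValueError(f"no CRW ensemble for tracks {missing}")
    cache: dict = {}
    sig_counts = {t: 0 for t in spec.terms}
    aucs = []
    fits = []
    for run in range(n_runs):
        pseudo = []
        for t in tracks:
            ens = by_tag[t.tag_id]
            rng = substream(master_seed, "crw-sample", t.tag_id, run)
            idx = int(rng.integers(len(ens)))
            member = ens.members[idx]
            # cache key by member identity so repeat draws reuse extraction
            cache_key = ("pseudo", t.tag_id, idx)
            if cache_key not in cache:
                cache[cache_key] = extract_covariates_track(member, env)
            pseudo.append((member, cache_key))
        frames = []
        for t in tracks:
            key = ("real", t.tag_id)
            if key not in cache:
                cache[key] = extract_covariates_track(t, env)
            d = cache[key].copy()
            d["response"] = 1
            frames.append(d)
        for member, key in pseudo:
            d = cache[key].copy()
            d["response"] = 0
            frames.append(d)
        table = pd.concat(frames, ignore_index=True)
        fit = fit_gamm(table, spec)
        for t in spec.terms:
            if fit.pvalues[t] < alpha:
                sig_counts[t] += 1
        aucs.append(fit.auc)
        fits.append(fit)
    fractions = {t: sig_counts[t] / n_runs for t in spec.terms}
    return TermStabilityReport(fractions, n_runs, aucs, alpha, fits)


def cross_validate(
    table: pd.DataFrame,
    spec: ModelSpec,
    mode: str = "random_splits",
    k: int = 5,
    seed: int = 0,
    test_size: float = 0.25,
) -> dict:
    """Held-out AUC by stratified random 75/25 splits or leave-one-year-out.

    Folds whose held-out rows contain a single class are skipped with a
    warning.  Returns {"fold_aucs", "mean_auc", "folds"}.
    """
    y = table["response"].to_numpy()
    groups = table["tag_id"].to_numpy()
    folds: list[tuple[np.ndarray, np.ndarray, object]] = []
    if mode == "random_splits":
        splitter = StratifiedShuffleSplit(
            n_splits=k, test_size=test_size, random_state=int(substream(seed, "cv").integers(2**31))
        )
        for i, (tr, te) in enumerate(splitter.split(np.zeros(len(y)), y)):
            folds.append((tr, te, f"split{i}"))
    elif mode == "by_year":
        years = pd.to_datetime(table["date"]).dt.year.to_numpy()
        uniq = np.unique(years)
        if uniq.size < 2:
            raise ValueError("by_year cross-validation needs >= 2 calendar years")
        for yr in uniq:
            te = np.where(years == yr)[0]
            tr = np.where(years != yr)[0]
            folds.append((tr, te, int(yr)))
    else:
        raise ValueError(f"unknown cv mode {mode!r}")

    fold_aucs = []
    fold_ids = []
    for tr, te, label in folds:
        if np.unique(y[te]).size < 2 or np.unique(y[tr]).size < 2:
            warnings.warn(f"fold {label}: single-class fold skipped")
            continue
        est = spec.make_estimator()
        est.fit(table.iloc[tr], y[tr], groups=groups[tr])
        scores = est.predict_proba(table.iloc[te])[:, 1]
        fold_aucs.append(float(roc_auc_score(y[te], scores)))
        fold_ids.append(label)
    return {
        "fold_aucs": fold_aucs,
        "mean_auc": float(np.mean(fold_aucs)) if fold_aucs else float("nan"),
        "folds": fold_ids,
        "mode": mode,
    }
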