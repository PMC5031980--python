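"""Spawning-day detection from dive telemetry.

Bluefin spawning on the Gulf grounds has a telemetry signature: repeated
shallow depth oscillations at night with elevated internal (visceral)
temperature.  Each Gulf day is summarized by ten daily "proxy" statistics
(night oscillation count, median night depth, internal-external temperature
excess at night, seasonal/lunar covariates, ...), and days are classified
spawning vs non-spawning with a two-class naive-Bayes model over per-class,
per-proxy one-dimensional densities.  The combination is tolerant of single
false detections and only requires each proxy's values to be *concentrated*
somewhere along its axis on spawning days, not monotonically high or low.

Days are classified independently; no temporal state model is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.base import BaseEstimator, ClassifierMixin

from .astro import moon_fraction, sun_altitude
from .fields import EnvFieldStack
from .geo import gc_distance_km
from .tracks import DiveSeries, Track

#: Default proxy set, reconstructed from the behavioral description of
#: spawning-associated diving; configuration-driven, any proxy replaceable.
PROXY_NAMES = (
    "osc_cycles",        # night oscillation-cycle count
    "night_depth_med",   # median night depth, m
    "max_depth",         # daily maximum depth, m
    "night_temp_excess", # median night internal - external temperature, degC
    "sst",               # surface temperature at the day's position, degC
    "doy",               # day of year
    "moon",              # lunar illumination fraction
    "bathy",             # bathymetry at the day's position, m
    "displacement_km",   # daily great-circle displacement, km
    "osc_period_min",    # dominant night oscillation period, min
)

#: Minimum peak-to-trough excursion for a counted oscillation cycle, m.
OSC_MIN_AMPLITUDE_M = 5.0
#: Rolling-median detrending window for oscillation counting, minutes.
OSC_DETREND_WINDOW_MIN = 40.0


def count_night_oscillations(
    depth: np.ndarray,
    interval_s: float,
    min_amplitude: float = OSC_MIN_AMPLITUDE_M,
    window_min: float = OSC_DETREND_WINDOW_MIN,
) -> tuple[int, float]:
    """Count oscillation cycles in a night depth segment.

    The segment is detrended by its rolling median; cycles are descending
    zero-crossings (depth passing from above to below the local median,
    i.e. the start of a downward excursion) whose surrounding excursion has
    peak-to-trough amplitude >= ``min_amplitude``.  Returns (count, median
    inter-cycle period in minutes; NaN if < 2 cycles).
    """
    depth = np.asarray(depth, dtype=float)
    if depth.size < 5:
        return 0, float("nan")
    win = max(3, int(round(window_min * 60.0 / interval_s)) | 1)
    med = (
        pd.Series(depth).rolling(win, center=True, min_periods=1).median().to_numpy()
    )
    resid = depth - med
    sign = np.sign(resid)
    # descending crossing: residual goes negative (shallower) -> positive (deeper)
    crossings = np.where((sign[:-1] <= 0) & (sign[1:] > 0))[0]
    counted = []
    for k, c in enumerate(crossings):
        # cycle amplitude measured on the raw depth between adjacent crossings
        lo = crossings[k - 1] if k > 0 else 0
        hi = crossings[k + 1] if k + 1 < len(crossings) else len(depth) - 1
        seg = depth[lo: hi + 1]
        if seg.size and (seg.max() - seg.min()) >= min_amplitude:
            counted.append(c)
    if len(counted) >= 2:
        period = float(np.median(np.diff(counted)) * interval_s / 60.0)
    else:
        period = float("nan")
    return len(counted), period


def compute_proxies(
    dive: DiveSeries, track: Track, env: EnvFieldStack | None = None
) -> pd.DataFrame:
    """Daily proxy vectors for every track day covered by the dive record.

    Night is defined as sun altitude < 0 at the day's position (the same
    definition the dive generator uses).  Proxies that need night samples
    are missing (NaN) on days without any.
    """
    d = dive.df
    days = d["timestamp_utc"].dt.normalize()
    track_dates = track.dates.normalize()
    if not days.isin(track_dates).any():
        raise ValueError("dive series and track do not overlap in time")
    if len(d) > 1:
        interval_s = float(
            (d["timestamp_utc"].iloc[1] - d["timestamp_utc"].iloc[0]).total_seconds()
        )
    else:
        interval_s = 120.0
    disp = np.full(len(track), np.nan)
    if len(track) > 1:
        step = gc_distance_km(
            track.lons[:-1], track.lats[:-1], track.lons[1:], track.lats[1:]
        )
        disp[:-1] = step
        disp[-1] = step[-1]
    rows = []
    by_day = dict(tuple(d.groupby(days)))
    for i, date in enumerate(track_dates):
        if date not in by_day:
            continue
        sub = by_day[date]
        lon, lat = float(track.lons[i]), float(track.lats[i])
        night = sun_altitude(lon, lat, sub["timestamp_utc"]) < 0.0
        depth = sub["depth_m"].to_numpy(dtype=float)
        row = {
            "tag_id": track.tag_id,
            "date": date,
            "max_depth": float(depth.max()),
            "doy": float(date.dayofyear),
            "moon": moon_fraction(date),
            "displacement_km": float(disp[i]),
            "sst": (
                env.value_at("sst", lon, lat, date)
                if env is not None and env.in_domain(lon, lat)
                else float(
                    np.median(sub["external_temp_c"].to_numpy()[depth < 5.0])
                )
                if (depth < 5.0).any()
                else np.nan
            ),
            "bathy": (
                env.value_at("bathy", lon, lat)
                if env is not None and env.in_domain(lon, lat)
                else np.nan
            ),
        }
        if night.any():
            nd = depth[night]
            cycles, period = count_night_oscillations(nd, interval_s)
            excess = (
                sub["internal_temp_c"].to_numpy()[night]
                - sub["external_temp_c"].to_numpy()[night]
            )
            row.update(
                osc_cycles=float(cycles),
                osc_period_min=period,
                night_depth_med=float(np.median(nd)),
                night_temp_excess=float(np.median(excess)),
            )
        else:
            row.update(
                osc_cycles=np.nan,
                osc_period_min=np.nan,
                night_depth_med=np.nan,
                night_temp_excess=np.nan,
            )
        rows.append(row)
    return pd.DataFrame(rows, columns=["tag_id", "date", *PROXY_NAMES])


# ---------------------------------------------------------------------------
# Naive-Bayes day classifier
# ---------------------------------------------------------------------------

class _KDEDensity:
    def __init__(self, values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if np.ptp(values) == 0:
            # degenerate sample: Gaussian at the common value, with a floor
            # bandwidth of 5% of its magnitude so neighbouring values are
            # not annihilated
            self.kind = "delta"
            self.loc = float(values[0])
            self.scale = max(1e-3, abs(self.loc) * 0.05)
        else:
            self.kind = "kde"
            self.kde = gaussian_kde(values, bw_method="silverman")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if self.kind == "delta":
            from scipy.stats import norm

            return norm.pdf(x, self.loc, self.scale)
        return self.kde(x)


class _GaussianDensity:
    def __init__(self, values: np.ndarray):
        values = np.asarray(values, dtype=float)
        self.loc = float(values.mean())
        self.scale = max(float(values.std(ddof=1)), 1e-9)

    def __call__(self, x):
        from scipy.stats import norm

        return norm.pdf(np.atleast_1d(np.asarray(x, float)), self.loc, self.scale)


class _CategoricalDensity:
    """Empirical frequencies over observed discrete values (no smoothing)."""

    def __init__(self, values: np.ndarray):
        vals, counts = np.unique(np.asarray(values, dtype=float), return_counts=True)
        self.freq = dict(zip(vals, counts / counts.sum()))

    def __call__(self, x):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        return np.array([self.freq.get(v, 0.0) for v in x])


_DENSITIES = {"kde": _KDEDensity, "gaussian": _GaussianDensity, "categorical": _CategoricalDensity}


class ProxyNaiveBayes(BaseEstimator, ClassifierMixin):
    """Two-class naive-Bayes over per-proxy one-dimensional densities.

    Parameters
    ----------
    density : {"kde", "gaussian", "categorical"}
        Per-class per-proxy density family.  KDE uses Silverman's bandwidth.
    prior : float or None
        Prior probability of the spawning class; None = empirical class rate.
    threshold : float
        Posterior cut for the spawning label.
    min_per_class : int
        Minimum labeled examples per class required to fit.

    Missing proxy values (NaN) are skipped both in fitting and in scoring
    (they contribute likelihood 1), so a day with all proxies missing scores
    the prior.
    """

    def __init__(
        self,
        density: str = "kde",
        prior: float | None = None,
        threshold: float = 0.5,
        min_per_class: int = 5,
    ):
        self.density = density
        self.prior = prior
        self.threshold = threshold
        self.min_per_class = min_per_class

    def fit(self, X, y):
        X = self._as_frame(X)
        y = np.asarray(y).astype(int)
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("labels must be binary 0/1 (1 = spawning)")
        for cls in (0, 1):
            if (y == cls).sum() < self.min_per_class:
                raise ValueError(
                    f"class {cls} has {(y == cls).sum()} examples; "
                    f"need >= {self.min_per_class}"
                )
        family = _DENSITIES[self.density]
        self.feature_names_ = list(X.columns)
        self.densities_ = {0: {}, 1: {}}
        for cls in (0, 1):
            sub = X[y == cls]
            for col in X.columns:
                vals = sub[col].dropna().to_numpy(dtype=float)
                if vals.size >= 2:
                    self.densities_[cls][col] = family(vals)
        if self.prior is None:
            self.prior_ = float((y == 1).mean())
        else:
            if not 0.0 < self.prior < 1.0:
                raise ValueError("prior must be in (0, 1)")
            self.prior_ = float(self.prior)
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        X = self._as_frame(X)
        n = len(X)
        log_lik = {0: np.zeros(n), 1: np.zeros(n)}
        defined = np.zeros(n, dtype=bool)
        for col in self.feature_names_:
            if col not in X.columns:
                continue
            if col not in self.densities_[0] or col not in self.densities_[1]:
                continue
            x = X[col].to_numpy(dtype=float)
            ok = np.isfinite(x)
            if not ok.any():
                continue
            for cls in (0, 1):
                dens = np.clip(self.densities_[cls][col](x[ok]), 0.0, None)
                with np.errstate(divide="ignore"):
                    log_lik[cls][ok] += np.log(dens)
            defined |= ok
        # log-space normalization: extreme class-conditional densities must
        # saturate the posterior, not underflow both classes to zero
        log1 = np.log(self.prior_) + log_lik[1]
        log0 = np.log(1.0 - self.prior_) + log_lik[0]
        m = np.maximum(log0, log1)
        both_zero = ~np.isfinite(m)
        m = np.where(both_zero, 0.0, m)
        with np.errstate(invalid="ignore"):
            e0 = np.exp(log0 - m)
            e1 = np.exp(log1 - m)
        e0 = np.nan_to_num(e0)
        e1 = np.nan_to_num(e1)
        post = np.where(both_zero, self.prior_, e1 / (e0 + e1))
        post = np.where(defined, post, self.prior_)
        return np.column_stack([1.0 - post, post])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= self.threshold).astype(int)

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            cols = [c for c in X.columns if c not in ("tag_id", "date")]
            return X[cols]
        return pd.DataFrame(np.asarray(X, dtype=float))


# -- module-level wrappers ---------------------------------------------------

def fit_proxy_model(
    proxies: pd.DataFrame, labels, prior: float | None = None, density: str = "kde"
) -> ProxyNaiveBayes:
    """Fit the spawning-day classifier on labeled proxy vectors."""
    return ProxyNaiveBayes(density=density, prior=prior).fit(proxies, labels)


def classify_days(
    proxies: pd.DataFrame, model: ProxyNaiveBayes, threshold: float | None = None
) -> pd.DataFrame:
    """Posterior spawning probability and label per day.

    Returns the proxy frame's (tag_id, date) keys (when present) with
    ``posterior`` and ``label`` columns (1 = spawning).
    """
    post = model.predict_proba(proxies)[:, 1]
    thr = model.threshold if threshold is None else threshold
    out = pd.DataFrame({"posterior": post, "label": (post >= thr).astype(int)})
    if isinstance(proxies, pd.DataFrame):
        for key in ("date", "tag_id"):
            if key in proxies.columns:
                out.insert(0, key, proxies[key].to_numpy())
    return out


def concordance(labels_a, labels_b) -> float:
    """Fraction of aligned days with identical labels."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError(f"label vectors differ in length: {a.shape} vs {b.shape}")
    if a.size == 0:
        warnings.warn("empty label vectors; concordance undefined, returning nan")
        return float("nan")
    return float((a == b).mean())
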