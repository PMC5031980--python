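"""Penalized-spline binomial GAMM.

The habitat and spawning models are binary-response generalized additive
mixed models: a logit link, penalized regression-spline smooths of the
oceanographic covariates, and a per-fish random intercept to absorb
correlation among a tag's daily observations.

The implementation is penalized IRLS (P-IRLS) on cubic P-splines with a
second-order difference penalty per smooth; the random intercept enters as a
block of per-tag indicator columns under a ridge penalty, which is exactly
the Gaussian-random-intercept working model.  Smoothing parameters (one per
smooth, one for the intercept block) are chosen by GCV on the converged
working linear model (performance iteration).  Reported per-smooth
significance uses a Wald-type chi-square test on the penalized coefficient
block with the block's effective degrees of freedom, AIC uses the total
effective degrees of freedom, and prediction for new fish sets the random
intercept to its population mean (zero on the link scale).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.interpolate import BSpline
from scipy.stats import chi2
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score


class DegenerateFitError(ValueError):
    """Single-class response or otherwise unfittable design."""


@dataclass
class _SmoothBasis:
    """Cubic B-spline basis for one covariate, centered for identifiability."""

    var: str
    knots: np.ndarray
    degree: int
    lo: float
    hi: float
    col_means: np.ndarray | None = None

    @classmethod
    def from_data(cls, var: str, x: np.ndarray, n_splines: int, degree: int = 3):
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi <= lo:
            hi = lo + 1e-6
        n_interior = n_splines - degree - 1
        interior = np.linspace(lo, hi, n_interior + 2)[1:-1] if n_interior > 0 else []
        knots = np.concatenate(
            [[lo] * (degree + 1), interior, [hi] * (degree + 1)]
        )
        b = cls(var, knots, degree, lo, hi)
        b.col_means = b._raw(x).mean(axis=0)
        return b

    def _raw(self, x: np.ndarray) -> np.ndarray:
        x = np.clip(np.asarray(x, dtype=float), self.lo, self.hi)
        return BSpline.design_matrix(
            x, self.knots, self.degree, extrapolate=False
        ).toarray()

    def design(self, x: np.ndarray) -> np.ndarray:
        return self._raw(x) - self.col_means

    @property
    def n_cols(self) -> int:
        return len(self.knots) - self.degree - 1

    def penalty(self) -> np.ndarray:
        k = self.n_cols
        D = np.diff(np.eye(k), n=2, axis=0)
        return D.T @ D


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -35.0, 35.0)))


def _binomial_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, 1e-10, 1 - 1e-10)
    return float(-2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


class BinomialGAMM(BaseEstimator, ClassifierMixin):
    """Logit-link GAMM: penalized spline smooths + per-group ridge intercepts.

    Parameters
    ----------
    terms : sequence of str
        Covariate columns that get a smooth.
    n_splines : int
        Basis dimension per smooth (default 5; the response shapes of
        interest are smooth and low-complexity).
    degree : int
        Spline degree (cubic default).
    random_intercept : bool
        Penalized per-group intercept block (the mixed-model part).
    select_penalty : bool
        Choose smoothing parameters by GCV performance iteration; if False,
        ``lam_default`` is used for every block.
    lam_default : float
        Initial / fixed smoothing parameter.
    alpha : float
        Significance level used by :attr:`significant_terms_`.

    Fitted attributes (trailing underscore): ``coef_``, ``cov_``,
    ``lambdas_``, ``edf_``, ``edf_by_term_``, ``aic_``, ``auc_``,
    ``pvalues_``, ``deviance_``, ``deviance_explained_``, ``classes_``.
    """

    def __init__(
        self,
        terms=("sst",),
        n_splines: int = 5,
        degree: int = 3,
        random_intercept: bool = True,
        select_penalty: bool = True,
        lam_default: float = 1.0,
        alpha: float = 0.05,
        max_iter: int = 80,
        tol: float = 1e-7,
    ):
        self.terms = terms
        self.n_splines = n_splines
        self.degree = degree
        self.random_intercept = random_intercept
        self.select_penalty = select_penalty
        self.lam_default = lam_default
        self.alpha = alpha
        self.max_iter = max_iter
        self.tol = tol

    # -- design assembly -------------------------------------------------
    def _build_design(self, X: pd.DataFrame, groups) -> np.ndarray:
        cols = [np.ones((len(X), 1))]
        for t in self.terms:
            cols.append(self.bases_[t].design(X[t].to_numpy(dtype=float)))
        if self.use_group_ and groups is not None:
            g = pd.Categorical(groups, categories=self.group_levels_)
            G = np.zeros((len(X), len(self.group_levels_)))
            codes = np.asarray(g.codes)
            ok = codes >= 0
            G[np.arange(len(X))[ok], codes[ok]] = 1.0
            cols.append(G)
        elif self.use_group_:
            cols.append(np.zeros((len(X), len(self.group_levels_))))
        return np.hstack(cols)

    def _penalty(self, log10_lams: np.ndarray) -> np.ndarray:
        p = self.n_coef_
        S = np.zeros((p, p))
        for i, t in enumerate(self.terms):
            sl = self.blocks_[t]
            S[sl, sl] = 10.0 ** log10_lams[i] * self.bases_[t].penalty()
        if self.use_group_:
            sl = self.blocks_["_group"]
            S[sl, sl] = 10.0 ** log10_lams[len(list(self.terms))] * np.eye(
                sl.stop - sl.start
            )
        return S

    # -- fitting ---------------------------------------------------------
    def fit(self, X, y, groups=None):
        X = self._frame(X)
        y = np.asarray(y, dtype=float).ravel()
        classes = np.unique(y)
        if classes.size < 2:
            raise DegenerateFitError("response contains a single class")
        if groups is None and "tag_id" in X.columns:
            groups = X["tag_id"].to_numpy()
        n = len(y)
        if n < 10 * len(list(self.terms)):
            warnings.warn("fewer than 10 rows per smooth term; fit may be unstable")

        self.bases_ = {
            t: _SmoothBasis.from_data(
                t, X[t].to_numpy(dtype=float), self.n_splines, self.degree
            )
            for t in self.terms
        }
        self.group_levels_ = (
            sorted(pd.unique(np.asarray(groups)))
            if (self.random_intercept and groups is not None)
            else []
        )
        self.use_group_ = bool(self.group_levels_)

        Xd = self._build_design(X, groups)
        self.n_coef_ = Xd.shape[1]
        self.blocks_ = {}
        pos = 1
        for t in self.terms:
            k = self.bases_[t].n_cols
            self.blocks_[t] = slice(pos, pos + k)
            pos += k
        if self.use_group_:
            self.blocks_["_group"] = slice(pos, pos + len(self.group_levels_))

        n_lams = len(list(self.terms)) + (1 if self.use_group_ else 0)
        log_lams = np.full(n_lams, np.log10(self.lam_default))

        beta, S = self._pirls(Xd, y, log_lams)
        if self.select_penalty:
            for _ in range(2):
                log_lams = self._select_lams(Xd, y, beta, log_lams)
                beta, S = self._pirls(Xd, y, log_lams, beta0=beta)
        if np.abs(beta).max() > 200.0:
            warnings.warn(
                "possible complete separation; refitting with extra regularization"
            )
            log_lams = log_lams + 2.0
            beta, S = self._pirls(Xd, y, log_lams)

        self.lambdas_ = 10.0**log_lams
        self.coef_ = beta
        eta = Xd @ beta
        mu = _sigmoid(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        A = (Xd * w[:, None]).T @ Xd
        H = A + S + 1e-8 * np.eye(self.n_coef_)
        Hinv = np.linalg.inv(H)
        F = Hinv @ A  # edf matrix
        self.cov_ = Hinv
        self.edf_ = float(np.trace(F))
        self.edf_by_term_ = {
            t: float(np.trace(F[self.blocks_[t], self.blocks_[t]]))
            for t in self.terms
        }
        if self.use_group_:
            self.edf_by_term_["_group"] = float(
                np.trace(F[self.blocks_["_group"], self.blocks_["_group"]])
            )
        self.deviance_ = _binomial_deviance(y, mu)
        null_mu = np.full(n, y.mean())
        self.null_deviance_ = _binomial_deviance(y, null_mu)
        self.deviance_explained_ = 1.0 - self.deviance_ / self.null_deviance_
        self.aic_ = self.deviance_ + 2.0 * self.edf_
        self.auc_ = float(roc_auc_score(y, mu))
        self.pvalues_ = {t: self._wald_p(t) for t in self.terms}
        self.classes_ = np.array([0, 1])
        return self

    def _pirls(self, Xd, y, log_lams, beta0=None):
        S = self._penalty(log_lams)
        ridge = 1e-8 * np.eye(self.n_coef_)
        beta = np.zeros(self.n_coef_) if beta0 is None else beta0.copy()
        dev = np.inf
        for _ in range(self.max_iter):
            eta = Xd @ beta
            mu = _sigmoid(eta)
            w = np.clip(mu * (1 - mu), 1e-10, None)
            z = eta + (y - mu) / w
            XtW = Xd.T * w
            beta_new = np.linalg.solve(XtW @ Xd + S + ridge, XtW @ z)
            dev_new = _binomial_deviance(y, _sigmoid(Xd @ beta_new)) + float(
                beta_new @ S @ beta_new
            )
            if not np.isfinite(dev_new):
                break
            beta = beta_new
            if abs(dev - dev_new) < self.tol * (abs(dev_new) + 1e-9):
                dev = dev_new
                break
            dev = dev_new
        return beta, S

    def _select_lams(self, Xd, y, beta, log_lams):
        """GCV on the working linear model at the current fit."""
        eta = Xd @ beta
        mu = _sigmoid(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        XtW = Xd.T * w
        A = XtW @ Xd
        b = XtW @ z
        wz2 = float(np.sum(w * z * z))
        n = len(y)
        ridge = 1e-8 * np.eye(self.n_coef_)

        def gcv(ll):
            S = self._penalty(np.asarray(ll))
            H = A + S + ridge
            try:
                Hinv = np.linalg.inv(H)
            except np.linalg.LinAlgError:
                return np.inf
            bb = Hinv @ b
            edf = float(np.trace(Hinv @ A))
            rss = wz2 - 2.0 * float(b @ bb) + float(bb @ A @ bb)
            denom = max(n - edf, 1.0)
            return n * max(rss, 1e-12) / denom**2

        res = optimize.minimize(
            gcv,
            log_lams,
            method="Nelder-Mead",
            options={"maxiter": 60 * len(log_lams), "xatol": 0.05, "fatol": 1e-10},
        )
        return np.clip(res.x, -4.0, 8.0)

    def _wald_p(self, term: str) -> float:
        sl = self.blocks_[term]
        beta = self.coef_[sl]
        V = self.cov_[sl, sl]
        Vinv = np.linalg.pinv(V, rcond=1e-10)
        stat = float(beta @ Vinv @ beta)
        df = max(1, int(round(self.edf_by_term_[term])))
        return float(chi2.sf(stat, df))

    # -- prediction ------------------------------------------------------
    def decision_function(self, X, groups=None) -> np.ndarray:
        """Linear predictor; unknown/absent groups get the population intercept."""
        X = self._frame(X)
        if groups is None:
            Xd = self._build_design(X, None)
        else:
            Xd = self._build_design(X, np.asarray(groups))
        return Xd @ self.coef_

    def predict_proba(self, X, groups=None) -> np.ndarray:
        p = _sigmoid(self.decision_function(X, groups))
        return np.column_stack([1 - p, p])

    def predict(self, X, groups=None) -> np.ndarray:
        return (self.predict_proba(X, groups)[:, 1] >= 0.5).astype(int)

    def partial_effect(self, term: str, x) -> np.ndarray:
        """Centered smooth contribution f_term(x) on the link scale."""
        return self.bases_[term].design(np.asarray(x, dtype=float)) @ self.coef_[
            self.blocks_[term]
        ]

    @property
    def significant_terms_(self) -> list[str]:
        return [t for t, p in self.pvalues_.items() if p < self.alpha]

    @staticmethod
    def _frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        return pd.DataFrame(np.asarray(X, dtype=float))


@dataclass
class ModelSpec:
    """Candidate model: response kind, smooth terms, basis size, grouping."""

    name: str
    terms: tuple[str, ...]
    response: str = "presence"  # or "spawning"
    n_splines: int = 5
    random_intercept: bool = True

    def make_estimator(self, **overrides) -> BinomialGAMM:
        kw = dict(
            terms=tuple(self.terms),
            n_splines=self.n_splines,
            random_intercept=self.random_intercept,
        )
        kw.update(overrides)
        return BinomialGAMM(**kw)


@dataclass
class ModelFit:
    """A fitted candidate with its selection statistics."""

    spec: ModelSpec
    estimator: BinomialGAMM = field(repr=False)
    aic: float = np.nan
    auc: float = np.nan
    deviance_explained: float = np.nan
    pvalues: dict = field(default_factory=dict)

    @classmethod
    def from_estimator(cls, spec: ModelSpec, est: BinomialGAMM) -> "ModelFit":
        return cls(
            spec=spec,
            estimator=est,
            aic=est.aic_,
            auc=est.auc_,
            deviance_explained=est.deviance_explained_,
            pvalues=dict(est.pvalues_),
        )

    def to_dict(self) -> dict:
        return {
            "name": self.spec.name,
            "response": self.spec.response,
            "terms": list(self.spec.terms),
            "aic": self.aic,
            "auc": self.auc,
            "deviance_explained": self.deviance_explained,
            "pvalues": {k: float(v) for k, v in self.pvalues.items()},
        }
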