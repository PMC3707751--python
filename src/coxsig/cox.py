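"""Cox proportional-hazards machinery.

The model is ``lambda(t | x) = lambda_0(t) * exp(x @ beta)`` with an
unspecified baseline hazard; ``beta`` is estimated by maximizing the log
partial likelihood ``l(beta)`` (Efron or Breslow convention for tied
event times). The L1-penalized variant maximizes
``l(beta) - lam * sum |beta_j|``, shrinking unimportant coefficients
exactly to zero, with the penalty weight chosen by cross-validated
partial likelihood.

Estimators follow scikit-learn conventions (``fit``/``predict``,
``get_params``, fitted attributes with trailing underscores); the
module-level functions ``fit_cox``, ``fit_cox_lasso``,
``select_lambda_cv`` etc. are thin wrappers over them returning plain
result records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from . import _cd, _newton
from ._survdata import check_covariates, check_survival, sort_survival

__all__ = [
    "CoxFit", "CVResult", "CoxPH", "CoxLasso", "CoxLassoCV",
    "cox_partial_loglik", "fit_cox", "fit_cox_lasso", "lambda_max",
    "default_lambda_grid", "select_lambda_cv", "kaplan_meier",
    "linear_predictor", "KaplanMeierEstimate",
]


# ---------------------------------------------------------------------------
# Result records
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    """Fitted proportional-hazards model.

    Hazard ratios are ``exp(coef)`` exactly; confidence intervals are
    ``exp(coef +- z * se)``. ``lam`` is 0 for unpenalized fits.
    ``diverged`` flags coefficients pinned at the +-15 cap (monotone
    likelihood).
    """

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    ties: str
    converged: bool
    diverged: np.ndarray
    lam: float = 0.0
    n: int = 0
    n_events: int = 0
    ci_level: float = 0.95

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def _z(self) -> float:
        return float(stats.norm.ppf(0.5 + self.ci_level / 2))

    @property
    def ci_low(self) -> np.ndarray:
        return np.exp(self.coef - self._z * self.se)

    @property
    def ci_high(self) -> np.ndarray:
        return np.exp(self.coef + self._z * self.se)

    @property
    def p_values(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = self.coef / self.se
        return 2 * stats.norm.sf(np.abs(z))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coef": self.coef, "se": self.se, "HR": self.hazard_ratios,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "p": self.p_values, "diverged": self.diverged,
        }, index=self.names)

    def to_dict(self) -> dict:
        s = self.summary()
        return {
            "ties": self.ties, "lambda": self.lam, "loglik": self.loglik,
            "converged": bool(self.converged), "n": self.n,
            "n_events": self.n_events,
            "coefficients": {k: {c: (None if pd.isna(v) else
                                     (bool(v) if c == "diverged" else float(v)))
                                 for c, v in row.items()}
                             for k, row in s.to_dict("index").items()},
        }


@dataclass
class CVResult:
    """Cross-validated partial-likelihood profile over a penalty grid."""

    grid: np.ndarray          # descending lambda values
    cv_loglik: np.ndarray     # one CV partial log-likelihood per grid point
    chosen: float             # grid value maximizing cv_loglik
    folds: np.ndarray         # fold assignment per row
    seed: int | None = None

    def __post_init__(self):
        assert len(self.grid) == len(self.cv_loglik)


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

def _prepare(X, y):
    Xmat, names = check_covariates(X)
    t, e = check_survival(y, len(Xmat))
    if e.sum() < 1:
        raise ValueError("no events in data")
    sd = Xmat.std(axis=0)
    if (sd == 0).any():
        j = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"constant covariate: {names[j]}")
    return Xmat, names, t, e


class CoxPH(BaseEstimator):
    """Unpenalized Cox model fitted by Newton-Raphson with step-halving.

    Parameters
    ----------
    ties : {"efron", "breslow"}
        Tied-event-time convention (Efron default, the survival-analysis
        standard for unpenalized fits).
    tol : convergence tolerance on the log-likelihood change.
    max_iter : Newton iteration cap.

    Attributes (after fit)
    ----------------------
    coef_, se_ : coefficient vector and Wald standard errors.
    loglik_ : log partial likelihood at the optimum.
    converged_, diverged_ : convergence flag; per-coefficient monotone-
        likelihood flags (|beta| pinned at 15).
    """

    def __init__(self, ties: str = "efron", tol: float = 1e-9,
                 max_iter: int = 50):
        self.ties = ties
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        if self.ties not in ("efron", "breslow"):
            raise ValueError(f"unknown ties convention {self.ties!r}")
        Xmat, names, t, e = _prepare(X, y)
        _, ts, es, Xs, first = sort_survival(t, e, Xmat)
        beta, se, ll, conv, div, info = _newton.newton_fit(
            Xs, ts, es, first, ties=self.ties, tol=self.tol,
            max_iter=self.max_iter)
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = len(names)
        self.coef_ = beta
        self.se_ = se
        self.loglik_ = ll
        self.converged_ = conv
        self.diverged_ = div
        self.information_ = info
        self.n_ = len(t)
        self.n_events_ = int(e.sum())
        return self

    def predict(self, X):
        """Linear predictor (risk score) ``X @ coef_``."""
        return linear_predictor(self.result_, X)

    def score(self, X, y):
        """Log partial likelihood of ``coef_`` on new data."""
        Xmat, _ = check_covariates(X)
        t, e = check_survival(y, len(Xmat))
        return cox_partial_loglik(self.coef_, Xmat, t, e, ties=self.ties)

    @property
    def result_(self) -> CoxFit:
        return CoxFit(list(self.feature_names_in_), self.coef_, self.se_,
                      self.loglik_, self.ties, self.converged_,
                      self.diverged_, lam=0.0, n=self.n_,
                      n_events=self.n_events_)


class CoxLasso(BaseEstimator):
    """L1-penalized Cox model fitted by cyclic coordinate descent.

    Maximizes ``l(beta) - alpha * sum |beta_j|`` (Breslow ties). With
    ``standardize=True`` covariates are scaled to unit variance before
    fitting and coefficients back-transformed; the default leaves
    log2-expression covariates on their common natural scale.
    """

    def __init__(self, alpha: float = 0.0, ties: str = "breslow",
                 standardize: bool = False, tol: float = 1e-7,
                 max_sweeps: int = 1000):
        self.alpha = alpha
        self.ties = ties
        self.standardize = standardize
        self.tol = tol
        self.max_sweeps = max_sweeps

    def fit(self, X, y):
        if self.ties != "breslow":
            raise ValueError("penalized fitting implements Breslow ties only")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        Xmat, names, t, e = _prepare(X, y)
        scale = Xmat.std(axis=0) if self.standardize else np.ones(Xmat.shape[1])
        _, ts, es, Xs, first = sort_survival(t, e, Xmat / scale)
        beta0 = np.zeros(Xmat.shape[1])
        beta, conv, sweeps = _cd.lasso_fit(Xs, es, first, float(self.alpha),
                                           beta0, self.tol, self.max_sweeps)
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = len(names)
        self.coef_ = beta / scale
        self.loglik_ = float(_cd.breslow_loglik(Xs @ beta, es, first))
        self.converged_ = bool(conv)
        self.diverged_ = np.abs(beta) >= _cd.BETA_CAP - 1e-10
        self.n_sweeps_ = int(sweeps)
        self.n_ = len(t)
        self.n_events_ = int(e.sum())
        if not conv:
            import warnings
            warnings.warn("coordinate descent did not converge "
                          f"within {self.max_sweeps} sweeps", RuntimeWarning)
        return self

    def predict(self, X):
        return linear_predictor(self.result_, X)

    @property
    def result_(self) -> CoxFit:
        return CoxFit(list(self.feature_names_in_), self.coef_,
                      np.full(len(self.coef_), np.nan), self.loglik_,
                      "breslow", self.converged_, self.diverged_,
                      lam=float(self.alpha), n=self.n_,
                      n_events=self.n_events_)


class CoxLassoCV(BaseEstimator):
    """Cox LASSO with the penalty chosen by k-fold cross-validated
    partial likelihood.

    Folds are stratified on the event indicator. The CV criterion per
    grid point is the Verweij-van Houwelingen cross-validated partial
    log-likelihood ``sum_k [l_full(beta_-k) - l_train_k(beta_-k)]``; the
    chosen penalty maximizes it. The final model is refit on all rows at
    the chosen penalty.
    """

    def __init__(self, cv: int = 10, n_alphas: int = 50,
                 alpha_min_ratio: float = 1e-3, alphas=None,
                 random_state: int | None = None, tol: float = 1e-7,
                 max_sweeps: int = 1000):
        self.cv = cv
        self.n_alphas = n_alphas
        self.alpha_min_ratio = alpha_min_ratio
        self.alphas = alphas
        self.random_state = random_state
        self.tol = tol
        self.max_sweeps = max_sweeps

    def _make_folds(self, e, rng):
        """Event-stratified fold assignment; 0 events in a fold triggers
        one re-draw, then an error."""
        n = len(e)
        folds = np.empty(n, dtype=np.int64)
        for attempt in range(2):
            for group in (np.flatnonzero(e == 1), np.flatnonzero(e == 0)):
                gs = rng.permutation(group)
                folds[gs] = np.arange(len(gs)) % self.cv
            counts = np.bincount(folds[e == 1], minlength=self.cv)
            if (counts > 0).all():
                return folds
        raise ValueError("a fold has zero events after stratification")

    def fit(self, X, y):
        if self.cv < 2:
            raise ValueError("cv must be >= 2")
        Xmat, names, t, e = _prepare(X, y)
        if self.alphas is not None:
            grid = np.sort(np.asarray(self.alphas, float))[::-1]
        else:
            lmax = lambda_max(Xmat, t, e)
            grid = default_lambda_grid(lmax, self.n_alphas,
                                       self.alpha_min_ratio)
        rng = np.random.default_rng(self.random_state)
        folds = self._make_folds(e, rng)

        _, ts_all, es_all, Xs_all, first_all = sort_survival(t, e, Xmat)
        cvll = np.zeros(len(grid))
        for k in range(self.cv):
            train = folds != k
            _, ts, es, Xs, first = sort_survival(t[train], e[train],
                                                 Xmat[train])
            betas, _ = _cd.lasso_path(Xs, es, first, grid, self.tol,
                                      self.max_sweeps)
            for gi in range(len(grid)):
                b = betas[gi]
                l_full = _cd.breslow_loglik(Xs_all @ b, es_all, first_all)
                l_train = _cd.breslow_loglik(Xs @ b, es, first)
                cvll[gi] += l_full - l_train
        best = int(np.argmax(cvll))
        self.cv_result_ = CVResult(grid, cvll, float(grid[best]), folds,
                                   self.random_state)
        self.alpha_ = float(grid[best])
        final = CoxLasso(alpha=self.alpha_, tol=self.tol,
                         max_sweeps=self.max_sweeps).fit(Xmat, (t, e))
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = len(names)
        self.coef_ = final.coef_
        self.loglik_ = final.loglik_
        self.converged_ = final.converged_
        self.diverged_ = final.diverged_
        self.n_ = final.n_
        self.n_events_ = final.n_events_
        return self

    def predict(self, X):
        return linear_predictor(self.result_, X)

    @property
    def result_(self) -> CoxFit:
        return CoxFit(list(self.feature_names_in_), self.coef_,
                      np.full(len(self.coef_), np.nan), self.loglik_,
                      "breslow", self.converged_, self.diverged_,
                      lam=self.alpha_, n=self.n_, n_events=self.n_events_)


# ---------------------------------------------------------------------------
# Functional interface
# ---------------------------------------------------------------------------

def cox_partial_loglik(beta, X, times, events, ties: str = "efron") -> float:
    """Cox log partial likelihood ``l(beta)`` under the named ties rule."""
    Xmat, _ = check_covariates(X)
    beta = np.asarray(beta, float)
    if beta.shape != (Xmat.shape[1],):
        raise ValueError("beta length does not match number of covariates")
    t, e = check_survival((times, events), len(Xmat))
    if e.sum() < 1:
        raise ValueError("no events in data")
    _, ts, es, Xs, first = sort_survival(t, e, Xmat)
    return float(_newton.loglik_derivs(beta, Xs, ts, es, first, ties,
                                       order=0))


def fit_cox(X, times, events, ties: str = "efron", **kwargs) -> CoxFit:
    """Newton-fitted Cox model with Wald inference; see :class:`CoxPH`."""
    return CoxPH(ties=ties, **kwargs).fit(X, (times, events)).result_


def fit_cox_lasso(X, times, events, lam: float, ties: str = "breslow",
                  **kwargs) -> CoxFit:
    """L1-penalized Cox fit at penalty ``lam``; see :class:`CoxLasso`."""
    return CoxLasso(alpha=lam, ties=ties, **kwargs).fit(
        X, (times, events)).result_


def lambda_max(X, times, events) -> float:
    """Smallest penalty at which every coefficient is exactly zero:
    the largest absolute component of the score vector at beta = 0."""
    Xmat, _ = check_covariates(X)
    t, e = check_survival((times, events), len(Xmat))
    _, ts, es, Xs, first = sort_survival(t, e, Xmat)
    return float(np.abs(_cd.score_at_zero(Xs, es, first)).max())


def default_lambda_grid(lam_max: float, n: int = 50,
                        min_ratio: float = 1e-3) -> np.ndarray:
    """Descending log-spaced grid from ``lam_max`` to ``lam_max*min_ratio``."""
    return np.geomspace(lam_max, lam_max * min_ratio, n)


def select_lambda_cv(X, times, events, k: int = 10, grid=None,
                     seed: int | None = None) -> CVResult:
    """Choose the L1 penalty by 10-fold cross-validated partial
    likelihood; see :class:`CoxLassoCV`."""
    est = CoxLassoCV(cv=k, alphas=grid, random_state=seed)
    est.fit(X, (times, events))
    return est.cv_result_


def linear_predictor(fit: CoxFit, X) -> np.ndarray:
    """Risk scores ``X @ coef`` for a fitted model (rank-invariant under
    constant covariate shifts)."""
    if isinstance(X, pd.DataFrame):
        missing = [c for c in fit.names if c not in X.columns]
        if missing:
            raise ValueError(f"X lacks fitted covariates: {missing}")
        Xmat = X[fit.names].to_numpy(float)
    else:
        Xmat = np.asarray(X, float)
        if Xmat.ndim == 1:
            Xmat = Xmat[:, None]
        if Xmat.shape[1] != len(fit.names):
            raise ValueError(
                f"X has {Xmat.shape[1]} columns, fit has {len(fit.names)}")
    return Xmat @ fit.coef


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class KaplanMeierEstimate:
    """Product-limit estimate of S(t): right-continuous steps at event
    times, S(0) = 1."""

    event_times: np.ndarray
    survival: np.ndarray

    def at(self, t) -> np.ndarray | float:
        """S(t), right-continuous."""
        t = np.asarray(t, float)
        if len(self.event_times) == 0:
            out = np.ones_like(t)
            return float(out) if out.ndim == 0 else out
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        out = np.where(idx >= 0, self.survival[np.clip(idx, 0, None)], 1.0)
        return float(out) if out.ndim == 0 else out


def kaplan_meier(times, events) -> KaplanMeierEstimate:
    """Kaplan-Meier product-limit estimator (delegates to lifelines)."""
    from lifelines import KaplanMeierFitter

    t, e = check_survival((times, events))
    if len(t) < 1:
        raise ValueError("empty data")
    if e.sum() == 0:
        return KaplanMeierEstimate(np.empty(0), np.empty(0))
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    sf = kmf.survival_function_["KM_estimate"]
    ev_times = np.unique(t[e == 1])
    surv = sf.loc[ev_times].to_numpy(float)
    return KaplanMeierEstimate(ev_times, surv)
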