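"""Univariate covariate/imputation model families.

Each family fits ``target | predictors`` by maximum likelihood, supports an
approximate-Bayes parameter draw (MLE plus a multivariate-normal perturbation
using the estimated covariance; the linear family additionally draws the
residual variance from its scaled inverse-chi-square), and exposes either
per-level probabilities (discrete families) or a density and sampler
(linear family).  A column of ones is prepended internally: pass predictor
matrices without an intercept.

The binary-logistic fit is an in-package IRLS Newton solver (it sits in the
innermost imputation loops); multinomial and proportional-odds families
delegate to statsmodels.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

__all__ = [
    "LogisticModel",
    "LinearModel",
    "MultinomialModel",
    "ProportionalOddsModel",
    "make_family",
    "CovariateModelSpec",
]


def _expit(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _add_intercept(X):
    X = np.atleast_2d(np.asarray(X, float))
    return np.column_stack([np.ones(X.shape[0]), X])


class LogisticModel:
    """Binary logistic regression via IRLS with optional ridge fallback."""

    def __init__(self, ridge_fallback: float = 1e-4):
        self.ridge_fallback = ridge_fallback

    def fit(self, X, y):
        Xd = _add_intercept(X)
        y = np.asarray(y, float)
        self.levels_ = np.array([0.0, 1.0])
        p = Xd.shape[1]
        beta = np.zeros(p)
        ridge = 0.0
        for attempt in range(2):
            beta = np.zeros(p)
            ok = True
            for _ in range(100):
                eta = Xd @ beta
                mu = _expit(eta)
                w = mu * (1 - mu)
                grad = Xd.T @ (y - mu) - ridge * beta
                hess = (Xd * w[:, None]).T @ Xd + ridge * np.eye(p)
                try:
                    step = np.linalg.solve(hess, grad)
                except np.linalg.LinAlgError:
                    ok = False
                    break
                beta = beta + step
                if np.abs(step).max() < 1e-10:
                    break
            if ok and np.abs(beta).max() < 30:
                break
            if attempt == 0:
                warnings.warn(
                    "separation in logistic fit: falling back to ridge penalty"
                )
                ridge = self.ridge_fallback
        eta = Xd @ beta
        w = _expit(eta) * (1 - _expit(eta))
        hess = (Xd * w[:, None]).T @ Xd + ridge * np.eye(p)
        self.coef_ = beta
        self.cov_ = np.linalg.inv(hess)
        return self

    def draw(self, rng: np.random.Generator):
        return rng.multivariate_normal(self.coef_, self.cov_)

    def probs(self, X, params=None) -> np.ndarray:
        """(n, 2) matrix of P(target = level | predictors)."""
        beta = self.coef_ if params is None else params
        p1 = _expit(_add_intercept(X) @ beta)
        return np.column_stack([1 - p1, p1])

    def sample(self, X, params, rng: np.random.Generator):
        return (rng.uniform(size=np.atleast_2d(X).shape[0]) < self.probs(X, params)[:, 1]).astype(float)


class LinearModel:
    """Gaussian linear regression with the standard Bayesian parameter draw."""

    def fit(self, X, y):
        Xd = _add_intercept(X)
        y = np.asarray(y, float)
        n, p = Xd.shape
        beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
        resid = y - Xd @ beta
        dof = max(n - p, 1)
        sigma2 = float(resid @ resid) / dof
        self.coef_ = beta
        self.sigma2_ = sigma2
        self.dof_ = dof
        self.xtx_inv_ = np.linalg.inv(Xd.T @ Xd)
        self.cov_ = sigma2 * self.xtx_inv_
        return self

    def draw(self, rng: np.random.Generator):
        """(beta*, sigma2*) with sigma2* ~ dof*s2/chi2_dof, beta*|sigma2* normal."""
        sigma2 = self.dof_ * self.sigma2_ / rng.chisquare(self.dof_)
        beta = rng.multivariate_normal(self.coef_, sigma2 * self.xtx_inv_)
        return beta, sigma2

    def mean(self, X, params=None):
        beta = self.coef_ if params is None else params[0]
        return _add_intercept(X) @ beta

    def logpdf(self, values, X, params):
        beta, sigma2 = params
        mu = _add_intercept(X) @ beta
        return stats.norm.logpdf(np.asarray(values, float), mu, np.sqrt(sigma2))

    def sample(self, X, params, rng: np.random.Generator):
        beta, sigma2 = params
        mu = _add_intercept(X) @ beta
        return mu + rng.normal(scale=np.sqrt(sigma2), size=mu.shape)


class MultinomialModel:
    """Nominal categorical target via statsmodels MNLogit."""

    def fit(self, X, y):
        import statsmodels.api as sm

        y = np.asarray(y)
        self.levels_ = np.unique(y)
        Xd = _add_intercept(X)
        codes = np.searchsorted(self.levels_, y)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MNLogit(codes, Xd).fit(disp=0, maxiter=200)
        self.coef_ = np.asarray(res.params)  # (p, K-1)
        self.cov_ = np.asarray(res.cov_params())
        self._shape = self.coef_.shape
        return self

    def draw(self, rng: np.random.Generator):
        flat = rng.multivariate_normal(self.coef_.ravel(order="F"), self.cov_)
        return flat.reshape(self._shape, order="F")

    def probs(self, X, params=None) -> np.ndarray:
        beta = self.coef_ if params is None else params
        eta = _add_intercept(X) @ beta  # (n, K-1)
        full = np.column_stack([np.zeros(eta.shape[0]), eta])
        full -= full.max(axis=1, keepdims=True)
        ex = np.exp(full)
        return ex / ex.sum(axis=1, keepdims=True)

    def sample(self, X, params, rng: np.random.Generator):
        pr = self.probs(X, params)
        u = rng.uniform(size=pr.shape[0])[:, None]
        idx = (pr.cumsum(axis=1) < u).sum(axis=1)
        return self.levels_[idx]


class ProportionalOddsModel:
    """Ordered categorical target via statsmodels OrderedModel (logit link)."""

    def fit(self, X, y):
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        y = np.asarray(y)
        self.levels_ = np.unique(y)
        Xd = np.atleast_2d(np.asarray(X, float))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = OrderedModel(
                np.searchsorted(self.levels_, y), Xd, distr="logit"
            ).fit(disp=0, method="bfgs", maxiter=500)
        self._res = res
        self.coef_ = np.asarray(res.params)
        self.cov_ = np.asarray(res.cov_params())
        self._k = Xd.shape[1]
        return self

    def draw(self, rng: np.random.Generator):
        return rng.multivariate_normal(self.coef_, self.cov_)

    def probs(self, X, params=None) -> np.ndarray:
        params = self.coef_ if params is None else params
        Xd = np.atleast_2d(np.asarray(X, float))
        beta = params[: self._k]
        # statsmodels parametrizes thresholds as (t0, log-increments)
        raw = params[self._k:]
        thresh = np.concatenate([[raw[0]], raw[0] + np.cumsum(np.exp(raw[1:]))])
        eta = Xd @ beta
        cdf = _expit(thresh[None, :] - eta[:, None])
        cdf = np.column_stack([np.zeros(len(eta)), cdf, np.ones(len(eta))])
        return np.diff(cdf, axis=1)

    def sample(self, X, params, rng: np.random.Generator):
        pr = self.probs(X, params)
        u = rng.uniform(size=pr.shape[0])[:, None]
        idx = (pr.cumsum(axis=1) < u).sum(axis=1)
        return self.levels_[idx]


_FAMILIES = {
    "logistic": LogisticModel,
    "linear": LinearModel,
    "multinomial": MultinomialModel,
    "proportional_odds": ProportionalOddsModel,
}


def make_family(name: str):
    try:
        return _FAMILIES[name]()
    except KeyError:
        raise ValueError(
            f"unknown family {name!r}; choose from {sorted(_FAMILIES)}"
        ) from None


class CovariateModelSpec:
    """Model f(X_j | X_-j, Z) for one partially observed covariate.

    Parameters
    ----------
    target : str
        Column to impute.
    family : str
        'logistic', 'linear', 'multinomial' or 'proportional_odds'.
    predictors : list of str
        Covariate columns only — substantive-model-compatible imputation
        conditions on the outcome through the substantive likelihood, so
        outcome variables must not appear here.
    """

    _OUTCOME_COLS = {"time", "status", "v", "ev1", "h1_T", "h2_T", "l1_v"}

    def __init__(self, target: str, family: str, predictors: list[str]):
        if family not in _FAMILIES:
            raise ValueError(f"unknown family {family!r}")
        bad = set(predictors) & self._OUTCOME_COLS
        if bad:
            raise ValueError(
                f"outcome variables {sorted(bad)} may not be covariate-model "
                "predictors; compatibility comes through the substantive likelihood"
            )
        self.target = target
        self.family = family
        self.predictors = list(predictors)

    def make(self):
        return make_family(self.family)
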