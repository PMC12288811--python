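"""Semiparametric proportional hazards estimation with Breslow baseline.

The same machinery serves three roles in the package:

* the Fine-Gray substantive model, fitted as a standard Cox model on the
  subdistribution time V with event indicator I(D=1) (valid on
  censoring-complete data);
* cause-specific Cox models (one per competing event);
* a Cox model for the censoring process when censoring depends on continuous
  fully observed covariates.

Breslow tie handling is used both for fitting and for the baseline cumulative
hazard, so the likelihood evaluated inside substantive-model-compatible
imputation is exactly the quantity the fit maximizes.  The baseline refers to
covariates identically 0 (raw covariates, no internal centering).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .nonparametric import SurvivalSample, nelson_aalen
from .stepfun import StepFunction

__all__ = [
    "CoxPH",
    "ConvergenceError",
    "fit_ph",
    "draw_ph_parameters",
    "cif_from_ph",
    "cif_variance",
]


class ConvergenceError(RuntimeError):
    """Raised when Newton-Raphson fails (monotone likelihood / separation)."""

    def __init__(self, message: str, trace: list[float] | None = None):
        super().__init__(message)
        self.trace = trace or []


def _as_time_status(y):
    """Accept y as (time, status) tuple, (n, 2) array, or structured array."""
    if isinstance(y, tuple) and len(y) == 2:
        return np.asarray(y[0], float), np.asarray(y[1])
    arr = np.asarray(y)
    if arr.dtype.names:
        names = arr.dtype.names
        return arr[names[0]].astype(float), arr[names[1]]
    if arr.ndim == 2 and arr.shape[1] == 2:
        return arr[:, 0].astype(float), arr[:, 1]
    raise ValueError("y must be (time, status) or an (n, 2) array")


class CoxPH(BaseEstimator):
    """Cox proportional hazards model, Newton-Raphson with step-halving.

    Parameters
    ----------
    tol : float
        Convergence criterion on the change in partial log-likelihood.
    max_iter : int
        Maximum Newton iterations.
    keep_data : bool
        Retain the fitting sample (required by :meth:`draw_parameters`,
        which recomputes the Breslow baseline at a drawn coefficient vector).

    Attributes
    ----------
    coef_ : (p,) ndarray
        Partial-likelihood maximizer (Breslow ties).
    covariance_ : (p, p) ndarray
        Inverse observed information.
    baseline_cumhaz_ : StepFunction
        Breslow cumulative baseline hazard at covariates = 0.
    covariate_names_ : list of str
    n_events_ : int
    """

    def __init__(self, tol: float = 1e-9, max_iter: int = 100, keep_data: bool = True):
        self.tol = tol
        self.max_iter = max_iter
        self.keep_data = keep_data

    # -- internal likelihood machinery on the sorted sample ------------------

    @staticmethod
    def _prepare(time, status, X, weight):
        order = np.argsort(time, kind="stable")
        t = time[order]
        s = status[order].astype(float)
        Xs = X[order]
        w = weight[order]
        ev_mask = s > 0
        uniq_ev = np.unique(t[ev_mask])
        # first index in the sorted sample with time == each unique event time:
        # the suffix from there is the Breslow risk set (time >= t_j)
        first_idx = np.searchsorted(t, uniq_ev, side="left")
        # weighted event count per unique event time
        d = np.zeros(uniq_ev.size)
        pos = np.searchsorted(uniq_ev, t[ev_mask])
        np.add.at(d, pos, w[ev_mask])
        return t, s, Xs, w, ev_mask, uniq_ev, first_idx, d

    @staticmethod
    def _risk_sums(Xs, w, beta, first_idx, order=2, shift=True):
        """Suffix risk-set sums S0, S1, S2 evaluated at each event time.

        With ``shift=True`` the linear predictor is centered at its maximum to
        guard against overflow; the shift cancels in the score, information
        and (with the matching eta) the log-likelihood, but NOT in the raw
        sums — callers needing absolute S0/S1 (Breslow baseline, variance)
        must pass shift=False.
        """
        eta = Xs @ beta
        if shift and eta.size:
            eta = eta - eta.max()  # cancels in all ratios and in the loglik
        r = w * np.exp(eta)
        s0 = np.cumsum(r[::-1])[::-1]
        S0 = s0[first_idx]
        out = [S0]
        if order >= 1:
            rx = r[:, None] * Xs
            s1 = np.cumsum(rx[::-1], axis=0)[::-1]
            out.append(s1[first_idx])
        if order >= 2:
            rxx = rx[:, :, None] * Xs[:, None, :]
            s2 = np.cumsum(rxx[::-1], axis=0)[::-1]
            out.append(s2[first_idx])
        out.append(eta)
        return out

    def _loglik(self, beta, prep):
        t, s, Xs, w, ev_mask, uniq_ev, first_idx, d = prep
        S0, eta = self._risk_sums(Xs, w, beta, first_idx, order=0)
        return float(np.sum(w[ev_mask] * eta[ev_mask]) - np.sum(d * np.log(S0)))

    def fit(self, X, y, sample_weight=None):
        time, status = _as_time_status(y)
        col_names = list(X.columns) if hasattr(X, "columns") else None
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != time.size and X.shape[1] == time.size:
            X = X.T
        if X.size == 0:
            X = np.empty((time.size, 0))
        if X.shape[0] != time.size:
            raise ValueError("covariate row count must match sample size")
        if np.isnan(X).any():
            raise ValueError("missing covariate cells are not allowed in fit")
        w = (
            np.ones(time.size)
            if sample_weight is None
            else np.asarray(sample_weight, float)
        )
        sample = SurvivalSample(time, status, w)  # validates invariants
        p = X.shape[1]
        self.covariate_names_ = col_names or [f"x{j}" for j in range(p)]
        prep = self._prepare(sample.time, sample.status, X, sample.weight)
        t, s, Xs, w_s, ev_mask, uniq_ev, first_idx, d = prep
        self.n_events_ = int(round(float(d.sum())))
        if self.n_events_ == 0:
            raise ValueError("no events: proportional hazards fit undefined")

        beta = np.zeros(p)
        trace = [self._loglik(beta, prep)]
        if p > 0:
            if np.linalg.matrix_rank(Xs - Xs.mean(axis=0)) < p:
                raise ValueError("collinear covariates")
            for _ in range(self.max_iter):
                S0, S1, S2, eta = self._risk_sums(Xs, w_s, beta, first_idx)
                xbar = S1 / S0[:, None]
                score = np.sum(w_s[ev_mask, None] * Xs[ev_mask], axis=0) - d @ xbar
                info = np.einsum("j,jkl->kl", d / S0, S2) - np.einsum(
                    "j,jk,jl->kl", d, xbar, xbar
                )
                try:
                    step = np.linalg.solve(info, score)
                except np.linalg.LinAlgError as err:
                    raise ConvergenceError(
                        f"singular information matrix: {err}", trace
                    ) from err
                # step-halving until the likelihood does not decrease
                ll_old = trace[-1]
                frac = 1.0
                for _half in range(40):
                    cand = beta + frac * step
                    ll_new = self._loglik(cand, prep)
                    if ll_new >= ll_old - 1e-14:
                        break
                    frac /= 2.0
                beta = cand
                trace.append(ll_new)
                if abs(ll_new - ll_old) < self.tol:
                    break
            else:
                raise ConvergenceError(
                    "Newton-Raphson did not converge in "
                    f"{self.max_iter} iterations (possible separation); "
                    f"|beta| = {np.abs(beta).max():.3g}",
                    trace,
                )
            if np.abs(beta).max() > 50:
                raise ConvergenceError(
                    "divergent coefficients (monotone likelihood)", trace
                )
            S0, S1, S2, _ = self._risk_sums(Xs, w_s, beta, first_idx, shift=False)
            xbar = S1 / S0[:, None]
            info = np.einsum("j,jkl->kl", d / S0, S2) - np.einsum(
                "j,jk,jl->kl", d, xbar, xbar
            )
            self.covariance_ = np.linalg.inv(info)
        else:
            S0, _ = self._risk_sums(Xs, w_s, beta, first_idx, order=0, shift=False)
            S1 = np.empty((uniq_ev.size, 0))
            self.covariance_ = np.empty((0, 0))

        self.coef_ = beta
        self.loglik_ = trace[-1]
        self.n_iter_ = len(trace) - 1
        self._event_times = uniq_ev
        self._d = d
        self._S0 = S0
        self._S1 = S1 if p else np.empty((uniq_ev.size, 0))
        self.baseline_cumhaz_ = StepFunction(uniq_ev, np.cumsum(d / S0))
        if self.keep_data:
            self._fit_data = (sample.time, sample.status, X, sample.weight)
        return self

    # -- derived quantities --------------------------------------------------

    def breslow_baseline(self, coef: np.ndarray) -> StepFunction:
        """Breslow cumulative baseline hazard at an arbitrary coefficient vector."""
        if not hasattr(self, "_fit_data"):
            raise ValueError("fit with keep_data=True to recompute the baseline")
        time, status, X, w = self._fit_data
        prep = self._prepare(time, status, X, w)
        _, _, _, _, _, uniq_ev, first_idx, d = prep
        Xs = X[np.argsort(time, kind="stable")]
        ws = w[np.argsort(time, kind="stable")]
        eta = Xs @ np.asarray(coef, float)
        r = ws * np.exp(eta)
        S0 = np.cumsum(r[::-1])[::-1][first_idx]
        return StepFunction(uniq_ev, np.cumsum(d / S0))

    def draw_parameters(self, rng: np.random.Generator) -> "CoxPH":
        """Approximate posterior draw: beta* ~ N(coef_, covariance_).

        Returns a fitted copy with the drawn coefficients and the Breslow
        baseline recomputed at those coefficients on the retained sample.
        """
        cov = np.asarray(self.covariance_)
        p = self.coef_.size
        if p and cov.size:
            eigval = np.linalg.eigvalsh(cov)
            if eigval.min() < -1e-10 * max(eigval.max(), 1.0):
                warnings.warn("covariance not PSD; repairing by eigenvalue clipping")
                vals, vecs = np.linalg.eigh(cov)
                cov = (vecs * np.clip(vals, 0.0, None)) @ vecs.T
            draw = rng.multivariate_normal(self.coef_, cov, method="cholesky") \
                if np.all(np.linalg.eigvalsh(cov) > 0) else \
                rng.multivariate_normal(self.coef_, cov)
        else:
            draw = self.coef_.copy()
        new = CoxPH(tol=self.tol, max_iter=self.max_iter, keep_data=self.keep_data)
        new.coef_ = np.asarray(draw, float)
        new.covariance_ = self.covariance_
        new.covariate_names_ = list(self.covariate_names_)
        new.n_events_ = self.n_events_
        new.loglik_ = self.loglik_
        new._event_times = self._event_times
        new._d = self._d
        new._S0 = self._S0
        new._S1 = self._S1
        if hasattr(self, "_fit_data"):
            new._fit_data = self._fit_data
            new.baseline_cumhaz_ = self.breslow_baseline(new.coef_)
        else:
            new.baseline_cumhaz_ = self.baseline_cumhaz_
        return new

    def linear_predictor(self, X_row) -> np.ndarray | float:
        x = np.asarray(X_row, float)
        if x.ndim == 1 and x.size != self.coef_.size:
            raise ValueError("covariate dimension mismatch")
        if x.ndim == 2 and x.shape[1] != self.coef_.size:
            raise ValueError("covariate dimension mismatch")
        return x @ self.coef_

    def predict_cif(self, X_row, times) -> np.ndarray:
        """F(t | x) = 1 - exp{-Lambda0(t) e^{beta'x}} on the fitted scale.

        When the fit is the censoring-complete Fine-Gray representation this
        is the cause-1 cumulative incidence F1(t | x).
        """
        eta = self.linear_predictor(X_row)
        lam = np.atleast_1d(self.baseline_cumhaz_(np.asarray(times, float)))
        return 1.0 - np.exp(-lam * np.exp(eta))

    def cif_variance(self, X_row, times) -> np.ndarray:
        """Asymptotic variance of F(t|x) by the delta method.

        Var{Lambda(t|x)} combines the Poisson-type variance of the Breslow
        baseline, sum d_j / S0(t_j)^2, with the contribution of the estimated
        coefficients through the gradient
        e^{beta'x} { x Lambda0(t) - sum_{t_j<=t} d_j S1(t_j)/S0(t_j)^2 },
        then Var(F) = exp(-2 Lambda)^ Var(Lambda).
        """
        x = np.atleast_1d(np.asarray(X_row, float))
        times = np.atleast_1d(np.asarray(times, float))
        ev, d, S0 = self._event_times, self._d, self._S0
        if ev.size and times.max() > ev[-1]:
            warnings.warn("times beyond last event time: variance carries last value")
        base_var_steps = np.cumsum(d / S0**2)
        q_steps = np.cumsum(d[:, None] * self._S1 / (S0**2)[:, None], axis=0)
        idx = np.searchsorted(ev, times, side="right") - 1
        lam0 = self.baseline_cumhaz_(times)
        eta = float(x @ self.coef_) if self.coef_.size else 0.0
        e_eta = np.exp(eta)
        out = np.zeros_like(times)
        inside = idx >= 0
        bvar = np.where(inside, base_var_steps[np.clip(idx, 0, None)], 0.0)
        var_lam = e_eta**2 * bvar
        if self.coef_.size:
            q = np.where(
                inside[:, None], q_steps[np.clip(idx, 0, None)], 0.0
            )  # (T, p)
            grad = e_eta * (x[None, :] * lam0[:, None] - q)
            var_lam = var_lam + np.einsum("tk,kl,tl->t", grad, self.covariance_, grad)
        F = 1.0 - np.exp(-lam0 * e_eta)
        out = np.exp(-2.0 * lam0 * e_eta) * var_lam
        return np.maximum(out, 0.0)

    def confidence_interval(self, level: float = 0.95):
        z = stats.norm.ppf(0.5 + level / 2)
        se = np.sqrt(np.diag(self.covariance_))
        return self.coef_ - z * se, self.coef_ + z * se

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coef_.tolist(),
            "covariance": np.asarray(self.covariance_).tolist(),
            "covariate_names": self.covariate_names_,
            "n_events": self.n_events_,
            "baseline_cumhaz": self.baseline_cumhaz_.to_dict(),
        }


# -- thin functional wrappers ------------------------------------------------


def fit_ph(
    sample: SurvivalSample, covariates: np.ndarray, names: list[str] | None = None
) -> CoxPH:
    """Fit a proportional hazards model to a survival sample."""
    model = CoxPH().fit(
        covariates, (sample.time, sample.status), sample_weight=sample.weight
    )
    if names is not None:
        model.covariate_names_ = list(names)
    return model


def draw_ph_parameters(fit: CoxPH, rng: np.random.Generator) -> CoxPH:
    return fit.draw_parameters(rng)


def cif_from_ph(fit: CoxPH, covariate_row, times) -> np.ndarray:
    return fit.predict_cif(covariate_row, times)


def cif_variance(fit: CoxPH, covariate_row, times) -> np.ndarray:
    return fit.cif_variance(covariate_row, times)


def null_baseline_equals_nelson_aalen(sample: SurvivalSample) -> bool:
    """Breslow baseline of a zero-covariate fit equals Nelson-Aalen (exactly)."""
    fit = CoxPH().fit(np.empty((sample.time.size, 0)), (sample.time, sample.status),
                      sample_weight=sample.weight)
    na = nelson_aalen(sample)
    return np.allclose(fit.baseline_cumhaz_.knots, na.knots) and np.allclose(
        fit.baseline_cumhaz_.values, na.values
    )
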