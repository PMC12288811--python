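"""Rubin's-rules pooling across imputed datasets.

Coefficients are pooled on their natural (log hazard ratio) scale; cumulative
incidence curves are pooled after complementary log-log transformation,
theta = log(-log(1 - F)), with delta-method variances, and back-transformed.
Degrees of freedom use the Barnard-Rubin small-sample adjustment with
complete-data df = n - p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["PooledCoefficients", "PooledCIF", "pool_coefficients", "pool_cif"]


@dataclass
class PooledCoefficients:
    estimate: np.ndarray
    within_var: np.ndarray
    between_var: np.ndarray
    total_var: np.ndarray
    df: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    m: int

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(self.total_var)


@dataclass
class PooledCIF:
    times: np.ndarray
    estimate: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    transform: str = "cloglog"


def _barnard_rubin_df(m: int, B: np.ndarray, T: np.ndarray, df_com: float):
    """Barnard-Rubin adjusted df; df_com is the complete-data df (n - p)."""
    lam = np.clip((1 + 1 / m) * B / T, 1e-12, 1 - 1e-12)
    nu_old = (m - 1) / lam**2
    nu_obs = (df_com + 1) / (df_com + 3) * df_com * (1 - lam)
    return nu_old * nu_obs / (nu_old + nu_obs)


def pool_coefficients(
    estimates: np.ndarray,
    variances: np.ndarray,
    level: float = 0.95,
    df_com: float = np.inf,
) -> PooledCoefficients:
    """Pool an (M, p) matrix of estimates with their (M, p) variances.

    Pooled estimate = mean; within variance W = mean of variances; between
    variance B = sample variance of estimates; total T = W + (1 + 1/M) B;
    t-interval on Barnard-Rubin df (old-formula df when df_com is inf).
    """
    est = np.atleast_2d(np.asarray(estimates, float))
    var = np.atleast_2d(np.asarray(variances, float))
    m = est.shape[0]
    qbar = est.mean(axis=0)
    W = var.mean(axis=0)
    if m == 1:
        warnings.warn("M=1: no between-imputation variance; no interval computed")
        nan = np.full_like(qbar, np.nan)
        return PooledCoefficients(qbar, W, nan, W, nan, nan, nan, m=1)
    B = est.var(axis=0, ddof=1)
    T = W + (1 + 1 / m) * B
    lam = np.clip((1 + 1 / m) * B / T, 1e-12, 1 - 1e-12)
    if np.isfinite(df_com):
        df = _barnard_rubin_df(m, B, T, df_com)
    else:
        df = (m - 1) / lam**2
    t_q = stats.t.ppf(0.5 + level / 2, df)
    se = np.sqrt(T)
    return PooledCoefficients(qbar, W, B, T, df, qbar - t_q * se, qbar + t_q * se, m)


def pool_cif(
    curves: np.ndarray,
    variances: np.ndarray,
    times: np.ndarray | None = None,
    level: float = 0.95,
    df_com: float = np.inf,
) -> PooledCIF:
    """Pool M cumulative incidence curves on a shared time grid.

    ``curves`` is (M, T) of F values, ``variances`` (M, T) of Var(F) from the
    asymptotic Cox variance.  Pooling happens on the cloglog scale with
    delta-method variances Var(theta) = Var(F) / [(1-F) log(1-F)]^2; grid
    points where F is 0 or 1 in any dataset cannot be transformed and receive
    the untransformed bounds 0/1.
    """
    F = np.atleast_2d(np.asarray(curves, float))
    VF = np.atleast_2d(np.asarray(variances, float))
    m, nt = F.shape
    times = np.arange(nt, dtype=float) if times is None else np.asarray(times, float)
    ok = np.all((F > 0) & (F < 1), axis=0)
    est = np.zeros(nt)
    lo = np.zeros(nt)
    hi = np.zeros(nt)
    if ok.any():
        Fo = F[:, ok]
        theta = np.log(-np.log1p(-Fo))
        dtheta = 1.0 / ((1.0 - Fo) * np.log1p(-Fo))
        vtheta = VF[:, ok] * dtheta**2
        pooled = pool_coefficients(theta, vtheta, level=level, df_com=df_com)
        back = lambda x: 1.0 - np.exp(-np.exp(x))
        est[ok] = back(pooled.estimate)
        lo[ok] = back(pooled.ci_low if m > 1 else pooled.estimate)
        hi[ok] = back(pooled.ci_high if m > 1 else pooled.estimate)
    bad = ~ok
    if bad.any():
        fbar = F[:, bad].mean(axis=0)
        est[bad] = fbar
        lo[bad] = np.where(np.all(F[:, bad] <= 0, axis=0), 0.0, 0.0)
        hi[bad] = np.where(np.all(F[:, bad] >= 1, axis=0), 1.0, 1.0)
        est[bad] = np.clip(fbar, 0.0, 1.0)
    return PooledCIF(times, est, np.minimum(lo, est), np.maximum(hi, est))
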