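"""Synthetic competing-risks data generation and true estimand values.

Two mechanisms for (event time, cause) given covariates X, Z with
Z ~ N(0,1) and X | Z ~ Bernoulli(expit(Z)):

* ``gen_fg_correct`` — proportional subdistribution hazards hold for cause 1.
  The cause-1 cumulative incidence is specified directly as
  F1(t|X,Z) = 1 - [1 - p{1 - exp(-b1 t^a1)}]^{exp(beta1 X + beta2 Z)}
  (Weibull parametrization F(t) = 1 - exp(-b t^a): shape a, rate b).  The
  cause indicator is drawn first, then times by inverse-transform sampling
  within each cause; cause 2 uses a Weibull proportional hazards model for
  the conditional distribution given the cause.
* ``gen_cs_hazards`` — proportionality holds on the cause-specific hazard
  scale instead (latent Weibull-PH failure times, minimum taken); a Fine-Gray
  model for cause 1 is then misspecified and its probability limit is a
  "least-false" time-averaged coefficient.

Censoring is exponential (optionally covariate-dependent), and missingness in
X follows a logistic missing-at-random model whose intercept is calibrated by
root solving so the average missingness probability hits a target rate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import integrate, optimize

from .cox import CoxPH
from .subdist import make_subdist_time_uncensored

__all__ = [
    "FGCorrectParams",
    "CSHazardParams",
    "MissingnessSpec",
    "CensoringSpec",
    "gen_covariates",
    "gen_fg_correct",
    "gen_cs_hazards",
    "derive_least_false_cs_params",
    "apply_censoring",
    "calibrate_missingness",
    "induce_missingness",
    "true_cif",
    "true_least_false_beta",
]


def _expit(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


@dataclass
class FGCorrectParams:
    """Parameters of the directly specified Fine-Gray mechanism.

    ``p`` is the baseline cause-1 incidence at t = infinity (for X=Z=0);
    (a1, b1) the Weibull shape/rate of the baseline cumulative incidence;
    (beta1, beta2) the subdistribution log hazard ratios of X and Z;
    (a2, b2, beta1_star, beta2_star) the Weibull-PH model for the cause-2
    time conditional on the cause.
    """

    p: float = 0.15
    a1: float = 0.75
    b1: float = 1.0
    beta1: float = 0.75
    beta2: float = 0.5
    a2: float = 0.75
    b2: float = 1.0
    beta1_star: float = 0.75
    beta2_star: float = 0.5

    def __post_init__(self):
        if not 0 < self.p < 1:
            raise ValueError("p must lie in (0, 1)")
        for name in ("a1", "b1", "a2", "b2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class CSHazardParams:
    """Weibull cause-specific proportional hazards parameters.

    h_k(t | X, Z) = a_k b_k t^{a_k - 1} exp(gamma_k1 X + gamma_k2 Z).
    """

    a1: float
    b1: float
    gamma11: float
    gamma12: float
    a2: float
    b2: float
    gamma21: float
    gamma22: float

    def __post_init__(self):
        for name in ("a1", "b1", "a2", "b2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class MissingnessSpec:
    """Logistic MAR missingness in X.

    mechanism='mar_z': logit P(RX=0 | Z) = eta0 + eta1 Z (default eta1=1.5);
    mechanism='mar_t': logit P(RX=0 | T) = eta0 + eta1 log(T+1) (eta1=-1.5).
    ``eta0`` is calibrated so the average missingness equals ``target_rate``.
    """

    mechanism: str = "mar_z"
    eta1: float | None = None
    target_rate: float = 0.4
    eta0: float | None = None

    def __post_init__(self):
        if self.mechanism not in ("mar_z", "mar_t"):
            raise ValueError("mechanism must be 'mar_z' or 'mar_t'")
        if not 0 < self.target_rate < 1:
            raise ValueError("target_rate must lie in (0, 1)")
        if self.eta1 is None:
            self.eta1 = 1.5 if self.mechanism == "mar_z" else -1.5


@dataclass
class CensoringSpec:
    """Exponential censoring: C ~ Exp(rate) or Exp(rate * e^{z_coef Z}).

    kind='administrative' keeps the drawn times but marks them known for all
    subjects; kind='none' applies no censoring.
    """

    kind: str = "random"
    rate: float = 0.49
    z_coef: float = 1.0

    def __post_init__(self):
        if self.kind not in ("none", "administrative", "random", "covariate_dependent"):
            raise ValueError(f"unknown censoring kind {self.kind!r}")
        if self.kind != "none" and self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def known(self) -> bool:
        return self.kind == "administrative"


def gen_covariates(n: int, rng: np.random.Generator):
    """Z ~ N(0, 1) and X | Z ~ Bernoulli(expit(Z))."""
    if n < 1:
        raise ValueError("n must be >= 1")
    z = rng.normal(size=n)
    x = (rng.uniform(size=n) < _expit(z)).astype(float)
    return x, z


def fg_inverse_transform(u, eta, params: FGCorrectParams):
    """Invert the conditional cause-1 CDF given the cause and covariates.

    Solves P(T <= t | cause 1, X, Z) = u for t under the directly specified
    mechanism; eta = beta1 X + beta2 Z.
    """
    p, a1, b1 = params.p, params.a1, params.b1
    ee = np.exp(eta)
    inner = (1.0 - u * (1.0 - (1.0 - p) ** ee)) ** (1.0 / ee)
    return (-np.log(1.0 - (1.0 - inner) / p) / b1) ** (1.0 / a1)


def fg_conditional_cdf(t, eta, params: FGCorrectParams):
    """P(T <= t | cause 1, X, Z) under the directly specified mechanism."""
    p, a1, b1 = params.p, params.a1, params.b1
    ee = np.exp(eta)
    f01 = p * (1.0 - np.exp(-b1 * np.asarray(t, float) ** a1))
    return (1.0 - (1.0 - f01) ** ee) / (1.0 - (1.0 - p) ** ee)


def gen_fg_correct(
    n: int,
    params: FGCorrectParams | None = None,
    rng: np.random.Generator | None = None,
    covariates: tuple[np.ndarray, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Generate (time, cause, x, z) with proportional subdistribution hazards.

    Draw the cause first: P(cause 2 | X, Z) = (1-p)^{exp(beta1 X + beta2 Z)};
    cause-1 times by the closed-form inverse transform, cause-2 times by
    Weibull-PH inverse transform within the cause-2 subset.
    """
    params = params or FGCorrectParams()
    rng = rng or np.random.default_rng()
    x, z = covariates if covariates is not None else gen_covariates(n, rng)
    eta = params.beta1 * x + params.beta2 * z
    p2 = (1.0 - params.p) ** np.exp(eta)
    if np.any((p2 <= 0) | (p2 >= 1)):
        raise ValueError("P(cause 1 | X, Z) outside (0, 1) for generated covariates")
    cause = np.where(rng.uniform(size=n) < p2, 2, 1)
    t = np.empty(n)
    u = rng.uniform(size=n)
    is1 = cause == 1
    t[is1] = fg_inverse_transform(u[is1], eta[is1], params)
    eta_star = params.beta1_star * x + params.beta2_star * z
    # Weibull-PH inverse transform: H02*(t) e^{eta*} = -log(1-u)
    t[~is1] = (
        -np.log(1.0 - u[~is1]) / (params.b2 * np.exp(eta_star[~is1]))
    ) ** (1.0 / params.a2)
    return pd.DataFrame({"time": t, "status": cause, "x": x, "z": z})


def gen_cs_hazards(
    n: int,
    params: CSHazardParams,
    rng: np.random.Generator | None = None,
    covariates: tuple[np.ndarray, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Generate via latent Weibull proportional cause-specific hazards.

    T = min of the two latent times, cause = argmin.
    """
    rng = rng or np.random.default_rng()
    x, z = covariates if covariates is not None else gen_covariates(n, rng)
    u1, u2 = rng.uniform(size=(2, n))
    t1 = (
        -np.log(1 - u1) / (params.b1 * np.exp(params.gamma11 * x + params.gamma12 * z))
    ) ** (1.0 / params.a1)
    t2 = (
        -np.log(1 - u2) / (params.b2 * np.exp(params.gamma21 * x + params.gamma22 * z))
    ) ** (1.0 / params.a2)
    t = np.minimum(t1, t2)
    cause = np.where(t1 <= t2, 1, 2)
    return pd.DataFrame({"time": t, "status": cause, "x": x, "z": z})


def apply_censoring(
    data: pd.DataFrame,
    spec: CensoringSpec,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Apply exponential censoring: T = min(T~, C), status zeroed if censored.

    The drawn censoring time is retained in column 'c' when the spec marks it
    known (administrative) — for all subjects.
    """
    out = data.copy()
    if spec.kind == "none":
        return out
    rng = rng or np.random.default_rng()
    n = len(out)
    rate = spec.rate * (
        np.exp(spec.z_coef * out["z"].to_numpy(float))
        if spec.kind == "covariate_dependent"
        else np.ones(n)
    )
    c = rng.exponential(1.0 / rate)
    t = out["time"].to_numpy(float)
    censored = c < t
    out["time"] = np.minimum(t, c)
    out.loc[censored, "status"] = 0
    if spec.known:
        out["c"] = c
    return out


def calibrate_missingness(
    spec: MissingnessSpec,
    reference: np.ndarray | None = None,
    n_quad: int = 80,
) -> float:
    """Solve E[expit(eta0 + eta1 W)] = target_rate for eta0.

    W is Z ~ N(0,1) (Gauss-Hermite quadrature) for mar_z, or log(T+1)
    averaged over a supplied reference sample of observed times for mar_t.
    """
    if spec.eta1 == 0:
        return float(np.log(spec.target_rate / (1 - spec.target_rate)))
    if spec.mechanism == "mar_z":
        nodes, weights = np.polynomial.hermite_e.hermegauss(n_quad)
        weights = weights / np.sqrt(2 * np.pi)
        w_vals = nodes
    else:
        if reference is None:
            raise ValueError("mar_t calibration needs a reference sample of times")
        w_vals = np.log(np.asarray(reference, float) + 1.0)
        weights = np.full(w_vals.size, 1.0 / w_vals.size)

    def mean_rate(eta0):
        return float(np.sum(weights * _expit(eta0 + spec.eta1 * w_vals))) - spec.target_rate

    lo, hi = -10.0, 10.0
    for _ in range(5):
        if mean_rate(lo) < 0 < mean_rate(hi):
            break
        lo *= 2
        hi *= 2
    else:
        raise ValueError("could not bracket the calibration root")
    return float(optimize.brentq(mean_rate, lo, hi, xtol=1e-8))


def induce_missingness(
    data: pd.DataFrame,
    spec: MissingnessSpec,
    rng: np.random.Generator | None = None,
    target_col: str = "x",
) -> pd.DataFrame:
    """Blank ``target_col`` where the logistic MAR model draws RX = 0."""
    rng = rng or np.random.default_rng()
    out = data.copy()
    if spec.eta0 is None:
        spec = replace(
            spec,
            eta0=calibrate_missingness(
                spec,
                reference=out["time"].to_numpy(float)
                if spec.mechanism == "mar_t"
                else None,
            ),
        )
    w = (
        out["z"].to_numpy(float)
        if spec.mechanism == "mar_z"
        else np.log(out["time"].to_numpy(float) + 1.0)
    )
    p_missing = _expit(spec.eta0 + spec.eta1 * w)
    mask = rng.uniform(size=len(out)) < p_missing
    out.loc[mask, target_col] = np.nan
    return out


# -- least-false parameters and true estimands -------------------------------


def _weibull_ph_loglik(theta, t, delta, X):
    """Negative log-likelihood of a Weibull PH model h = a b t^{a-1} e^{X g}."""
    log_a, log_b = theta[0], theta[1]
    gamma = theta[2:]
    a, b = np.exp(log_a), np.exp(log_b)
    eta = X @ gamma
    log_h = log_a + log_b + (a - 1.0) * np.log(t) + eta
    H = b * t**a * np.exp(eta)
    return -(np.sum(delta * log_h) - np.sum(H))


def fit_weibull_ph(t, delta, X) -> tuple[float, float, np.ndarray]:
    """Maximum likelihood Weibull PH fit; returns (shape, rate, gammas)."""
    t = np.asarray(t, float)
    delta = np.asarray(delta, float)
    X = np.atleast_2d(np.asarray(X, float))
    theta0 = np.concatenate([[0.0, np.log(max(delta.mean(), 1e-3))],
                             np.zeros(X.shape[1])])
    res = optimize.minimize(
        _weibull_ph_loglik, theta0, args=(t, delta, X), method="L-BFGS-B"
    )
    if not res.success:
        res = optimize.minimize(
            _weibull_ph_loglik, theta0, args=(t, delta, X), method="Nelder-Mead",
            options={"maxiter": 5000, "xatol": 1e-8, "fatol": 1e-10},
        )
        if not res.success:
            raise RuntimeError(
                "Weibull PH maximum likelihood did not converge; try restarting "
                f"from a parameter grid ({res.message})"
            )
    return float(np.exp(res.x[0])), float(np.exp(res.x[1])), res.x[2:]


def derive_least_false_cs_params(
    fg_params: FGCorrectParams,
    n_large: int = 200_000,
    censoring: CensoringSpec | None = None,
    rng: np.random.Generator | None = None,
) -> CSHazardParams:
    """Weibull cause-specific parameters matching a Fine-Gray-correct world.

    Simulates a large dataset from the directly specified mechanism (with the
    scenario's censoring applied), fits parametric Weibull PH models per
    cause by maximum likelihood, and returns their point estimates as the
    cause-specific generating parameters.  Both fits are (mildly) misspecified
    — these are least-false values, not structural truths.
    """
    rng = rng or np.random.default_rng()
    data = gen_fg_correct(n_large, fg_params, rng)
    if censoring is not None and censoring.kind != "none":
        data = apply_censoring(data, censoring, rng)
    t = data["time"].to_numpy(float)
    d = data["status"].to_numpy()
    X = data[["x", "z"]].to_numpy(float)
    a1, b1, g1 = fit_weibull_ph(t, (d == 1).astype(float), X)
    a2, b2, g2 = fit_weibull_ph(t, (d == 2).astype(float), X)
    return CSHazardParams(a1, b1, g1[0], g1[1], a2, b2, g2[0], g2[1])


def true_cif(
    params,
    mechanism: str,
    x: float,
    z: float,
    times: np.ndarray,
    cause: int = 1,
) -> np.ndarray:
    """True cumulative incidence F_cause(t | x, z) under either mechanism.

    Closed form for the directly specified Fine-Gray mechanism; adaptive
    quadrature of integral h_k exp(-H1 - H2) for the cause-specific one.
    """
    times = np.asarray(times, float)
    if mechanism == "fg_correct":
        if cause != 1:
            raise ValueError("closed form available for cause 1 only")
        eta = params.beta1 * x + params.beta2 * z
        f01 = params.p * (1.0 - np.exp(-params.b1 * times**params.a1))
        return 1.0 - (1.0 - f01) ** np.exp(eta)
    if mechanism != "cs_hazards":
        raise ValueError(f"unknown mechanism {mechanism!r}")
    if cause == 1:
        a, b, g1, g2 = params.a1, params.b1, params.gamma11, params.gamma12
    else:
        a, b, g1, g2 = params.a2, params.b2, params.gamma21, params.gamma22
    e1 = np.exp(params.gamma11 * x + params.gamma12 * z)
    e2 = np.exp(params.gamma21 * x + params.gamma22 * z)
    ek = np.exp(g1 * x + g2 * z)

    def integrand(u):
        return (
            a * b * u ** (a - 1.0) * ek
            * np.exp(-params.b1 * u**params.a1 * e1 - params.b2 * u**params.a2 * e2)
        )

    out = np.empty(times.size)
    for i, t in enumerate(np.atleast_1d(times)):
        out[i] = 0.0 if t <= 0 else integrate.quad(
            integrand, 0.0, t, epsabs=1e-8, limit=200
        )[0]
    return out


def true_least_false_beta(
    cs_params: CSHazardParams,
    censoring: CensoringSpec | None = None,
    n_large: int = 200_000,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Time-averaged subdistribution log hazard ratios under misspecification.

    Simulates the cause-specific mechanism at scale, applies censoring with
    the censoring times treated as known, builds the censoring-complete
    subdistribution time V and fits the Fine-Gray model as a Cox model on
    (V, I(D=1)); the coefficients are the least-false (beta1~, beta2~).
    """
    rng = rng or np.random.default_rng()
    data = gen_cs_hazards(n_large, cs_params, rng)
    if censoring is not None and censoring.kind != "none":
        spec = replace(censoring, kind="administrative")  # known censoring times
        data = apply_censoring(data, spec, rng)
        ccd = make_subdist_time_uncensored(
            data, "administrative", admin_times=data["c"].to_numpy(float)
        )
    else:
        ccd = make_subdist_time_uncensored(data, "no_censoring")
    fit = CoxPH(keep_data=False).fit(
        ccd[["x", "z"]].to_numpy(float),
        (ccd["v"].to_numpy(float), ccd["ev1"].to_numpy()),
    )
    return fit.coef_
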