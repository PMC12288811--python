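"""Construction of censoring-complete data for Fine-Gray estimation.

On censoring-complete data the Fine-Gray model for cause 1 is an ordinary Cox
model with outcome ``(V, I(D=1))``, where the subdistribution time is
``V = I(D=1) T + I(D!=1) C``.  For subjects failing from the competing event
under random censoring the potential censoring time ``C`` is unknown; it is
multiply imputed by drawing from the conditional censoring distribution
``1 - G(t-)/G(T_i-)`` (Kaplan-Meier imputation), where ``G`` is an estimate of
``P(C > t)`` — marginal or stratified KM, or a Cox model when censoring depends
on continuous fully observed covariates.

This module also attaches the hazard columns the covariate-imputation models
need: marginal cause-specific cumulative hazards ``H1(T)``, ``H2(T)`` and the
marginal cumulative subdistribution hazard ``L1(V)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cox import CoxPH
from .nonparametric import SurvivalSample, kaplan_meier, nelson_aalen
from .stepfun import StepFunction

__all__ = [
    "CensoringModelSpec",
    "attach_cause_specific_hazards",
    "make_subdist_time_uncensored",
    "fit_censoring_distribution",
    "impute_censoring_times",
    "recompute_subdist_hazard",
    "CensoringImputer",
]

# canonical column names for censoring-complete data
V, EV1, H1_T, H2_T, L1_V, V_IMPUTED = "v", "ev1", "h1_T", "h2_T", "l1_v", "v_imputed"


@dataclass
class CensoringModelSpec:
    """How to estimate the censoring distribution P(C > t).

    kind='marginal_km' ignores covariates; 'stratified_km' fits a KM per level
    combination of (categorical) ``covariate_names``; 'ph_model' fits a Cox
    model for the censoring hazard on ``covariate_names``.  ``bootstrap=True``
    re-estimates G on an independent bootstrap resample for each imputation.
    """

    kind: str = "marginal_km"
    covariate_names: list[str] = field(default_factory=list)
    bootstrap: bool = False

    def __post_init__(self):
        if self.kind not in ("marginal_km", "stratified_km", "ph_model"):
            raise ValueError(f"unknown censoring model kind {self.kind!r}")
        if self.kind in ("stratified_km", "ph_model") and not self.covariate_names:
            raise ValueError(f"{self.kind} requires covariate_names")


def _check_competing(data: pd.DataFrame, time_col: str, status_col: str) -> None:
    t = data[time_col].to_numpy(float)
    d = data[status_col].to_numpy()
    if np.any(t <= 0):
        raise ValueError("all times must be positive")
    if not np.isin(d, (0, 1, 2)).all():
        raise ValueError("status must take values in {0, 1, 2}")


def attach_cause_specific_hazards(
    data: pd.DataFrame, time_col: str = "time", status_col: str = "status"
) -> pd.DataFrame:
    """Add marginal Nelson-Aalen cause-specific cumulative hazard columns.

    ``h1_T`` and ``h2_T`` hold H_k(T_i): cause k treated as the event,
    everything else as censoring, evaluated at each subject's own time.
    """
    _check_competing(data, time_col, status_col)
    out = data.copy()
    t = out[time_col].to_numpy(float)
    d = out[status_col].to_numpy()
    for k, col in ((1, H1_T), (2, H2_T)):
        if not np.any(d == k):
            warnings.warn(f"no cause-{k} events: {col} set to 0")
            out[col] = 0.0
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hk = nelson_aalen(SurvivalSample(t, (d == k).astype(int)))
        out[col] = hk(t)
    return out


def make_subdist_time_uncensored(
    data: pd.DataFrame,
    mode: str = "no_censoring",
    admin_times: np.ndarray | None = None,
    time_col: str = "time",
    status_col: str = "status",
) -> pd.DataFrame:
    """Build the subdistribution time V when it is fully observed.

    mode='no_censoring': competing-event failures receive a common V larger
    than every observed time (max(T) + 1; any value past the last cause-1
    event time gives an identical partial likelihood).
    mode='administrative': competing-event failures receive their known
    potential censoring time from ``admin_times`` (per-subject, full length).
    """
    _check_competing(data, time_col, status_col)
    out = data.copy()
    t = out[time_col].to_numpy(float)
    d = out[status_col].to_numpy()
    v = t.copy()
    comp = d == 2
    if mode == "no_censoring":
        v[comp] = t.max() + 1.0
    elif mode == "administrative":
        if admin_times is None:
            raise ValueError("administrative mode requires admin_times")
        admin = np.asarray(admin_times, float)
        if admin.shape[0] != len(out):
            raise ValueError("admin_times must be given per subject")
        if np.any(admin[comp] < t[comp]):
            raise ValueError("administrative censoring time before failure time")
        v[comp] = admin[comp]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out[V] = v
    out[EV1] = (d == 1).astype(int)
    out[V_IMPUTED] = 0
    return out


def fit_censoring_distribution(
    data: pd.DataFrame,
    spec: CensoringModelSpec,
    time_col: str = "time",
    status_col: str = "status",
):
    """Estimate P(C > t) reversing roles: censoring (D=0) is the event.

    Returns a StepFunction (marginal), a dict level -> StepFunction
    (stratified), or a fitted CoxPH for the censoring hazard.
    """
    _check_competing(data, time_col, status_col)
    t = data[time_col].to_numpy(float)
    cens = (data[status_col].to_numpy() == 0).astype(int)
    if cens.sum() == 0:
        raise ValueError(
            "no censored observations: use make_subdist_time_uncensored instead"
        )
    if spec.kind == "marginal_km":
        return kaplan_meier(SurvivalSample(t, cens))
    if spec.kind == "stratified_km":
        out: dict = {}
        by = (
            spec.covariate_names[0]
            if len(spec.covariate_names) == 1
            else spec.covariate_names
        )
        for key, grp in data.groupby(by, observed=True):
            tt = grp[time_col].to_numpy(float)
            cc = (grp[status_col].to_numpy() == 0).astype(int)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out[key] = kaplan_meier(SurvivalSample(tt, cc))
        return out
    Xc = data[spec.covariate_names].to_numpy(float)
    return CoxPH().fit(Xc, (t, cens))


def _draw_from_km(
    G: StepFunction, t_fail: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw censoring times from the conditional KM distribution given C > T_i.

    Support is restricted to censoring knots strictly greater than T_i;
    residual KM mass beyond the last knot is assigned to the last knot
    (tail rule, treated as administrative).
    """
    knots, jumps = G.knots, -G.jumps()  # jumps of the distribution, >= 0
    if knots.size == 0:
        raise ValueError("degenerate censoring estimate: no censoring mass")
    mass = jumps.copy()
    mass[-1] += float(G.values[-1])  # residual survival mass to last knot
    cum = np.cumsum(mass)
    start = np.searchsorted(knots, t_fail, side="right")
    out = np.empty(t_fail.size)
    beyond = start >= knots.size
    if beyond.any():
        warnings.warn(
            f"{int(beyond.sum())} failure time(s) beyond the censoring support: "
            "imputing at the largest support knot"
        )
        out[beyond] = knots[-1]
    inside = ~beyond
    if inside.any():
        lo = np.where(start[inside] > 0, cum[start[inside] - 1], 0.0)
        hi = cum[-1]
        if np.any(hi - lo <= 0):
            raise ValueError("zero conditional censoring mass past a failure time")
        target = lo + rng.uniform(size=int(inside.sum())) * (hi - lo)
        idx = np.searchsorted(cum, target, side="left")
        idx = np.minimum(np.maximum(idx, start[inside]), knots.size - 1)
        out[inside] = knots[idx]
    return out


def _draw_from_coxph(
    fit: CoxPH, t_fail: np.ndarray, x_rows: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Inverse-CDF draw from a Cox-model censoring distribution given C > T_i.

    U ~ Uniform(0, S_C(T_i- | z)); V is the smallest baseline knot with
    S_C(knot | z) <= U, equivalently Lambda0(knot) >= -log(U) e^{-eta}.
    """
    knots = fit.baseline_cumhaz_.knots
    lam0 = fit.baseline_cumhaz_.values
    eta = x_rows @ fit.coef_
    s_left = np.exp(-np.asarray(fit.baseline_cumhaz_.left_limit(t_fail)) * np.exp(eta))
    if np.any(s_left <= 0):
        raise ValueError("estimated censoring survival is 0 at a failure time")
    u = rng.uniform(size=t_fail.size) * s_left
    thr = -np.log(u) * np.exp(-eta)
    idx = np.searchsorted(lam0, thr, side="left")
    after = np.searchsorted(knots, t_fail, side="right")  # enforce V > T_i
    idx = np.maximum(idx, after)
    beyond = idx >= knots.size
    if beyond.any():
        warnings.warn(
            f"{int(beyond.sum())} draw(s) beyond the censoring support: "
            "imputing at the largest support knot"
        )
    return knots[np.minimum(idx, knots.size - 1)]


def impute_censoring_times(
    data: pd.DataFrame,
    censoring_estimate=None,
    m: int = 30,
    rng: np.random.Generator | None = None,
    spec: CensoringModelSpec | None = None,
    time_col: str = "time",
    status_col: str = "status",
) -> list[pd.DataFrame]:
    """Multiply impute potential censoring times for competing-event failures.

    Returns ``m`` censoring-complete datasets.  Rows with D != 2 are identical
    across datasets; each D=2 subject's V is an independent draw from the
    conditional censoring distribution given ``C > T_i`` (per stratum or
    covariate row where applicable).  ``l1_v`` is recomputed per dataset.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    rng = rng or np.random.default_rng()
    spec = spec or CensoringModelSpec()
    if censoring_estimate is None and not spec.bootstrap:
        censoring_estimate = fit_censoring_distribution(data, spec, time_col, status_col)
    t = data[time_col].to_numpy(float)
    d = data[status_col].to_numpy()
    comp = d == 2
    streams = rng.spawn(m)
    out = []
    for s in streams:
        if spec.bootstrap:
            boot = data.sample(len(data), replace=True, random_state=np.random.RandomState(
                s.integers(2**31)))
            est = fit_censoring_distribution(boot, spec, time_col, status_col)
        else:
            est = censoring_estimate
        ccd = data.copy()
        v = t.copy()
        if comp.any():
            if isinstance(est, StepFunction):
                v[comp] = _draw_from_km(est, t[comp], s)
            elif isinstance(est, dict):
                strata = data[spec.covariate_names]
                keys = (
                    strata.iloc[:, 0]
                    if len(spec.covariate_names) == 1
                    else pd.Series(list(map(tuple, strata.to_numpy())), index=data.index)
                )
                v_comp = np.empty(int(comp.sum()))
                comp_idx = np.flatnonzero(comp)
                keys_comp = keys.to_numpy()[comp_idx]
                for key in pd.unique(keys_comp):
                    sel = keys_comp == key
                    v_comp[sel] = _draw_from_km(est[key], t[comp_idx[sel]], s)
                v[comp] = v_comp
            elif isinstance(est, CoxPH):
                x_rows = data.loc[comp, spec.covariate_names].to_numpy(float)
                v[comp] = _draw_from_coxph(est, t[comp], x_rows, s)
            else:
                raise TypeError("unrecognized censoring estimate")
        ccd[V] = v
        ccd[EV1] = (d == 1).astype(int)
        ccd[V_IMPUTED] = comp.astype(int)
        out.append(recompute_subdist_hazard(ccd))
    return out


def recompute_subdist_hazard(ccd: pd.DataFrame) -> pd.DataFrame:
    """Attach L1(V): marginal Nelson-Aalen on (V, I(D=1)) evaluated at own V."""
    out = ccd.copy()
    v = out[V].to_numpy(float)
    ev = out[EV1].to_numpy()
    if not np.any(ev == 1):
        warnings.warn("no cause-1 events: l1_v set to 0")
        out[L1_V] = 0.0
        return out
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        na = nelson_aalen(SurvivalSample(v, ev))
    out[L1_V] = na(v)
    return out


class CensoringImputer(BaseEstimator):
    """sklearn-style wrapper: multiply impute potential censoring times.

    Parameters mirror :func:`impute_censoring_times`; ``transform`` returns a
    list of ``m`` censoring-complete DataFrames with columns
    (v, ev1, v_imputed, l1_v) added.
    """

    def __init__(
        self,
        kind: str = "marginal_km",
        covariate_names: tuple = (),
        bootstrap: bool = False,
        m: int = 30,
        random_state: int | None = None,
        time_col: str = "time",
        status_col: str = "status",
    ):
        self.kind = kind
        self.covariate_names = covariate_names
        self.bootstrap = bootstrap
        self.m = m
        self.random_state = random_state
        self.time_col = time_col
        self.status_col = status_col

    def _spec(self) -> CensoringModelSpec:
        return CensoringModelSpec(
            self.kind, list(self.covariate_names), self.bootstrap
        )

    def fit(self, data: pd.DataFrame, y=None):
        self.censoring_estimate_ = fit_censoring_distribution(
            data, self._spec(), self.time_col, self.status_col
        )
        return self

    def transform(self, data: pd.DataFrame) -> list[pd.DataFrame]:
        rng = np.random.default_rng(self.random_state)
        return impute_censoring_times(
            data,
            getattr(self, "censoring_estimate_", None),
            m=self.m,
            rng=rng,
            spec=self._spec(),
            time_col=self.time_col,
            status_col=self.status_col,
        )

    def fit_transform(self, data: pd.DataFrame, y=None) -> list[pd.DataFrame]:
        return self.fit(data).transform(data)
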