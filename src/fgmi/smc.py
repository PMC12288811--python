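"""Substantive-model-compatible FCS imputation of missing covariates.

Missing covariate values are sampled from the full conditional

    f(X_j | outcome, X_-j, Z)  proportional to  f(outcome | X, Z) f(X_j | X_-j, Z)

where the outcome factor is the likelihood contribution of the substantive
model evaluated at a drawn parameter vector:

* FG-SMC — substantive model is a Fine-Gray model for cause 1 fitted as a Cox
  model on censoring-complete data:
  f(V, D | X, Z) = lambda1(V|X,Z)^{I(D=1)} exp{-Lambda1(V|X,Z)};
* CS-SMC — substantive models are two cause-specific Cox models:
  f(T, D | X, Z) = h_D(T|X,Z)^{I(D>0)} exp{-H1(T|X,Z) - H2(T|X,Z)}.

Baseline hazard factors use the Breslow jump at the subject's event time and
cancel in all ratios over candidate covariate values; they are retained so the
same code path serves both densities.  Discrete targets are imputed by exact
normalization over their levels; continuous targets by rejection sampling from
the covariate model with an adaptive bound.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .covmodels import CovariateModelSpec, LinearModel
from .cox import ConvergenceError, CoxPH
from .subdist import EV1, V

__all__ = [
    "SubstantiveSpec",
    "ImputationStack",
    "outcome_density_fg",
    "outcome_density_cs",
    "discrete_full_conditional",
    "impute_discrete_covariate",
    "impute_continuous_covariate",
    "run_smcfcs",
    "SMCFCSImputer",
]


@dataclass
class SubstantiveSpec:
    """The outcome model that imputations must be compatible with.

    kind='fine_gray_cause1' fits a Cox model on (v, ev1) — valid on
    censoring-complete data; kind='cause_specific' fits one Cox model per
    cause on (time, I(status=k)).
    """

    kind: str = "fine_gray_cause1"
    covariate_names: list[str] = field(default_factory=list)
    cause1_covariates: list[str] | None = None
    cause2_covariates: list[str] | None = None
    time_col: str = "time"
    status_col: str = "status"

    def __post_init__(self):
        if self.kind not in ("fine_gray_cause1", "cause_specific"):
            raise ValueError(f"unknown substantive kind {self.kind!r}")
        if self.kind == "cause_specific":
            if self.cause1_covariates is None:
                self.cause1_covariates = list(self.covariate_names)
            if self.cause2_covariates is None:
                self.cause2_covariates = list(self.covariate_names)


@dataclass
class ImputationStack:
    """M completed datasets plus chain metadata."""

    datasets: list[pd.DataFrame]
    meta: dict

    def __len__(self) -> int:
        return len(self.datasets)

    def __iter__(self):
        return iter(self.datasets)


# -- outcome densities -------------------------------------------------------


def _baseline_factors(fit: CoxPH, times: np.ndarray, events: np.ndarray):
    """Per-row (cumhaz, jump^event) factors of the Breslow likelihood.

    Event rows sit on a baseline jump by construction; a row whose time
    carries no jump falls back to the nearest prior jump.
    """
    lam = np.asarray(fit.baseline_cumhaz_(times), float)
    jump = np.asarray(fit.baseline_cumhaz_.jump_at(times), float)
    ev = events.astype(bool)
    missing = ev & (jump <= 0)
    if missing.any():
        jump = np.where(
            missing,
            np.asarray(fit.baseline_cumhaz_.jump_at(times, nearest_prior=True), float),
            jump,
        )
        if np.any(ev & (jump <= 0)):
            raise ValueError("event time carries no baseline hazard jump")
    return lam, np.where(ev, jump, 1.0)


def fg_density_factory(fit: CoxPH, v: np.ndarray, ev1: np.ndarray):
    """Vectorized FG likelihood: rows x candidate designs -> density values."""
    v = np.asarray(v, float)
    ev1 = np.asarray(ev1, float)
    lam, jump = _baseline_factors(fit, v, ev1)

    def density(X_rows: np.ndarray) -> np.ndarray:
        eta = np.asarray(X_rows, float) @ fit.coef_
        return jump * np.exp(ev1 * eta - lam * np.exp(eta))

    return density


def cs_density_factory(
    fit1: CoxPH, fit2: CoxPH, t: np.ndarray, d: np.ndarray,
    cols1: np.ndarray, cols2: np.ndarray,
):
    """Vectorized cause-specific likelihood over candidate designs.

    ``cols1``/``cols2`` index the columns of the candidate design matrix used
    by each cause-specific fit.
    """
    t = np.asarray(t, float)
    d = np.asarray(d)
    e1 = (d == 1).astype(float)
    e2 = (d == 2).astype(float)
    # a cause with no events contributes nothing: H_k = 0, jump factor = 1
    if fit1 is not None:
        lam1, jump1 = _baseline_factors(fit1, t, e1)
    else:
        lam1, jump1 = np.zeros_like(t), np.ones_like(t)
    if fit2 is not None:
        lam2, jump2 = _baseline_factors(fit2, t, e2)
    else:
        lam2, jump2 = np.zeros_like(t), np.ones_like(t)

    def density(X_rows: np.ndarray) -> np.ndarray:
        X_rows = np.asarray(X_rows, float)
        eta1 = X_rows[:, cols1] @ fit1.coef_ if fit1 is not None else 0.0
        eta2 = X_rows[:, cols2] @ fit2.coef_ if fit2 is not None else 0.0
        return (
            jump1 * jump2
            * np.exp(e1 * eta1 + e2 * eta2 - lam1 * np.exp(eta1) - lam2 * np.exp(eta2))
        )

    return density


def outcome_density_fg(v, ev1, x_row, fit: CoxPH) -> float:
    """Fine-Gray likelihood contribution of one subject at covariates x_row."""
    dens = fg_density_factory(fit, np.atleast_1d(v), np.atleast_1d(ev1))
    return float(dens(np.atleast_2d(x_row))[0])


def outcome_density_cs(t, d, x_row, fits: tuple[CoxPH, CoxPH]) -> float:
    """Cause-specific likelihood contribution of one subject at x_row.

    Both fits must use the covariates of ``x_row`` in the same order.
    """
    p = np.atleast_1d(x_row).size
    cols = np.arange(p)
    dens = cs_density_factory(
        fits[0], fits[1], np.atleast_1d(t), np.atleast_1d(d), cols, cols
    )
    return float(dens(np.atleast_2d(x_row))[0])


# -- elementary imputation draws --------------------------------------------


def discrete_full_conditional(
    levels: np.ndarray,
    outcome_density,
    prior_probs: np.ndarray,
    design_for_level,
) -> np.ndarray:
    """(n, K) matrix with P(level) prop. to outcome_density(level) * prior."""
    weights = np.stack(
        [outcome_density(design_for_level(lv)) for lv in levels], axis=1
    )
    weights = weights * prior_probs
    total = weights.sum(axis=1)
    if np.any(total <= 0) or not np.all(np.isfinite(total)):
        bad = np.flatnonzero((total <= 0) | ~np.isfinite(total))
        raise ValueError(
            f"zero or non-finite product density for rows {bad[:10].tolist()}"
        )
    return weights / total[:, None]


def impute_discrete_covariate(
    levels: np.ndarray,
    outcome_density,
    prior_probs: np.ndarray,
    design_for_level,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample exactly from the normalized product density over levels.

    ``prior_probs`` is (n, K) from the covariate model at drawn parameters;
    ``design_for_level(level)`` returns the (n, p) substantive design with the
    target column set to that level.
    """
    probs = discrete_full_conditional(
        levels, outcome_density, prior_probs, design_for_level
    )
    u = rng.uniform(size=probs.shape[0])[:, None]
    idx = (probs.cumsum(axis=1) < u).sum(axis=1)
    return np.asarray(levels)[idx]


def impute_continuous_covariate(
    outcome_density,
    proposal_sampler,
    design_with_values,
    rng: np.random.Generator,
    n_rows: int,
    presample: int = 25,
    bound_inflation: float = 1.2,
    max_attempts: int = 1000,
) -> tuple[np.ndarray, dict]:
    """Rejection-sample a continuous covariate row-wise.

    Proposals come from the covariate model; acceptance probability is
    outcome_density / bound, where the bound is the max outcome density over a
    per-row pre-sample, inflated.  On hitting the attempt cap the best
    proposal seen (highest product density) is kept and counted.
    """
    pre = np.stack([proposal_sampler(rng) for _ in range(presample)], axis=0)
    pre_dens = np.stack(
        [outcome_density(design_with_values(pre[s])) for s in range(presample)], axis=0
    )
    bound = pre_dens.max(axis=0) * bound_inflation
    bound = np.where(bound > 0, bound, 1.0)

    out = np.empty(n_rows)
    best_val = pre[pre_dens.argmax(axis=0), np.arange(n_rows)]
    best_dens = pre_dens.max(axis=0)
    active = np.ones(n_rows, dtype=bool)
    attempts = 0
    n_accepted_attempts = 0
    while active.any() and attempts < max_attempts:
        prop = proposal_sampler(rng)
        dens = outcome_density(design_with_values(prop))
        u = rng.uniform(size=n_rows)
        accept = active & (u * bound <= dens)
        out[accept] = prop[accept]
        improve = active & (dens > best_dens)
        best_val[improve] = prop[improve]
        best_dens[improve] = dens[improve]
        n_accepted_attempts += int(accept.sum())
        active &= ~accept
        attempts += 1
    n_fallback = int(active.sum())
    if n_fallback:
        warnings.warn(
            f"rejection cap reached for {n_fallback} row(s): keeping the best "
            "proposal seen"
        )
        out[active] = best_val[active]
    diag = {
        "attempts": attempts,
        "fallback_rows": n_fallback,
        "acceptance_rate": n_accepted_attempts / max(attempts * n_rows, 1),
    }
    return out, diag


# -- the chained algorithm ---------------------------------------------------


def _fit_substantive(completed: pd.DataFrame, spec: SubstantiveSpec):
    if spec.kind == "fine_gray_cause1":
        fit = CoxPH().fit(
            completed[spec.covariate_names].to_numpy(float),
            (completed[V].to_numpy(float), completed[EV1].to_numpy()),
        )
        return (fit,)
    t = completed[spec.time_col].to_numpy(float)
    d = completed[spec.status_col].to_numpy()
    fits = []
    for k, covs in ((1, spec.cause1_covariates), (2, spec.cause2_covariates)):
        if not np.any(d == k):  # degenerate single-event data
            fits.append(None)
            continue
        fits.append(
            CoxPH().fit(completed[covs].to_numpy(float), (t, (d == k).astype(int)))
        )
    return tuple(fits)


def _density_for_rows(spec: SubstantiveSpec, drawn_fits, rows: pd.DataFrame):
    """Outcome density over candidate designs for the given (missing) rows.

    The candidate design columns follow ``all_covs`` ordering; returns
    (density callable, list of design columns).
    """
    if spec.kind == "fine_gray_cause1":
        all_covs = list(spec.covariate_names)
        dens = fg_density_factory(
            drawn_fits[0], rows[V].to_numpy(float), rows[EV1].to_numpy()
        )
        return dens, all_covs
    all_covs = list(dict.fromkeys(spec.cause1_covariates + spec.cause2_covariates))
    cols1 = np.array([all_covs.index(c) for c in spec.cause1_covariates])
    cols2 = np.array([all_covs.index(c) for c in spec.cause2_covariates])
    dens = cs_density_factory(
        drawn_fits[0],
        drawn_fits[1],
        rows[spec.time_col].to_numpy(float),
        rows[spec.status_col].to_numpy(),
        cols1,
        cols2,
    )
    return dens, all_covs


def _impute_one_dataset(
    data: pd.DataFrame,
    substantive: SubstantiveSpec,
    covariate_models: list[CovariateModelSpec],
    iterations: int,
    rng: np.random.Generator,
    diagnostics: dict,
) -> pd.DataFrame:
    completed = data.copy()
    miss_masks = {cm.target: data[cm.target].isna().to_numpy() for cm in covariate_models}
    # initialize missing cells from the observed marginal of each covariate
    for cm in covariate_models:
        mask = miss_masks[cm.target]
        observed = data.loc[~data[cm.target].isna(), cm.target].to_numpy()
        if observed.size == 0:
            raise ValueError(f"covariate {cm.target!r} has no observed values")
        completed.loc[mask, cm.target] = rng.choice(observed, size=int(mask.sum()))
    # visit sequence: ascending missingness fraction, ties by column order
    order = sorted(
        range(len(covariate_models)),
        key=lambda i: (miss_masks[covariate_models[i].target].mean(), i),
    )
    for _it in range(iterations):
        fits = _fit_substantive(completed, substantive)
        drawn = tuple(f.draw_parameters(rng) if f is not None else None for f in fits)
        for i in order:
            cm = covariate_models[i]
            mask = miss_masks[cm.target]
            if not mask.any():
                continue
            family = cm.make().fit(
                completed[cm.predictors].to_numpy(float),
                completed[cm.target].to_numpy(),
            )
            phi = family.draw(rng)
            rows = completed.loc[mask]
            dens, design_cols = _density_for_rows(substantive, drawn, rows)
            base_design = rows[design_cols].to_numpy(float)
            j = design_cols.index(cm.target)
            pred_X = rows[cm.predictors].to_numpy(float)

            if isinstance(family, LinearModel):

                def design_with_values(vals, base=base_design, j=j):
                    out = base.copy()
                    out[:, j] = vals
                    return out

                imputed, diag = impute_continuous_covariate(
                    dens,
                    lambda r, f=family, px=pred_X, p=phi: f.sample(px, p, r),
                    design_with_values,
                    rng,
                    int(mask.sum()),
                )
                diagnostics.setdefault(cm.target, []).append(diag)
            else:
                levels = family.levels_
                prior = family.probs(pred_X, phi)

                def design_for_level(lv, base=base_design, j=j):
                    out = base.copy()
                    out[:, j] = lv
                    return out

                imputed = impute_discrete_covariate(
                    levels, dens, prior, design_for_level, rng
                )
            completed.loc[mask, cm.target] = imputed
    return completed


def run_smcfcs(
    data: pd.DataFrame,
    substantive: SubstantiveSpec,
    covariate_models: list[CovariateModelSpec],
    m: int = 5,
    iterations: int = 20,
    rng: np.random.Generator | None = None,
) -> ImputationStack:
    """Chained substantive-model-compatible imputation.

    Produces ``m`` completed datasets.  Per dataset: initialize missing cells
    from observed marginals, then for each of ``iterations`` cycles (i) refit
    the substantive model(s) and take an approximate posterior draw (baseline
    recomputed by Breslow at the drawn coefficients), (ii) for each partially
    observed covariate refit its covariate model, draw its parameters, and
    re-impute its missing cells from the product density.  A diverging
    substantive fit restarts that dataset from a fresh initialization once.

    Internally rows are processed in index order, so the imputation stream is
    keyed by subject id rather than row position.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if substantive.kind == "fine_gray_cause1" and V not in data.columns:
        raise ValueError(
            "fine_gray_cause1 requires censoring-complete data with a 'v' column"
        )
    rng = rng or np.random.default_rng()
    sort_order = np.argsort(data.index.to_numpy(), kind="stable")
    work = data.iloc[sort_order]
    streams = rng.spawn(m)
    datasets = []
    diagnostics: dict = {}
    for s in streams:
        for attempt in range(2):
            try:
                completed = _impute_one_dataset(
                    work, substantive, covariate_models, iterations, s, diagnostics
                )
                break
            except ConvergenceError:
                if attempt == 1:
                    raise
                warnings.warn(
                    "substantive fit diverged mid-chain: restarting dataset once"
                )
        datasets.append(completed.loc[data.index])
    meta = {
        "m": m,
        "iterations": iterations,
        "substantive_kind": substantive.kind,
        "diagnostics": diagnostics,
    }
    return ImputationStack(datasets, meta)


class SMCFCSImputer(BaseEstimator):
    """sklearn-style wrapper around :func:`run_smcfcs`.

    Parameters
    ----------
    substantive_kind : 'fine_gray_cause1' or 'cause_specific'
    covariates : tuple of str
        Substantive-model covariates, in order.
    targets : tuple of (name, family) pairs
        Partially observed covariates and their model families; each target's
        covariate-model predictors are the remaining covariates.
    m, iterations : int
    random_state : int or None
    """

    def __init__(
        self,
        substantive_kind: str = "fine_gray_cause1",
        covariates: tuple = (),
        targets: tuple = (),
        m: int = 5,
        iterations: int = 20,
        random_state: int | None = None,
    ):
        self.substantive_kind = substantive_kind
        self.covariates = covariates
        self.targets = targets
        self.m = m
        self.iterations = iterations
        self.random_state = random_state

    def _specs(self):
        covs = list(self.covariates)
        substantive = SubstantiveSpec(self.substantive_kind, covs)
        models = [
            CovariateModelSpec(t, fam, [c for c in covs if c != t])
            for t, fam in self.targets
        ]
        return substantive, models

    def fit(self, data: pd.DataFrame, y=None):
        return self

    def transform(self, data: pd.DataFrame) -> ImputationStack:
        substantive, models = self._specs()
        return run_smcfcs(
            data,
            substantive,
            models,
            m=self.m,
            iterations=self.iterations,
            rng=np.random.default_rng(self.random_state),
        )

    def fit_transform(self, data: pd.DataFrame, y=None) -> ImputationStack:
        return self.fit(data).transform(data)
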