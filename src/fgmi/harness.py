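"""Simulation-study harness: scenario grid, replicates, performance measures.

One replicate runs the full pipeline: generate data under a scenario's
mechanism, apply censoring, induce missingness, impute potential censoring
times when censoring is random (shared across the covariate-imputation
methods so method contrasts are paired), impute the missing covariate with the
requested method, fit the Fine-Gray model as a Cox model on (V, I(D=1)) in
each completed dataset, and pool with Rubin's rules.

Performance measures follow standard simulation-study reporting: bias,
relative bias, empirical and average model SE, coverage, each with its Monte
Carlo standard error; and the number of replicates needed for a target
MCSE(bias) = empSE / sqrt(nsim).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .approx import ApproxImputer
from .cox import CoxPH
from .dgm import (
    CensoringSpec,
    CSHazardParams,
    FGCorrectParams,
    MissingnessSpec,
    apply_censoring,
    derive_least_false_cs_params,
    gen_cs_hazards,
    gen_fg_correct,
    induce_missingness,
    true_least_false_beta,
)
from .pooling import pool_cif, pool_coefficients
from .smc import SMCFCSImputer
from .subdist import (
    EV1,
    V,
    attach_cause_specific_hazards,
    impute_censoring_times,
    make_subdist_time_uncensored,
    recompute_subdist_hazard,
    CensoringModelSpec,
)

__all__ = [
    "Scenario",
    "ScenarioSetup",
    "METHODS",
    "required_nsim",
    "prepare_scenario",
    "run_replicate",
    "run_scenario",
    "summarize",
    "default_grid",
]

METHODS = ("full", "cca", "cs_smc", "cs_approx", "fg_smc", "fg_approx")


@dataclass
class Scenario:
    """One cell of the simulation grid."""

    mechanism: str = "fg_correct"  # or "cs_hazards"
    p: float = 0.15
    censoring: str = "none"  # none | administrative | random
    missingness: MissingnessSpec = field(default_factory=MissingnessSpec)
    n: int = 2000
    m: int = 30
    iterations: int = 20
    nsim: int = 500
    seed: int = 1
    censoring_model: CensoringModelSpec = field(default_factory=CensoringModelSpec)
    censoring_rate: float = 0.49

    def __post_init__(self):
        if self.mechanism not in ("fg_correct", "cs_hazards"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.censoring not in ("none", "administrative", "random"):
            raise ValueError(f"unknown censoring type {self.censoring!r}")

    @property
    def name(self) -> str:
        return f"{self.mechanism}_p{self.p:g}_{self.censoring}"

    def censoring_spec(self) -> CensoringSpec:
        kind = "administrative" if self.censoring == "administrative" else (
            "random" if self.censoring == "random" else "none"
        )
        return CensoringSpec(kind=kind, rate=self.censoring_rate)


@dataclass
class ScenarioSetup:
    """Per-scenario constants: generating parameters and true estimands."""

    fg_params: FGCorrectParams
    cs_params: CSHazardParams | None
    truth_beta: np.ndarray


def required_nsim(emp_se: float, mcse_target: float) -> int:
    """Replicates needed so MCSE(bias) = empSE / sqrt(nsim) <= target."""
    return math.ceil((emp_se / mcse_target) ** 2)


def prepare_scenario(
    scenario: Scenario, n_large: int = 200_000, rng: np.random.Generator | None = None
) -> ScenarioSetup:
    """Resolve generating parameters and the true (or least-false) betas.

    For the cause-specific mechanism the Weibull generating parameters are
    derived from the uncensored Fine-Gray-correct mechanism at scale, and the
    least-false coefficients are computed after applying the scenario's
    censoring with known censoring times.
    """
    rng = rng or np.random.default_rng(scenario.seed + 10_000)
    fg = FGCorrectParams(p=scenario.p)
    if scenario.mechanism == "fg_correct":
        return ScenarioSetup(fg, None, np.array([fg.beta1, fg.beta2]))
    cs = derive_least_false_cs_params(fg, n_large=n_large, censoring=None, rng=rng)
    cens = scenario.censoring_spec() if scenario.censoring != "none" else None
    truth = true_least_false_beta(cs, censoring=cens, n_large=n_large, rng=rng)
    return ScenarioSetup(fg, cs, truth)


def _generate(scenario: Scenario, setup: ScenarioSetup, rng) -> pd.DataFrame:
    if scenario.mechanism == "fg_correct":
        return gen_fg_correct(scenario.n, setup.fg_params, rng)
    return gen_cs_hazards(scenario.n, setup.cs_params, rng)


def _build_ccds(data: pd.DataFrame, scenario: Scenario, m: int, rng) -> list[pd.DataFrame]:
    """Censoring-complete datasets with all hazard columns attached."""
    data = attach_cause_specific_hazards(data)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if scenario.censoring == "random":
            return impute_censoring_times(
                data, m=m, rng=rng, spec=scenario.censoring_model
            )
        if scenario.censoring == "administrative":
            ccd = make_subdist_time_uncensored(
                data, "administrative", admin_times=data["c"].to_numpy(float)
            )
        else:
            ccd = make_subdist_time_uncensored(data, "no_censoring")
        return [recompute_subdist_hazard(ccd)]


def _fit_fg(completed: pd.DataFrame) -> CoxPH:
    return CoxPH(keep_data=True).fit(
        completed[["x", "z"]].to_numpy(float),
        (completed[V].to_numpy(float), completed[EV1].to_numpy()),
    )


def _completed_for_method(
    method: str,
    data_missing: pd.DataFrame,
    data_full: pd.DataFrame,
    ccds: list[pd.DataFrame],
    scenario: Scenario,
    rng,
) -> list[pd.DataFrame]:
    if method == "full":
        out = []
        for ccd in ccds:
            cc = ccd.copy()
            cc["x"] = data_full["x"].to_numpy()
            out.append(cc)
        return out
    if method == "cca":
        keep = ~data_missing["x"].isna().to_numpy()
        sub = data_missing.loc[keep]
        return _build_ccds(sub, scenario, len(ccds), rng)
    per_ccd_m = 1 if len(ccds) > 1 else scenario.m
    if method in ("fg_smc", "cs_smc"):
        imputer = SMCFCSImputer(
            substantive_kind=(
                "fine_gray_cause1" if method == "fg_smc" else "cause_specific"
            ),
            covariates=("x", "z"),
            targets=(("x", "logistic"),),
            m=per_ccd_m,
            iterations=scenario.iterations,
        )
    elif method in ("fg_approx", "cs_approx"):
        imputer = ApproxImputer(
            flavor="fg_approx" if method == "fg_approx" else "cs_approx",
            covariates=("x", "z"),
            targets=(("x", "logistic"),),
            m=per_ccd_m,
            iterations=1,
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    out = []
    for ccd in ccds:
        imputer.random_state = int(rng.integers(2**31))
        out.extend(imputer.fit_transform(ccd).datasets)
    return out


def run_replicate(
    scenario: Scenario,
    setup: ScenarioSetup,
    methods: tuple[str, ...],
    rep_index: int,
    compute_cif: bool = False,
    cif_grid: np.ndarray | None = None,
) -> dict:
    """Run one replicate for every requested method on shared data.

    All methods see the same generated dataset, the same missingness pattern
    and (except CCA, which re-applies the censoring step to its complete-case
    subset) the same imputed censoring times.
    """
    rng = np.random.default_rng([scenario.seed, rep_index])
    data_full = _generate(scenario, setup, rng)
    data_cens = apply_censoring(data_full, scenario.censoring_spec(), rng)
    data_miss = induce_missingness(data_cens, scenario.missingness, rng)
    n_ccd = scenario.m if scenario.censoring == "random" else 1
    ccds = _build_ccds(data_miss, scenario, n_ccd, rng)
    grid = (
        np.linspace(0, 5, 101) if cif_grid is None else np.asarray(cif_grid, float)
    )
    out: dict = {}
    for method in methods:
        completed = _completed_for_method(
            method, data_miss, data_cens, ccds, scenario, rng
        )
        fits = [_fit_fg(cc) for cc in completed]
        ests = np.array([f.coef_ for f in fits])
        variances = np.array([np.diag(f.covariance_) for f in fits])
        row: dict = {"method": method, "n_datasets": len(fits)}
        if len(fits) > 1:
            pooled = pool_coefficients(
                ests, variances, df_com=len(completed[0]) - ests.shape[1]
            )
            row.update(
                beta=pooled.estimate,
                se=pooled.se,
                ci_low=pooled.ci_low,
                ci_high=pooled.ci_high,
            )
        else:
            f = fits[0]
            se = np.sqrt(np.diag(f.covariance_))
            lo, hi = f.confidence_interval()
            row.update(beta=f.coef_, se=se, ci_low=lo, ci_high=hi)
        if compute_cif:
            for label, ref in (("00", (0.0, 0.0)), ("11", (1.0, 1.0))):
                curves = np.array([f.predict_cif(ref, grid) for f in fits])
                cvars = np.array([f.cif_variance(ref, grid) for f in fits])
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    pooled_cif = pool_cif(curves, cvars, times=grid)
                row[f"cif_{label}"] = pooled_cif.estimate
        out[method] = row
    return out


def run_scenario(
    scenario: Scenario,
    methods: tuple[str, ...] = METHODS,
    setup: ScenarioSetup | None = None,
    compute_cif: bool = False,
    progress: bool = False,
) -> dict:
    """Run ``scenario.nsim`` replicates; failed replicates are logged, not fatal."""
    setup = setup or prepare_scenario(scenario)
    results: dict = {m: [] for m in methods}
    failures: list[tuple[int, str]] = []
    for rep in range(scenario.nsim):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rows = run_replicate(scenario, setup, methods, rep, compute_cif)
        except Exception as err:  # noqa: BLE001 — any stage error fails the rep
            failures.append((rep, repr(err)))
            continue
        for m in methods:
            results[m].append(rows[m])
        if progress and (rep + 1) % 10 == 0:
            print(f"  replicate {rep + 1}/{scenario.nsim}", flush=True)
    return {
        "scenario": scenario,
        "setup": setup,
        "results": results,
        "failures": failures,
        "failed_fraction": len(failures) / max(scenario.nsim, 1),
    }


def summarize(run: dict, level: float = 0.95) -> pd.DataFrame:
    """Performance table: bias, relative bias %, empSE, modSE, coverage + MCSEs."""
    scenario: Scenario = run["scenario"]
    truth = run["setup"].truth_beta
    rows = []
    for method, reps in run["results"].items():
        if len(reps) < 2:
            continue
        est = np.array([r["beta"] for r in reps])
        se = np.array([r["se"] for r in reps])
        lo = np.array([r["ci_low"] for r in reps])
        hi = np.array([r["ci_high"] for r in reps])
        nsim = est.shape[0]
        for j, name in enumerate(("beta1", "beta2")):
            bias = est[:, j].mean() - truth[j]
            emp_se = est[:, j].std(ddof=1)
            mod_se = float(np.sqrt(np.mean(se[:, j] ** 2)))
            cover = float(np.mean((lo[:, j] <= truth[j]) & (truth[j] <= hi[:, j])))
            mcse_bias = emp_se / math.sqrt(nsim)
            rows.append(
                {
                    "scenario": scenario.name,
                    "method": method,
                    "estimand": name,
                    "truth": truth[j],
                    "nsim": nsim,
                    "bias": bias,
                    "mcse_bias": mcse_bias,
                    "rel_bias_pct": 100.0 * bias / truth[j],
                    "mcse_rel_bias_pct": 100.0 * mcse_bias / abs(truth[j]),
                    "emp_se": emp_se,
                    "mcse_emp_se": emp_se / math.sqrt(2 * (nsim - 1)),
                    "mod_se": mod_se,
                    "coverage": cover,
                    "mcse_coverage": math.sqrt(cover * (1 - cover) / nsim),
                    "rmse": float(
                        np.sqrt(np.mean((est[:, j] - truth[j]) ** 2))
                    ),
                }
            )
    return pd.DataFrame(rows)


def default_grid(nsim: int = 100, m: int = 10, seed: int = 1) -> list[Scenario]:
    """The 12-scenario grid: mechanism x p x censoring type."""
    out = []
    for mechanism in ("fg_correct", "cs_hazards"):
        for p in (0.15, 0.65):
            for censoring in ("none", "administrative", "random"):
                out.append(
                    Scenario(
                        mechanism=mechanism,
                        p=p,
                        censoring=censoring,
                        nsim=nsim,
                        m=m,
                        seed=seed,
                    )
                )
    return out
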