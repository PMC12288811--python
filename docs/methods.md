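# Methods

## Setting and notation

Subjects experience at most one of two competing events. We observe
`T = min(T~, C)` and `D ∈ {0, 1, 2}` (0 = censored), with fully observed
covariates `Z` and partially observed covariates `X`. Interest is in the
Fine–Gray model for the event of interest (cause 1),

    λ1(t | X, Z) = λ01(t) exp{β' (X, Z)},

equivalently `F1(t | X, Z) = 1 − {1 − F01(t)}^{exp(β'(X,Z))}` with
`F01(t) = 1 − exp{−Λ01(t)}` the baseline (covariates = 0) cumulative
incidence. The subdistribution time `V = I(D=1)·T + I(D≠1)·C` makes the
model an ordinary Cox model with outcome `(V, I(D=1))` whenever the
potential censoring time `C` is known for everyone ("censoring complete"
data).

## The imputation procedure

With random right-censoring, `C` is unknown for subjects failing from the
competing event; their `V` is coarsened. The package therefore proceeds
sequentially, which is valid when censoring is independent of `X` given the
`Z` included in the censoring model:

1. **Censoring-time imputation.** `G(t) = P(C > t)` is estimated by
   Kaplan–Meier (marginally or within strata) or by a Cox model on `Z`.
   For each subject failing from cause 2 at `T_i`, a potential censoring
   time is drawn from the conditional distribution
   `1 − G(t−)/G(T_i−)`, restricted to censoring-support knots strictly
   greater than `T_i`. Residual survival mass beyond the last knot is
   assigned to the last knot (treated as administrative); subjects whose
   failure time exceeds the entire censoring support receive the largest
   knot with a warning. Repeating this M times yields M censoring-complete
   datasets. The draws are not "proper" (no parameter draw for G); an
   optional bootstrap layer re-estimates G on a resample per imputation
   (off by default, matching common practice).
2. **Covariate imputation** in each censoring-complete dataset, by one of:
   * **FG-SMC** — substantive-model-compatible FCS with the Fine–Gray
     likelihood on `(V, I(D=1))`:
     `f(V, D | X, Z) = λ1(V|X,Z)^{I(D=1)} exp{−Λ1(V|X,Z)}`.
     Missing `X_j` is drawn from a density proportional to this likelihood
     times a covariate model `f(X_j | X_−j, Z; φ)`.
   * **CS-SMC** — the same scheme but compatible with two cause-specific
     Cox models:
     `f(T, D | X, Z) = h_D(T|X,Z)^{I(D>0)} exp{−H1(T|X,Z) − H2(T|X,Z)}`.
   * **FG-Approx** — MICE-style: a directly specified imputation model with
     predictors `X_−j, Z, I(D=1)` and the marginal Nelson–Aalen cumulative
     subdistribution hazard `Λ̂1(V)`.
   * **CS-Approx** — predictors `X_−j, Z`, `D` as indicator contrasts, and
     the marginal cause-specific cumulative hazards `Ĥ1(T), Ĥ2(T)`.
3. **Analysis and pooling.** The Fine–Gray model is fitted as a Cox model
   on `(V, I(D=1))` in each completed dataset; coefficients are pooled by
   Rubin's rules with Barnard–Rubin degrees of freedom (complete-data df
   `n − p`); predicted cumulative incidences are pooled after
   complementary log-log transformation with delta-method variances
   (predict-then-pool).

The FG-based methods rely on a missing-at-random assumption in terms of
`(V, I(D=1), X_obs, Z)`: missingness must not depend on the competing-event
indicator or on the failure time of cause-2 failures. Censoring models that
depend on partially observed `X` would require an iterative joint scheme and
are out of scope; censoring may depend on fully observed `Z`.

## Estimation primitives

* **Cox model.** Newton–Raphson with step-halving on the Breslow partial
  likelihood; convergence when the log-likelihood changes by < 1e-9, at most
  100 iterations; covariance from the inverse observed information; baseline
  cumulative hazard by the Breslow estimator at covariates exactly 0 (raw
  covariates, no centering). Breslow tie handling is used everywhere so the
  likelihood evaluated inside SMC imputation is exactly the quantity the fit
  maximizes. Non-convergence and coefficient divergence (|β| > 50,
  monotone likelihood) raise a flagged error carrying the iteration trace.
  The linear predictor is centered at its maximum inside the iterations to
  avoid overflow; the absolute risk sums used for the baseline and variance
  are computed unshifted.
* **CIF variance.** `Var{Λ̂(t|x)}` combines the Poisson-type Breslow
  baseline variance `Σ d_j/S0(t_j)²` with the coefficient contribution via
  the gradient `e^{β'x}{x Λ0(t) − Σ_{t_j≤t} d_j S1(t_j)/S0(t_j)²}` and the
  coefficient covariance; `Var(F̂)` follows by the delta method. This is an
  asymptotically standard estimator; its calibration is checked by a
  simulation test of 95% cloglog-interval coverage.
* **Parameter draws.** Approximate-Bayes draws: coefficients from
  `N(β̂, Cov)` (non-PSD covariances repaired by eigenvalue clipping, with a
  warning), with the Breslow baseline recomputed at the drawn coefficients
  on the retained fitting sample. No separate draw of the baseline is made
  — an approximation shared with standard SMC-FCS practice.

## SMC-FCS numerical choices

* Missing cells are initialized by draws from the observed marginal of each
  covariate; the chain default is 20 iterations, which dominates the
  initialization.
* Visit sequence: covariates in ascending missingness fraction, ties by
  column order. Internally rows are processed in (stable) index order, so
  imputation draws are keyed by subject id, not row position.
* Discrete targets are imputed by exact normalization of the product
  density over their levels — no rejection sampling. The baseline-jump
  factor `λ01(V)` (the Breslow jump at the subject's event time, with a
  nearest-prior-jump fallback) is retained even though it cancels in these
  ratios, so one code path serves both the FG and CS densities.
* Continuous targets use rejection sampling from the covariate model: the
  bound is the maximum outcome density over a 25-draw pre-sample inflated
  by 1.2, the attempt cap is 1000, and on hitting the cap the
  highest-product-density proposal seen is kept and counted in the
  diagnostics.
* A substantive fit that diverges mid-chain restarts that dataset once from
  a fresh initialization before failing.
* Covariate-model families: an in-package IRLS binary-logistic fit (with a
  1e-4 ridge fallback under separation), closed-form Gaussian linear
  regression with the standard draw of the residual variance from its
  scaled inverse chi-square, and statsmodels-backed multinomial and
  proportional-odds models. Approximate-compatibility (MICE) imputation
  defaults to predictive mean matching with 5 donors for continuous
  targets; FG-Approx optionally adds the `I(D=1) × Λ̂1(V)` interaction
  (off by default).

## Synthetic data generation

Covariates: `Z ~ N(0,1)`, `X | Z ~ Bernoulli(expit(Z))`. Two outcome
mechanisms (Weibull parametrization `F(t) = 1 − exp(−b t^a)`, shape `a`,
rate `b`):

* **Proportional subdistribution hazards (FG-correct).** The cause-1
  cumulative incidence is specified directly as
  `F1(t|X,Z) = 1 − [1 − p{1−exp(−b1 t^{a1})}]^{exp(β1 X + β2 Z)}` with
  defaults `β = (0.75, 0.5)`, shapes 0.75, rates 1, and `p ∈ {0.15, 0.65}`
  (the baseline cause-1 incidence at t = ∞). The cause indicator is drawn
  first (`P(cause 2 | X,Z) = (1−p)^{exp(β1X+β2Z)}`), then cause-1 times by
  the closed-form inverse transform of the conditional CDF and cause-2
  times by a Weibull-PH inverse transform given the cause
  (`β* = (0.75, 0.5)`, shape 0.75, rate 1).
* **Proportional cause-specific hazards.** Latent Weibull-PH failure times
  per cause, minimum taken. The generating parameters are the maximum
  likelihood Weibull-PH fits (per cause) to a large uncensored sample from
  the FG-correct mechanism, making the two worlds closely comparable at
  baseline; a Fine–Gray model is then misspecified and its target is the
  least-false (time-averaged) coefficient, computed by fitting the
  censoring-complete Cox representation on a fresh large sample after
  applying the scenario's censoring with known censoring times. The default
  derivation size is 200,000, chosen as a desk-scale compromise; Monte
  Carlo noise in the resulting targets is of order 0.01.

Censoring is exponential with rate 0.49 (≈30% censored under these
mechanisms), optionally covariate-dependent (`0.49·e^Z`), and marked
"known" in administrative scenarios. Missingness in `X` is logistic MAR:
on `Z` with slope 1.5, or on `log(T+1)` with slope −1.5 (outcome-dependent
variant); the intercept is root-solved (Gauss–Hermite quadrature over Z, or
an empirical average for the time-dependent variant; bracketing Brent,
tolerance 1e-8) so the average missingness probability is 0.4.

What the generator deliberately does not emulate: covariate measurement
error, more than two causes or more than one partially observed covariate
family per scenario, delayed entry, ties in continuous times, and
centre-level heterogeneity. Passing tests therefore demonstrate correctness
of the machinery under clean MAR mechanisms, not robustness to those
features of real registry data.

## Simulation harness

A scenario is mechanism × p × censoring type (12 cells). Per replicate the
methods (Full-data benchmark, complete-case analysis, CS-SMC, CS-Approx,
FG-SMC, FG-Approx) share the generated data, missingness pattern and
censoring-time imputations, so method contrasts are paired; complete-case
analysis re-applies the censoring step to its complete-case subset.
Replicate seeds derive from (scenario seed, replicate index), so any
replicate can be reproduced in isolation and replicates may run
concurrently. Failed replicates are caught, logged and reported as a
fraction. Performance measures: bias, relative bias (%), empirical SE,
average model SE, coverage, RMSE, each with the standard Monte Carlo
standard errors; the helper `required_nsim(emp_se, mcse_target)` gives the
replication count `(empSE/target)²`.

Desk-scale defaults are nsim=100 and M=10 imputed datasets (the study-scale
configuration nsim=500, M=30, 20 SMC iterations is available by flags);
the Monte Carlo SEs scale accordingly (√5 and √3 inflation).

## Known limitations

* The censoring-time imputer does not model censoring that depends on
  partially observed covariates; the weighted-likelihood alternative to
  censoring-time imputation is not implemented.
* Left truncation, interval censoring, time-varying effects, frailties and
  K > 2 causes are unsupported.
* Imputed censoring times are drawn without parameter uncertainty in G
  unless the bootstrap option is enabled; slight over-coverage of pooled
  intervals can result.
* The proportional-odds and multinomial covariate families delegate to
  statsmodels and are slower than the built-in logistic/linear paths.
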