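# fgmi — Fine–Gray-compatible multiple imputation of missing covariates

`fgmi` is a Python toolkit for competing-risks analyses in which the
substantive model is a Fine–Gray model for the subdistribution hazard of one
event of interest and some covariates have missing values. It is aimed at
biostatisticians building prognostic models on registry-style data (e.g.
transplant or oncology cohorts) where both competing events and missing
baseline covariates are the norm.

## The idea

The Fine–Gray model for cause 1,

    λ1(t | X, Z) = λ01(t) · exp{β'(X, Z)},
    F1(t | X, Z) = 1 − {1 − F01(t)}^{exp(β'(X,Z))},

is an ordinary Cox model for the subdistribution time
`V = I(D=1)·T + I(D≠1)·C` with event indicator `I(D=1)` — provided the
potential censoring time `C` is known for everyone. `fgmi` exploits this in
two sequential imputation steps:

1. **Impute potential censoring times** for subjects failing from the
   competing event, drawing from the conditional Kaplan–Meier censoring
   distribution `1 − Ĝ(t−)/Ĝ(T_i−)` (marginal, stratified, or Cox-based
   when censoring depends on fully observed covariates). This yields M
   censoring-complete datasets.
2. **Impute missing covariates** in each, either *compatibly* with the
   substantive model (SMC-FCS: sample `X_j` from a density ∝
   `λ1(V|X,Z)^{I(D=1)} exp{−Λ1(V|X,Z)} · f(X_j|X_−j,Z)`) or *approximately*
   (MICE-style, with `I(D=1)` and the Nelson–Aalen `Λ̂1(V)` as predictors).
   Cause-specific-hazards analogues (CS-SMC, CS-Approx) are included for
   comparison.

Fits across the completed datasets are pooled by Rubin's rules
(Barnard–Rubin df); cumulative incidence curves are pooled on the
complementary log-log scale. A synthetic-data module generates competing
risks data with proportional subdistribution or cause-specific hazards,
exponential censoring and calibrated MAR missingness, and a harness runs
the full method-comparison simulation grid.

## Worked example

```python
import numpy as np
from fgmi import (
    CensoringImputer, SMCFCSImputer, CoxPH, pool_coefficients,
    FGCorrectParams, CensoringSpec, MissingnessSpec,
    gen_fg_correct, apply_censoring, induce_missingness,
    attach_cause_specific_hazards,
)

rng = np.random.default_rng(1)

# synthetic cohort: 2000 subjects, ~30% censored, 40% of x missing (MAR on z)
data = gen_fg_correct(2000, FGCorrectParams(p=0.15), rng)      # true beta1 = 0.75
data = apply_censoring(data, CensoringSpec(kind="random", rate=0.49), rng)
data = induce_missingness(data, MissingnessSpec("mar_z"), rng)
data = attach_cause_specific_hazards(data)

# step 1: 10 censoring-complete datasets (Kaplan-Meier imputation)
ccds = CensoringImputer(m=10, random_state=2).fit_transform(data)

# step 2: Fine-Gray-compatible covariate imputation, one completion per ccd
completed = []
for i, ccd in enumerate(ccds):
    imputer = SMCFCSImputer(substantive_kind="fine_gray_cause1",
                            covariates=("x", "z"), targets=(("x", "logistic"),),
                            m=1, iterations=20, random_state=100 + i)
    completed.append(imputer.fit_transform(ccd).datasets[0])

# step 3: fit the Fine-Gray model as a Cox model on (v, ev1) and pool
fits = [CoxPH().fit(df[["x", "z"]].to_numpy(),
                    (df["v"].to_numpy(), df["ev1"].to_numpy()))
        for df in completed]
pooled = pool_coefficients(np.array([f.coef_ for f in fits]),
                           np.array([np.diag(f.covariance_) for f in fits]),
                           df_com=len(data) - 2)
for name, est, se, lo, hi in zip(["x", "z"], pooled.estimate, pooled.se,
                                 pooled.ci_low, pooled.ci_high):
    print(f"{name}: {est:.3f} (SE {se:.3f}, 95% CI {lo:.3f} to {hi:.3f})")
```

Output:

```
x: 0.880 (SE 0.189, 95% CI 0.497 to 1.262)
z: 0.451 (SE 0.062, 95% CI 0.329 to 0.573)
```

The pooled subdistribution log hazard ratios recover the generating values
(0.75 for `x`, 0.5 for `z`) within sampling error, despite 40% of `x`
being missing; the interval for `x` is wider than for the fully observed
`z`, reflecting the lost information.

The same pipeline is available from the shell:

```sh
fgmi simulate --n 2000 --seed 1 --out data.csv
fgmi impute --data data.csv --method fg-smc --m 10 --seed 2 --out stack/
fgmi pool --stack stack/ --out pooled.csv
fgmi bench --scenarios fg_correct_p0.15_none --nsim 20 --out bench.csv
```

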