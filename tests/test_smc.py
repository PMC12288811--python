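import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

import fgmi.smc as smc_mod
from fgmi.covmodels import CovariateModelSpec, LinearModel, LogisticModel
from fgmi.cox import CoxPH
from fgmi.smc import (
    SMCFCSImputer,
    SubstantiveSpec,
    discrete_full_conditional,
    impute_continuous_covariate,
    outcome_density_cs,
    outcome_density_fg,
    run_smcfcs,
)
from fgmi.stepfun import StepFunction
from fgmi.subdist import make_subdist_time_uncensored, recompute_subdist_hazard


def make_fit(coef, knots, values):
    """A proportional hazards fit with prescribed coefficients/baseline."""
    fit = CoxPH()
    fit.coef_ = np.atleast_1d(np.asarray(coef, float))
    fit.covariance_ = np.zeros((fit.coef_.size, fit.coef_.size))
    fit.covariate_names_ = [f"x{i}" for i in range(fit.coef_.size)]
    fit.baseline_cumhaz_ = StepFunction(knots, values)
    fit.n_events_ = len(knots)
    return fit


class TestOutcomeDensityFG:
    def test_no_event_before_first_knot_is_one(self):
        fit = make_fit([0.7], [2.0], [0.5])
        assert outcome_density_fg(1.0, 0, [3.0], fit) == pytest.approx(1.0)

    def test_zero_coef_censored_density_independent_of_x(self):
        fit = make_fit([0.0], [1.0], [0.4])
        d1 = outcome_density_fg(2.0, 0, [0.0], fit)
        d2 = outcome_density_fg(2.0, 0, [5.0], fit)
        assert d1 == pytest.approx(np.exp(-0.4))
        assert d1 == pytest.approx(d2)

    def test_hand_ratio_two_over_e(self):
        # ev1=1, Lambda01(V)=1, beta=ln 2: f(1)/f(0) = 2 e^-2 / e^-1 = 2/e
        fit = make_fit([np.log(2.0)], [1.0], [1.0])
        r = outcome_density_fg(1.0, 1, [1.0], fit) / outcome_density_fg(
            1.0, 1, [0.0], fit
        )
        assert r == pytest.approx(2.0 / np.e, abs=1e-12)

    def test_event_without_jump_uses_nearest_prior(self):
        fit = make_fit([0.0], [1.0, 2.0], [0.3, 0.9])
        # event at t=1.5 sits between knots; nearest prior jump is 0.3
        d = outcome_density_fg(1.5, 1, [0.0], fit)
        assert d == pytest.approx(0.3 * np.exp(-0.3))

    def test_event_before_any_jump_errors(self):
        fit = make_fit([0.0], [1.0], [0.3])
        with pytest.raises(ValueError, match="no baseline hazard jump"):
            outcome_density_fg(0.5, 1, [0.0], fit)


class TestOutcomeDensityCS:
    def test_censored_zero_hazard_is_one(self):
        f1 = make_fit([0.5], [2.0], [0.4])
        f2 = make_fit([0.2], [2.0], [0.3])
        assert outcome_density_cs(1.0, 0, [1.0], (f1, f2)) == pytest.approx(1.0)

    def test_zero_coefs_independent_of_x(self):
        f1 = make_fit([0.0], [1.0], [0.4])
        f2 = make_fit([0.0], [1.0], [0.3])
        d = [outcome_density_cs(2.0, 0, [xv], (f1, f2)) for xv in (0.0, 9.0)]
        assert d[0] == pytest.approx(np.exp(-0.7))
        assert d[0] == pytest.approx(d[1])

    def test_hand_cause1_ratio(self):
        # H1(T|x) = x ln 2 increments via beta1 = ln 2, Lambda01(T) = 1;
        # cause-2 model null with Lambda02(T) = 0.5
        f1 = make_fit([np.log(2.0)], [1.0], [1.0])
        f2 = make_fit([0.0], [1.0], [0.5])
        num = outcome_density_cs(1.0, 1, [1.0], (f1, f2))
        den = outcome_density_cs(1.0, 1, [0.0], (f1, f2))
        # hand: [2 e^{-2} e^{-0.5}] / [e^{-1} e^{-0.5}] = 2/e
        assert num / den == pytest.approx(2.0 / np.e, abs=1e-12)


class TestDiscreteFullConditional:
    def test_hand_normalized_probability(self):
        fit = make_fit([np.log(2.0)], [1.0], [1.0])
        dens = smc_mod.fg_density_factory(fit, np.array([1.0]), np.array([1]))
        probs = discrete_full_conditional(
            np.array([0.0, 1.0]),
            dens,
            np.array([[0.5, 0.5]]),
            lambda lv: np.array([[lv]]),
        )
        expected = (2 / np.e) / (1 + 2 / np.e)
        assert probs[0, 1] == pytest.approx(expected, abs=1e-12)
        assert probs[0, 1] == pytest.approx(0.4239, abs=1e-4)

    def test_flat_outcome_returns_prior(self):
        fit = make_fit([0.0], [1.0], [0.7])
        dens = smc_mod.fg_density_factory(fit, np.array([2.0]), np.array([0]))
        probs = discrete_full_conditional(
            np.array([0.0, 1.0]),
            dens,
            np.array([[0.3, 0.7]]),
            lambda lv: np.array([[lv]]),
        )
        np.testing.assert_allclose(probs, [[0.3, 0.7]], atol=1e-14)

    def test_degenerate_prior_forces_level(self, rng):
        fit = make_fit([1.0], [1.0], [0.5])
        dens = smc_mod.fg_density_factory(fit, np.array([2.0]), np.array([1]))
        from fgmi.smc import impute_discrete_covariate

        out = impute_discrete_covariate(
            np.array([0.0, 1.0]),
            dens,
            np.array([[0.0, 1.0]]),
            lambda lv: np.array([[lv]]),
            rng,
        )
        assert out[0] == 1.0


class TestContinuousRejection:
    def test_flat_outcome_reproduces_proposal(self, rng):
        n = 5000
        dens = lambda X: np.ones(X.shape[0])
        out, diag = impute_continuous_covariate(
            dens,
            lambda r: r.normal(1.0, 2.0, size=n),
            lambda vals: vals[:, None],
            rng,
            n,
        )
        assert diag["fallback_rows"] == 0
        ks = stats.kstest(out, stats.norm(1.0, 2.0).cdf)
        assert ks.pvalue > 0.01

    def test_matches_quadrature_normalized_product(self, rng):
        """Accepted draws follow outcome x proposal, against a grid oracle."""
        beta, lam = 0.6, 0.8
        n = 10_000

        def dens(X):
            x = X[:, 0]
            return np.exp(beta * x - lam * np.exp(beta * x))

        out, _ = impute_continuous_covariate(
            dens,
            lambda r: r.normal(0.5, 1.0, size=n),
            lambda vals: vals[:, None],
            rng,
            n,
        )
        grid = np.linspace(-5, 6, 4001)
        pdf = stats.norm(0.5, 1.0).pdf(grid) * np.exp(
            beta * grid - lam * np.exp(beta * grid)
        )
        cdf = integrate.cumulative_trapezoid(pdf, grid, initial=0)
        cdf /= cdf[-1]
        emp = np.searchsorted(np.sort(out), grid) / n
        assert np.max(np.abs(emp - cdf)) < 0.02

    def test_acceptance_rate_logged_in_unit_interval(self, rng):
        n = 200
        dens = lambda X: np.exp(-np.abs(X[:, 0]))
        _, diag = impute_continuous_covariate(
            dens, lambda r: r.normal(size=n), lambda v: v[:, None], rng, n
        )
        assert 0 < diag["acceptance_rate"] <= 1


def _fg_toy(rng, n=300, miss_frac=0.4):
    z = rng.normal(size=n)
    x = (rng.uniform(size=n) < 0.5).astype(float)
    t = rng.exponential(np.exp(-(0.5 * x + 0.3 * z)))
    d = (rng.uniform(size=n) < 0.7).astype(int)
    df = pd.DataFrame({"time": t, "status": d, "x": x, "z": z})
    ccd = make_subdist_time_uncensored(df, "no_censoring")
    ccd = recompute_subdist_hazard(ccd)
    miss = rng.uniform(size=n) < miss_frac
    ccd.loc[miss, "x"] = np.nan
    return ccd


class TestRunSMCFCS:
    def test_zero_missing_is_identity(self, rng):
        ccd = _fg_toy(rng, miss_frac=0.0)
        stack = run_smcfcs(
            ccd,
            SubstantiveSpec("fine_gray_cause1", ["x", "z"]),
            [CovariateModelSpec("x", "logistic", ["z"])],
            m=2,
            iterations=3,
            rng=rng,
        )
        for df in stack:
            pd.testing.assert_frame_equal(df, ccd)

    def test_observed_cells_bitwise_identical_across_stack(self, rng):
        ccd = _fg_toy(rng)
        obs = ~ccd["x"].isna()
        stack = run_smcfcs(
            ccd,
            SubstantiveSpec("fine_gray_cause1", ["x", "z"]),
            [CovariateModelSpec("x", "logistic", ["z"])],
            m=3,
            iterations=2,
            rng=rng,
        )
        for df in stack:
            assert not df["x"].isna().any()
            np.testing.assert_array_equal(
                df.loc[obs, "x"].to_numpy(), ccd.loc[obs, "x"].to_numpy()
            )

    def test_forced_flat_outcome_reduces_to_plain_fcs(self, rng, monkeypatch):
        """With the outcome factor forced to 1 the imputations are draws from
        the covariate model alone."""
        ccd = _fg_toy(rng, n=400)
        miss = ccd["x"].isna()

        def flat_factory(fit, v, ev1):
            return lambda X: np.ones(X.shape[0])

        monkeypatch.setattr(smc_mod, "fg_density_factory", flat_factory)
        imputed = []
        for seed in range(60):
            stack = run_smcfcs(
                ccd,
                SubstantiveSpec("fine_gray_cause1", ["x", "z"]),
                [CovariateModelSpec("x", "logistic", ["z"])],
                m=1,
                iterations=1,
                rng=np.random.default_rng(seed),
            )
            imputed.append(stack.datasets[0].loc[miss, "x"].to_numpy())
        imputed = np.concatenate(imputed)
        # oracle: logistic model of x on z fitted to observed rows
        obs = ~miss
        oracle = LogisticModel().fit(
            ccd.loc[obs, ["z"]].to_numpy(), ccd.loc[obs, "x"].to_numpy()
        )
        expected = oracle.probs(ccd.loc[miss, ["z"]].to_numpy())[:, 1]
        expected_mean = np.tile(expected, 60).mean()
        se = np.sqrt(expected_mean * (1 - expected_mean) / imputed.size) * 4
        assert abs(imputed.mean() - expected_mean) < se + 0.01

    def test_cs_on_single_event_data_equals_fg(self, rng):
        """With no competing events and V = T, CS-SMC and FG-SMC coincide."""
        ccd = _fg_toy(rng)  # status in {0, 1} only, v = time
        assert set(ccd["status"].unique()) <= {0, 1}
        fg = run_smcfcs(
            ccd,
            SubstantiveSpec("fine_gray_cause1", ["x", "z"]),
            [CovariateModelSpec("x", "logistic", ["z"])],
            m=2,
            iterations=3,
            rng=np.random.default_rng(77),
        )
        cs = run_smcfcs(
            ccd,
            SubstantiveSpec("cause_specific", ["x", "z"]),
            [CovariateModelSpec("x", "logistic", ["z"])],
            m=2,
            iterations=3,
            rng=np.random.default_rng(77),
        )
        for a, b in zip(fg.datasets, cs.datasets):
            np.testing.assert_array_equal(a["x"].to_numpy(), b["x"].to_numpy())

    def test_exchangeable_over_row_order(self, rng):
        ccd = _fg_toy(rng)
        perm = rng.permutation(len(ccd))
        shuffled = ccd.iloc[perm]
        a = run_smcfcs(
            ccd,
            SubstantiveSpec("fine_gray_cause1", ["x", "z"]),
            [CovariateModelSpec("x", "logistic", ["z"])],
            m=1,
            iterations=2,
            rng=np.random.default_rng(5),
        ).datasets[0]
        b = run_smcfcs(
            shuffled,
            SubstantiveSpec("fine_gray_cause1", ["x", "z"]),
            [CovariateModelSpec("x", "logistic", ["z"])],
            m=1,
            iterations=2,
            rng=np.random.default_rng(5),
        ).datasets[0]
        np.testing.assert_array_equal(
            a["x"].to_numpy(), b.loc[a.index, "x"].to_numpy()
        )

    def test_requires_v_column_for_fg(self, rng):
        df = pd.DataFrame({"time": [1.0, 2.0], "status": [1, 0], "x": [1.0, np.nan],
                           "z": [0.0, 1.0]})
        with pytest.raises(ValueError, match="censoring-complete"):
            run_smcfcs(
                df,
                SubstantiveSpec("fine_gray_cause1", ["x", "z"]),
                [CovariateModelSpec("x", "logistic", ["z"])],
                m=1,
                iterations=1,
                rng=rng,
            )


def test_imputer_estimator_api(rng):
    ccd = _fg_toy(rng)
    imp = SMCFCSImputer(
        covariates=("x", "z"), targets=(("x", "logistic"),), m=2, iterations=2,
        random_state=0,
    )
    stack = imp.fit_transform(ccd)
    assert len(stack) == 2
    again = imp.fit_transform(ccd)
    for a, b in zip(stack, again):
        pd.testing.assert_frame_equal(a, b)
    assert imp.get_params()["m"] == 2
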