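import numpy as np
import pytest
from scipy import stats

from fgmi.dgm import (
    CensoringSpec,
    CSHazardParams,
    FGCorrectParams,
    MissingnessSpec,
    apply_censoring,
    calibrate_missingness,
    derive_least_false_cs_params,
    fg_conditional_cdf,
    fg_inverse_transform,
    fit_weibull_ph,
    gen_covariates,
    gen_cs_hazards,
    gen_fg_correct,
    induce_missingness,
    true_cif,
)
from fgmi.dgm import _expit


class TestCovariates:
    def test_marginal_mean_of_x_is_half(self):
        rng = np.random.default_rng(0)
        x, z = gen_covariates(100_000, rng)
        # E[expit(Z)] = 1/2 by symmetry of expit around Z=0
        assert abs(x.mean() - 0.5) < 3 * 0.5 / np.sqrt(100_000)
        assert abs(z.mean()) < 3 / np.sqrt(100_000)
        assert abs(z.var() - 1) < 0.02

    def test_n_validation(self, rng):
        with pytest.raises(ValueError):
            gen_covariates(0, rng)


class TestFGCorrect:
    def test_inverse_transform_boundaries(self):
        params = FGCorrectParams(p=0.3)
        assert fg_inverse_transform(0.0, 0.7, params) == pytest.approx(0.0)

    def test_printed_inverse_value_round_trip(self):
        params = FGCorrectParams(p=0.65)
        t = fg_inverse_transform(0.5, 0.0, params)
        assert t == pytest.approx(0.6134, abs=1e-4)
        assert fg_conditional_cdf(t, 0.0, params) == pytest.approx(0.5, abs=1e-10)

    @pytest.mark.parametrize("p", [0.15, 0.65])
    def test_round_trip_uniformity(self, p):
        """CDF evaluated at generated cause-1 times is Uniform(0,1) (KS)."""
        rng = np.random.default_rng(1)
        params = FGCorrectParams(p=p)
        data = gen_fg_correct(30_000, params, rng)
        is1 = data["status"] == 1
        sub = data[is1].head(10_000)
        eta = params.beta1 * sub["x"].to_numpy() + params.beta2 * sub["z"].to_numpy()
        u = fg_conditional_cdf(sub["time"].to_numpy(), eta, params)
        assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_cause_probabilities_by_stratum(self):
        """P(cause 2 | X, Z) = (1-p)^{exp(b1 X + b2 Z)} on covariate strata."""
        rng = np.random.default_rng(2)
        params = FGCorrectParams(p=0.15)
        n = 50_000
        x = rng.integers(0, 2, size=n).astype(float)
        z = np.zeros(n)
        data = gen_fg_correct(n, params, rng, covariates=(x, z))
        for xv in (0.0, 1.0):
            sub = data[data["x"] == xv]
            expected = (1 - params.p) ** np.exp(params.beta1 * xv)
            se = np.sqrt(expected * (1 - expected) / len(sub))
            assert abs((sub["status"] == 2).mean() - expected) < 3 * se

    def test_baseline_cause1_fraction_is_p(self):
        rng = np.random.default_rng(3)
        params = FGCorrectParams(p=0.15)
        n = 50_000
        data = gen_fg_correct(
            n, params, rng, covariates=(np.zeros(n), np.zeros(n))
        )
        frac = (data["status"] == 1).mean()
        assert abs(frac - 0.15) < 3 * np.sqrt(0.15 * 0.85 / n)


class TestCSHazards:
    def test_symmetric_causes_split_evenly(self):
        rng = np.random.default_rng(4)
        params = CSHazardParams(0.75, 1.0, 0.0, 0.0, 0.75, 1.0, 0.0, 0.0)
        data = gen_cs_hazards(100_000, params, rng)
        assert abs((data["status"] == 1).mean() - 0.5) < 3 * 0.5 / np.sqrt(100_000)

    def test_marginal_weibull_when_other_cause_negligible(self):
        rng = np.random.default_rng(5)
        params = CSHazardParams(1.3, 0.8, 0.0, 0.0, 1.0, 1e-9, 0.0, 0.0)
        data = gen_cs_hazards(10_000, params, rng)
        assert (data["status"] == 1).all()
        # F(t) = 1 - exp(-b t^a): Weibull with scale b^(-1/a), shape a
        dist = stats.weibull_min(c=1.3, scale=0.8 ** (-1 / 1.3))
        assert stats.kstest(data["time"], dist.cdf).pvalue > 0.01

    def test_crude_incidence_matches_quadrature(self):
        rng = np.random.default_rng(6)
        params = CSHazardParams(0.9, 0.7, 0.3, 0.1, 1.1, 0.5, -0.2, 0.4)
        n = 100_000
        data = gen_cs_hazards(n, params, rng, covariates=(np.ones(n), np.zeros(n)))
        t_star = 2.0
        emp = ((data["status"] == 1) & (data["time"] <= t_star)).mean()
        truth = true_cif(params, "cs_hazards", 1.0, 0.0, np.array([t_star]))[0]
        assert abs(emp - truth) < 3 * np.sqrt(truth * (1 - truth) / n)


class TestCensoring:
    def test_none_is_identity(self, rng):
        data = gen_fg_correct(100, FGCorrectParams(), rng)
        out = apply_censoring(data, CensoringSpec(kind="none"), rng)
        assert out.equals(data)

    def test_exponential_mean(self, rng):
        data = gen_fg_correct(50_000, FGCorrectParams(), rng)
        data["time"] = 1e9  # never fail: observed time is the censoring time
        out = apply_censoring(data, CensoringSpec(kind="administrative"), rng)
        assert out["c"].mean() == pytest.approx(1 / 0.49, rel=0.02)
        assert (out["status"] == 0).all()

    def test_administrative_keeps_known_time_column(self, rng):
        data = gen_fg_correct(200, FGCorrectParams(), rng)
        out = apply_censoring(data, CensoringSpec(kind="administrative"), rng)
        assert "c" in out.columns
        assert np.all(out["time"] <= out["c"] + 1e-12)

    def test_covariate_dependent_rate(self):
        rng = np.random.default_rng(7)
        n = 200_000
        data = gen_fg_correct(n, FGCorrectParams(), rng)
        data["time"] = 1e9
        out = apply_censoring(
            data, CensoringSpec(kind="covariate_dependent", rate=0.49), rng
        )
        # E[C | Z] = 1 / (0.49 e^Z): check on a Z stratum
        sel = np.abs(out["z"]) < 0.05
        assert out.loc[sel, "time"].mean() == pytest.approx(1 / 0.49, rel=0.05)


class TestMissingness:
    def test_closed_form_when_slope_zero(self):
        spec = MissingnessSpec("mar_z", eta1=0.0, target_rate=0.4)
        assert calibrate_missingness(spec) == pytest.approx(
            np.log(0.4 / 0.6), abs=1e-10
        )

    def test_monotone_in_target_rate(self):
        lo = calibrate_missingness(MissingnessSpec("mar_z", target_rate=0.2))
        hi = calibrate_missingness(MissingnessSpec("mar_z", target_rate=0.6))
        assert lo < hi

    def test_quadrature_matches_monte_carlo(self):
        spec = MissingnessSpec("mar_z")
        eta0 = calibrate_missingness(spec)
        rng = np.random.default_rng(8)
        z = rng.normal(size=200_000)
        mc = _expit(eta0 + 1.5 * z).mean()
        assert abs(mc - 0.4) < 3 * 0.5 / np.sqrt(200_000)

    def test_mar_t_calibration_on_reference_sample(self, rng):
        data = gen_fg_correct(50_000, FGCorrectParams(), rng)
        spec = MissingnessSpec("mar_t")
        eta0 = calibrate_missingness(spec, reference=data["time"].to_numpy())
        rate = _expit(eta0 - 1.5 * np.log(data["time"].to_numpy() + 1)).mean()
        assert rate == pytest.approx(0.4, abs=1e-6)

    def test_missingness_independent_of_x_given_z(self):
        """The MAR-on-Z mechanism leaves no partial association with X."""
        import statsmodels.api as sm

        rng = np.random.default_rng(9)
        data = gen_fg_correct(100_000, FGCorrectParams(), rng)
        out = induce_missingness(data, MissingnessSpec("mar_z"), rng)
        r = out["x"].isna().astype(float)
        X = sm.add_constant(
            np.column_stack([data["x"].to_numpy(), data["z"].to_numpy()])
        )
        fit = sm.Logit(r, X).fit(disp=0)
        assert abs(np.asarray(fit.params)[1]) < 3 * np.asarray(fit.bse)[1]
        assert abs(out["x"].isna().mean() - 0.4) < 0.01


class TestLeastFalse:
    def test_weibull_ph_self_consistency(self):
        """ML recovery of generating parameters on exactly Weibull-PH data."""
        rng = np.random.default_rng(10)
        params = CSHazardParams(0.75, 1.0, 0.75, 0.5, 0.75, 1.0, 0.3, 0.2)
        data = gen_cs_hazards(100_000, params, rng)
        a, b, g = fit_weibull_ph(
            data["time"].to_numpy(),
            (data["status"] == 1).to_numpy(float),
            data[["x", "z"]].to_numpy(),
        )
        assert a == pytest.approx(0.75, abs=0.02)
        assert b == pytest.approx(1.0, abs=0.03)
        np.testing.assert_allclose(g, [0.75, 0.5], atol=0.03)

    def test_deterministic_given_seed(self):
        fg = FGCorrectParams(p=0.3)
        a = derive_least_false_cs_params(fg, 20_000, rng=np.random.default_rng(1))
        b = derive_least_false_cs_params(fg, 20_000, rng=np.random.default_rng(1))
        assert a == b

    def test_derived_cifs_overlay_fg_cifs(self):
        """The cause-specific world mimics the Fine-Gray world closely at
        baseline (max |dF01| < 0.02 on [0, 5]); away from baseline the two
        mechanisms genuinely diverge somewhat (quadrature shows ~0.03-0.04 at
        covariates (1, 1)), so only comparability is asserted there."""
        fg = FGCorrectParams(p=0.15)
        cs = derive_least_false_cs_params(fg, 200_000, rng=np.random.default_rng(11))
        times = np.linspace(0.1, 5, 25)
        f_fg0 = true_cif(fg, "fg_correct", 0.0, 0.0, times)
        f_cs0 = true_cif(cs, "cs_hazards", 0.0, 0.0, times)
        assert np.max(np.abs(f_fg0 - f_cs0)) < 0.02
        f_fg1 = true_cif(fg, "fg_correct", 1.0, 1.0, times)
        f_cs1 = true_cif(cs, "cs_hazards", 1.0, 1.0, times)
        assert np.max(np.abs(f_fg1 - f_cs1)) < 0.05


class TestTrueCIF:
    def test_zero_at_origin(self):
        assert true_cif(FGCorrectParams(), "fg_correct", 1.0, 1.0, np.array([0.0]))[0] == 0.0

    def test_fg_limit_is_p_at_baseline(self):
        f = true_cif(FGCorrectParams(p=0.15), "fg_correct", 0.0, 0.0, np.array([1e9]))
        assert f[0] == pytest.approx(0.15, abs=1e-12)

    def test_cs_total_failure_below_one_and_single_cause_identity(self):
        params = CSHazardParams(0.9, 0.7, 0.3, 0.1, 1.1, 0.5, -0.2, 0.4)
        times = np.linspace(0.2, 5, 10)
        f1 = true_cif(params, "cs_hazards", 0.5, 0.5, times, cause=1)
        f2 = true_cif(params, "cs_hazards", 0.5, 0.5, times, cause=2)
        assert np.all(f1 + f2 <= 1 + 1e-9)
        # with cause 2 removed, F1 = 1 - exp(-H1)
        solo = CSHazardParams(0.9, 0.7, 0.3, 0.1, 1.1, 1e-12, 0.0, 0.0)
        f1_solo = true_cif(solo, "cs_hazards", 0.5, 0.5, times, cause=1)
        h1 = 0.7 * times**0.9 * np.exp(0.3 * 0.5 + 0.1 * 0.5)
        np.testing.assert_allclose(f1_solo, 1 - np.exp(-h1), atol=1e-6)


def test_parameter_validation():
    with pytest.raises(ValueError):
        FGCorrectParams(p=1.2)
    with pytest.raises(ValueError):
        CSHazardParams(-1, 1, 0, 0, 1, 1, 0, 0)
    with pytest.raises(ValueError):
        MissingnessSpec("bad")
    with pytest.raises(ValueError):
        CensoringSpec(kind="random", rate=-1)
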