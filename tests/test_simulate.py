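"""Data generation, the profile-ML fitter, and the Monte-Carlo harness."""

import math

import numpy as np
import pytest

from crtsubgroup import (
    DesignParams,
    EffectSpec,
    ModelParams,
    SimScenario,
    fit_lmm,
    generate_subgroup,
    omega_delta,
    power_ate,
    power_iut,
    power_omnibus,
    run_scenario,
    simulate_trial,
)
from crtsubgroup.simulate import reproduce_tables
from crtsubgroup.simulate import test_iut as iut_decision
from crtsubgroup.simulate import test_omnibus as omnibus_decision


def _anova_icc(s: np.ndarray) -> float:
    # one-way ANOVA estimator of the ICC of a (n, m) cluster matrix
    n, m = s.shape
    grand = s.mean()
    msb = m * ((s.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msw = ((s - s.mean(axis=1, keepdims=True)) ** 2).sum() / (n * (m - 1))
    return (msb - msw) / (msb + (m - 1) * msw)


class TestSubgroupGenerator:
    def test_beta_binomial_moment_recovery(self, rng):
        d = DesignParams(m=20, n=10_000, p1=0.5, rho_s=0.25)
        s, p = generate_subgroup(d, rng)
        se_mean = math.sqrt(0.25 / s.size)
        assert s.mean() == pytest.approx(0.5, abs=3 * se_mean)
        assert _anova_icc(s) == pytest.approx(0.25, abs=0.02)
        assert p.shape == (10_000,)

    def test_cluster_level_shares_one_label(self, rng):
        d = DesignParams(m=15, n=200, p1=0.4, rho_s=1.0)
        s, _ = generate_subgroup(d, rng)
        assert (s.min(axis=1) == s.max(axis=1)).all()

    def test_independent_limit_has_no_cluster_structure(self, rng):
        d = DesignParams(m=20, n=5_000, p1=0.3, rho_s=0.0)
        s, _ = generate_subgroup(d, rng)
        assert abs(_anova_icc(s)) < 0.01


class TestOutcomeGeneratorAndFitter:
    def test_noise_free_outcomes_recover_coefficients_exactly(self, rng):
        d = DesignParams(m=8, n=12, p1=0.5, rho_y=0.0, rho_s=0.2)
        model = ModelParams(
            effect=EffectSpec(0.2, 0.3), sigma_b2=0.0, sigma_e2=1.0,
            beta1=0.4, beta3=0.15,
        )
        data = simulate_trial(d, model, rng)
        # replace residual noise with zero: outcome equals linear predictor
        mean = (
            model.beta1
            + model.effect.beta2 * data.z[:, None]
            + model.beta3 * data.s
            + model.effect.beta4 * data.z[:, None] * data.s
        )
        noise_free = type(data)(z=data.z, s=data.s, y=mean)
        fit = fit_lmm(noise_free)
        assert fit.converged
        assert fit.beta_hat == pytest.approx(
            [0.4, 0.2, 0.15, 0.1], abs=1e-8
        )
        assert fit.sigma_b2_hat + fit.sigma_e2_hat == pytest.approx(0.0, abs=1e-10)

    def test_outcome_icc_recovery(self, rng):
        d = DesignParams(m=20, n=3_000, rho_y=0.1, rho_s=0.0)
        model = ModelParams.from_design(d, EffectSpec(0.0, 0.0), beta3=0.0)
        data = simulate_trial(d, model, rng)
        assert _anova_icc(data.y) == pytest.approx(0.1, abs=0.02)

    def test_fit_matches_statsmodels_ml(self, rng):
        statsmodels = pytest.importorskip("statsmodels.api")
        d = DesignParams(m=10, n=30, p1=0.4, rho_y=0.1, rho_s=0.2)
        model = ModelParams.from_design(d, EffectSpec(0.3, 0.5))
        data = simulate_trial(d, model, rng)
        fit = fit_lmm(data)
        df = data.to_frame()
        df["zs"] = df.z * df.s
        ml = statsmodels.MixedLM.from_formula(
            "y ~ z + s + zs", groups="cluster", data=df
        ).fit(reml=False)
        assert fit.beta_hat == pytest.approx(ml.fe_params.values, abs=1e-5)
        assert fit.sigma_b2_hat == pytest.approx(
            float(ml.cov_re.iloc[0, 0]), abs=1e-5
        )
        assert fit.sigma_e2_hat == pytest.approx(ml.scale, abs=1e-5)

    def test_ols_limit_without_clustering(self):
        d = DesignParams(m=6, n=40, rho_y=0.0, rho_s=0.0)
        model = ModelParams.from_design(d, EffectSpec(0.2, 0.4))
        data = simulate_trial(d, model, np.random.default_rng(0))
        fit = fit_lmm(data)
        # this realization estimates the ICC at exactly zero, where the GLS
        # fit must collapse to ordinary least squares
        assert fit.sigma_b2_hat == 0.0
        df = data.to_frame()
        x = np.column_stack(
            [np.ones(len(df)), df.z, df.s, df.z * df.s]
        )
        beta_ols, *_ = np.linalg.lstsq(x, df.y.values, rcond=None)
        assert fit.beta_hat == pytest.approx(beta_ols, abs=1e-10)

    def test_estimator_covariance_matches_closed_form(self):
        # links the simulation to the variance algebra: empirical covariance
        # of the fitted subgroup effects across replicates vs the formula;
        # n is kept moderately large so the design-stage (known-variance)
        # formula is accurate for the ML fit with estimated components
        d = DesignParams(m=10, n=40, p1=0.5, rho_y=0.05, rho_s=0.25)
        model = ModelParams.from_design(d, EffectSpec(0.0, 0.0))
        reps = 2_000
        deltas = np.empty((reps, 2))
        streams = np.random.SeedSequence(777).spawn(reps)
        for i, ss in enumerate(streams):
            data = simulate_trial(d, model, np.random.default_rng(ss))
            deltas[i] = fit_lmm(data).delta_hat
        emp = np.cov(deltas.T)
        cov = omega_delta(d)
        se_var0 = cov.var0 * math.sqrt(2 / (reps - 1))
        se_var1 = cov.var1 * math.sqrt(2 / (reps - 1))
        se_cov = math.sqrt((cov.var0 * cov.var1 + cov.cov**2) / (reps - 1))
        assert emp[0, 0] == pytest.approx(cov.var0, abs=3 * se_var0)
        assert emp[1, 1] == pytest.approx(cov.var1, abs=3 * se_var1)
        assert emp[0, 1] == pytest.approx(cov.cov, abs=3 * se_cov)


class TestTestStatistics:
    def _converged_fit(self, rng):
        d = DesignParams(m=10, n=20, rho_y=0.05, rho_s=0.2)
        model = ModelParams.from_design(d, EffectSpec(0.3, 0.4))
        return fit_lmm(simulate_trial(d, model, rng)), d

    def test_zero_estimate_never_rejects(self, rng):
        fit, d = self._converged_fit(rng)
        zeroed = type(fit)(
            beta_hat=np.array([0.0, 0.0, 0.1, 0.0]),
            sigma_b2_hat=fit.sigma_b2_hat,
            sigma_e2_hat=fit.sigma_e2_hat,
            omega_hat=fit.omega_hat,
            converged=True,
        )
        reject, fstat = omnibus_decision(zeroed, d)
        assert fstat == 0.0 and not reject

    def test_iut_requires_both_effects_positive(self, rng):
        fit, d = self._converged_fit(rng)
        negative = type(fit)(
            beta_hat=np.array([0.0, -0.5, 0.1, 1.0]),
            sigma_b2_hat=fit.sigma_b2_hat,
            sigma_e2_hat=fit.sigma_e2_hat,
            omega_hat=fit.omega_hat,
            converged=True,
        )
        reject, (z0, z1) = iut_decision(negative, d)
        assert z0 < 0 and not reject


class TestScenarioDriver:
    def test_zero_replicates_rejected(self, table1_design, table1_effect):
        d = table1_design.with_n(44)
        model = ModelParams.from_design(d, table1_effect)
        with pytest.raises(ValueError):
            run_scenario(SimScenario(d, model, "omnibus", reps=0))

    def test_reproducible_given_master_seed(self, table1_design, table1_effect):
        d = table1_design.with_n(44)
        model = ModelParams.from_design(d, table1_effect)
        sc = SimScenario(d, model, "omnibus", "alternative", reps=50, master_seed=9)
        assert run_scenario(sc) == run_scenario(sc)

    def test_omnibus_empirical_power_tracks_prediction(
        self, table1_design, table1_effect
    ):
        d = table1_design.with_n(44)
        model = ModelParams.from_design(d, table1_effect)
        emp = run_scenario(
            SimScenario(d, model, "omnibus", "alternative", reps=500, master_seed=11)
        )
        pred = power_omnibus(d, table1_effect).power
        assert emp.rejection_rate == pytest.approx(pred, abs=3 * emp.mc_se)
        assert emp.convergence_rate == 1.0

    def test_omnibus_empirical_size_in_band(self, table1_design, table1_effect):
        d = table1_design.with_n(44)
        model = ModelParams.from_design(d, table1_effect)
        emp = run_scenario(
            SimScenario(d, model, "omnibus", "null", reps=500, master_seed=12)
        )
        se = math.sqrt(0.05 * 0.95 / 500)
        assert emp.rejection_rate == pytest.approx(0.05, abs=3 * se)

    def test_iut_size_conservative_at_small_cluster_size(
        self, table1_design, table2_effect
    ):
        # boundary null (Delta0 = 0, interaction retained): the test is valid
        # and markedly conservative for m = 20
        d = table1_design.with_n(38)
        model = ModelParams.from_design(d, table2_effect)
        emp = run_scenario(
            SimScenario(d, model, "iut", "null", reps=500, master_seed=13)
        )
        assert emp.rejection_rate <= 0.060

    def test_iut_empirical_power_tracks_prediction(
        self, table1_design, table2_effect
    ):
        d = table1_design.with_n(38)
        model = ModelParams.from_design(d, table2_effect)
        emp = run_scenario(
            SimScenario(d, model, "iut", "alternative", reps=500, master_seed=14)
        )
        pred = power_iut(d, table2_effect).power
        assert emp.rejection_rate == pytest.approx(pred, abs=3 * emp.mc_se)

    def test_nuisance_coefficients_do_not_move_power(
        self, table1_design, table1_effect
    ):
        # intercept and subgroup main effect are power-neutral by theory
        d = table1_design.with_n(44)
        base = ModelParams.from_design(d, table1_effect, beta1=0.0, beta3=0.15)
        moved = ModelParams.from_design(d, table1_effect, beta1=3.0, beta3=-1.0)
        e1 = run_scenario(SimScenario(d, base, "omnibus", reps=400, master_seed=21))
        e2 = run_scenario(SimScenario(d, moved, "omnibus", reps=400, master_seed=22))
        se = math.sqrt(2) * max(e1.mc_se, e2.mc_se)
        assert e1.rejection_rate == pytest.approx(e2.rejection_rate, abs=3 * se)

    def test_ate_power_against_simulation(self):
        # the companion ATE calculator agrees with a direct Wald-test MC run
        # on a moderate design; the ATE is a weighted combination of the two
        # subgroup effects, so its variance comes from the fitted covariance
        d = DesignParams(m=10, n=30, p1=0.36, rho_y=0.04, rho_s=0.2)
        e = EffectSpec(0.4, 0.3)
        model = ModelParams.from_design(d, e)
        from scipy import stats

        reps = 1_000
        crit = stats.t.ppf(0.95, d.df)
        rej = 0
        for ss in np.random.SeedSequence(31).spawn(reps):
            fit = fit_lmm(simulate_trial(d, model, np.random.default_rng(ss)))
            delta = fit.delta_hat
            ate_hat = (1 - d.p1) * delta[0] + d.p1 * delta[1]
            m2 = fit.omega_hat.matrix
            w = np.array([1 - d.p1, d.p1])
            var_hat = float(w @ m2 @ w)
            rej += int(ate_hat / math.sqrt(var_hat) > crit)
        emp = rej / reps
        pred = power_ate(d, e).power
        se = math.sqrt(max(emp * (1 - emp), 0.05) / reps)
        assert emp == pytest.approx(pred, abs=3.5 * se)


class TestReproduceTables:
    def test_single_cell_consistency(self, table1_design, table1_effect):
        df = reproduce_tables(
            "omnibus", m_values=[20], rho_y_values=[0.02], rho_s_values=[0.10]
        )
        assert len(df) == 1
        row = df.iloc[0]
        assert row.n == 44 and row.n_c == 48
        assert row.pred_power == pytest.approx(0.806, abs=5e-4)

    def test_unknown_test_rejected(self):
        with pytest.raises(ValueError):
            reproduce_tables("wilcoxon")
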