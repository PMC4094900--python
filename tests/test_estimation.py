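"""SAEM estimation, marginal likelihood, BIC, Wald tests, standard errors."""

import dataclasses
import math
import warnings

import numpy as np
import pandas as pd
import pytest
from numpy.polynomial.hermite_e import hermegauss
from scipy.special import logsumexp

from gaucher_ert.estimation import (
    FitSettings,
    LikelihoodProblem,
    bic,
    compare_models,
    fit_laplace,
    fit_saem,
    loglik_is,
    parameter_table,
    standard_errors,
    wald_p,
)
from gaucher_ert.population_model import (
    observation_loglik,
    prior_log_means,
)
from _helpers import platelet_cohort, platelet_model, platelet_template

warnings.filterwarnings("ignore", message="SAEM trace")

FAST = FitSettings(seed=0, n_burnin=150, n_smoothing=100, compute_loglik=False)


class TestBicAndWald:
    def test_bic_formula(self):
        assert bic(-100.0, 5, 100) == pytest.approx(200 + 5 * math.log(100))
        assert bic(-50.0, 0, 10) == pytest.approx(100.0)
        assert bic(-50.0, 7, 1) == pytest.approx(100.0)

    def test_bic_rejects_empty(self):
        with pytest.raises(ValueError):
            bic(-1.0, 1, 0)

    def test_wald_examples(self):
        assert wald_p(0.0, 1.0) == pytest.approx(1.0)
        assert wald_p(1.959964, 1.0) == pytest.approx(0.05, abs=1e-6)
        assert wald_p(-0.7, 0.2) == pytest.approx(wald_p(0.7, 0.2))

    def test_wald_rejects_bad_se(self):
        with pytest.raises(ValueError):
            wald_p(1.0, 0.0)

    def test_rse_definition(self):
        # RSE% = 100 * se / |estimate|: 0.154 / 1.4 -> 11%
        assert 100 * 0.154 / 1.4 == pytest.approx(11.0)


class TestCompareModels:
    def _fake_fit(self, bic_val, fingerprint="f"):
        from gaucher_ert.estimation import FitResult
        from gaucher_ert.population_model import reference_joint_model

        return FitResult(
            estimates=reference_joint_model(False),
            loglik=-0.5 * bic_val,
            loglik_se=0.1,
            bic=bic_val,
            n_parameters=5,
            n_patients=10,
            trace=pd.DataFrame(),
            settings=FAST,
            seed=0,
            data_fingerprint=fingerprint,
            converged=True,
        )

    def test_ranking_and_delta(self):
        ranked = compare_models([self._fake_fit(122.0), self._fake_fit(100.0)])
        assert ranked["bic"].tolist() == [100.0, 122.0]
        assert ranked["delta_bic"].tolist() == [0.0, 22.0]

    def test_single_fit(self):
        ranked = compare_models([self._fake_fit(50.0)])
        assert len(ranked) == 1 and ranked["delta_bic"].iloc[0] == 0.0

    def test_mismatched_data_rejected(self):
        with pytest.raises(ValueError, match="different data"):
            compare_models([self._fake_fit(1.0, "a"), self._fake_fit(2.0, "b")])


class TestLoglikIS:
    def test_no_random_effect_limit(self):
        # with vanishing omegas the marginal equals the eta=0 likelihood
        model = platelet_model(omega=(1e-6, 1e-6, 1e-6), sigma=0.2)
        cohort = platelet_cohort(model, seed=5, n=6, n_obs=4)
        est = loglik_is(model, cohort, is_samples=4000, seed=1)
        closed = sum(
            observation_loglik(model, rec, np.zeros(3)) for rec in cohort
        )
        assert est.value == pytest.approx(closed, abs=max(4 * est.se, 0.02))

    def test_matches_gauss_hermite(self):
        # one effective random effect: adaptive 64-node quadrature oracle
        omega1 = 0.5
        model = platelet_model(omega=(omega1, 1e-3, 1e-3), sigma=0.2)
        cohort = platelet_cohort(model, seed=6, n=3, n_obs=2)
        est = loglik_is(model, cohort, is_samples=20_000, seed=2)

        problem = LikelihoodProblem(model, cohort)
        nodes, weights = hermegauss(64)
        total = 0.0
        for i, rec in enumerate(problem.patients):
            m = prior_log_means(model, rec)

            def joint(eta1, i=i, m=m):
                # integrand over the single live random effect
                phi = m.copy()
                phi[0] += eta1
                ll = problem.patient_obs_loglik_multi(i, phi[None, :], np.array([0.2]))[0]
                return ll - 0.5 * eta1**2 / omega1**2 - math.log(
                    omega1 * math.sqrt(2 * math.pi)
                )

            # adapt nodes to the conditional mode and curvature
            from scipy.optimize import minimize_scalar

            mode = minimize_scalar(
                lambda e: -joint(e), bounds=(-5 * omega1, 5 * omega1), method="bounded",
                options={"xatol": 1e-10},
            ).x
            h = 1e-4
            curv = -(joint(mode + h) - 2 * joint(mode) + joint(mode - h)) / h**2
            scale = 1.0 / math.sqrt(max(curv, 1e-8))
            lls = [
                joint(mode + scale * x) + 0.5 * x**2 + math.log(w) + math.log(scale)
                for x, w in zip(nodes, weights)
            ]
            total += logsumexp(lls)
        assert est.value == pytest.approx(total, abs=max(0.01, 3 * est.se))

    def test_monte_carlo_error_scaling(self):
        model = platelet_model()
        cohort = platelet_cohort(model, seed=7, n=10, n_obs=5)
        se_small = np.mean(
            [loglik_is(model, cohort, is_samples=250, seed=s).se for s in range(4)]
        )
        se_big = np.mean(
            [loglik_is(model, cohort, is_samples=1000, seed=s).se for s in range(4)]
        )
        # quadrupling the sample count should halve the SE (allow slack)
        assert 0.35 < se_big / se_small < 0.75


class TestFitSaem:
    def test_deterministic_given_seed(self):
        truth = platelet_model(beta_splen=math.log(2.5))
        cohort = platelet_cohort(truth, seed=11, n=40)
        tmpl = platelet_template()
        a = fit_saem(tmpl, cohort, FAST)
        b = fit_saem(tmpl, cohort, FAST)
        assert a.estimates == b.estimates
        pd.testing.assert_frame_equal(a.trace, b.trace)

    def test_near_deterministic_limit(self):
        # tiny variabilities: estimates should land within 2% of truth
        truth = platelet_model(omega=(0.01, 0.01, 0.01), sigma=0.01)
        cohort = platelet_cohort(truth, seed=12, n=40, n_obs=8)
        tmpl = platelet_template(with_splen=False)
        fit = fit_saem(tmpl, cohort, dataclasses.replace(FAST, seed=3))
        est = fit.estimates
        assert est.fixed.c0["platelets"] == pytest.approx(74300.0, rel=0.02)
        assert est.fixed.r["platelets"] == pytest.approx(2.1, rel=0.02)
        assert est.fixed.k == pytest.approx(1.4, rel=0.02)

    def test_single_biomarker_recovery(self):
        truth = platelet_model(beta_splen=math.log(2.5))
        cohort = platelet_cohort(truth, seed=13, n=120, n_obs=7)
        fit = fit_saem(platelet_template(), cohort, dataclasses.replace(FAST, seed=4))
        est = fit.estimates
        assert est.fixed.c0["platelets"] == pytest.approx(74300.0, rel=0.15)
        assert est.fixed.r["platelets"] == pytest.approx(2.1, rel=0.15)
        assert est.fixed.k == pytest.approx(1.4, rel=0.15)
        assert math.exp(est.effects[0].beta) == pytest.approx(2.5, rel=0.2)

    def test_counts_parameters_and_patients(self):
        truth = platelet_model()
        cohort = platelet_cohort(truth, seed=14, n=15)
        fit = fit_saem(platelet_template(with_splen=False), cohort, FAST)
        # 3 fixed effects + 3 omegas + 1 sigma
        assert fit.n_parameters == 7
        assert fit.n_patients == 15

    def test_empty_likelihood_rejected(self):
        truth = platelet_model()
        cohort = platelet_cohort(truth, seed=15, n=4)
        from gaucher_ert.population_model import reference_joint_model

        with pytest.raises(ValueError, match="no observations"):
            fit_saem(reference_joint_model(False), cohort, FAST)

    def test_trace_positive_and_bounded(self):
        truth = platelet_model()
        cohort = platelet_cohort(truth, seed=16, n=30)
        fit = fit_saem(platelet_template(with_splen=False), cohort, FAST)
        pop_cols = [c for c in fit.trace.columns if not c.startswith("beta.")]
        assert (fit.trace[pop_cols] > 0).all().all()
        assert np.isfinite(fit.trace.to_numpy(float)).all()


class TestStandardErrors:
    def test_se_calibrated_against_replicates(self):
        # reported SE of the baseline fixed effect vs the empirical SD of
        # the estimator over replicate cohorts
        truth = platelet_model(omega=(0.4, 0.3, 0.5), sigma=0.15)
        tmpl = platelet_template(with_splen=False)
        estimates, ses = [], []
        for s in range(24):
            cohort = platelet_cohort(truth, seed=700 + s, n=50, n_obs=6)
            fit = fit_saem(tmpl, cohort, dataclasses.replace(FAST, seed=s))
            fit = standard_errors(fit, cohort)
            estimates.append(math.log(fit.estimates.fixed.c0["platelets"]))
            ses.append(fit.rse_pct["c0_pop.platelets"] / 100.0)
        empirical = np.std(estimates, ddof=1)
        assert np.mean(ses) == pytest.approx(empirical, rel=0.40)

    def test_sqrt_n_scaling(self):
        truth = platelet_model()
        tmpl = platelet_template(with_splen=False)
        ses = {}
        for n in (40, 160):
            cohort = platelet_cohort(truth, seed=21, n=n)
            fit = fit_saem(tmpl, cohort, dataclasses.replace(FAST, seed=5))
            fit = standard_errors(fit, cohort)
            ses[n] = fit.se["c0_pop.platelets"] / fit.estimates.fixed.c0["platelets"]
        ratio = ses[40] / ses[160]
        assert 1.4 < ratio < 2.9  # ~2 expected

    def test_methods_agree(self):
        truth = platelet_model(beta_splen=math.log(2.5))
        cohort = platelet_cohort(truth, seed=22, n=60)
        fit = fit_saem(platelet_template(), cohort, dataclasses.replace(FAST, seed=6))
        lin = standard_errors(fit, cohort, method="linearization")
        sto = standard_errors(fit, cohort, method="stochastic_fisher")
        name = "beta.c0.platelets.splenectomized"
        assert lin.se[name] == pytest.approx(sto.se[name], rel=0.5)
        assert lin.wald[name] < 0.05 and sto.wald[name] < 0.05

    def test_bootstrap_runs_at_small_scale(self):
        truth = platelet_model()
        cohort = platelet_cohort(truth, seed=25, n=12, n_obs=5)
        fast = FitSettings(seed=1, n_burnin=60, n_smoothing=40, compute_loglik=False)
        fit = fit_saem(platelet_template(with_splen=False), cohort, fast)
        fit = standard_errors(fit, cohort, method="bootstrap", n_boot=4)
        assert fit.se["c0_pop.platelets"] > 0
        assert np.isfinite(fit.rse_pct["c0_pop.platelets"])

    def test_unknown_method_rejected(self):
        truth = platelet_model()
        cohort = platelet_cohort(truth, seed=23, n=10)
        fit = fit_saem(platelet_template(with_splen=False), cohort, FAST)
        with pytest.raises(ValueError, match="unknown method"):
            standard_errors(fit, cohort, method="magic")

    def test_parameter_table_layout(self):
        truth = platelet_model()
        cohort = platelet_cohort(truth, seed=24, n=20)
        fit = fit_saem(platelet_template(with_splen=False), cohort, FAST)
        fit = standard_errors(fit, cohort)
        table = parameter_table(fit)
        assert set(table.columns) == {"parameter", "estimate", "rse_pct", "p_value"}
        assert (table["parameter"].str.startswith("omega.")).sum() == 3
        assert (table["parameter"].str.startswith("sigma.")).sum() == 1


class TestEmaxComparator:
    def test_exponential_truth_beats_emax_by_bic(self):
        truth = platelet_model(omega=(0.42, 0.31, 0.5), sigma=0.2)
        cohort = platelet_cohort(truth, seed=90, n=100, n_obs=7)
        from gaucher_ert.estimation import initial_model_from_data

        settings = FitSettings(seed=1, n_burnin=200, n_smoothing=120, is_samples=500)
        exp_fit = fit_saem(initial_model_from_data(cohort, shared_k=True), cohort, settings)
        emax_fit = fit_saem(
            initial_model_from_data(cohort, shared_k=True, model_kind="emax"),
            cohort,
            settings,
        )
        # equal parameter counts: c0, r, k vs c0, r, t50
        assert exp_fit.n_parameters == emax_fit.n_parameters
        ranked = compare_models([exp_fit, emax_fit], names=["exponential", "emax"])
        assert ranked.iloc[0]["model"] == "exponential"

    def test_emax_fit_recovers_emax_truth(self):
        from gaucher_ert.estimation import initial_model_from_data
        from gaucher_ert.population_model import (
            ErrorModel,
            FixedEffects,
            PopulationModel,
            RandomEffectSpec,
        )

        truth = PopulationModel(
            shared_k=True,
            fixed=FixedEffects(c0={"platelets": 74300.0}, r={"platelets": 2.1}, k=1.4),
            random=RandomEffectSpec(
                omega={"c0.platelets": 0.3, "r.platelets": 0.2, "t50": 0.3}
            ),
            error=ErrorModel(sigma={"platelets": 0.15}),
            model_kind="emax",  # third slot holds T50 = 1.4 years
        )
        cohort = platelet_cohort(truth, seed=91, n=80, n_obs=7)
        fit = fit_saem(
            initial_model_from_data(cohort, shared_k=True, model_kind="emax"),
            cohort,
            FitSettings(seed=2, n_burnin=200, n_smoothing=120, compute_loglik=False),
        )
        est = fit.estimates
        assert est.model_kind == "emax"
        assert est.fixed.c0["platelets"] == pytest.approx(74300.0, rel=0.15)
        assert est.fixed.k == pytest.approx(1.4, rel=0.25)  # T50


class TestLaplaceCrossCheck:
    def test_laplace_agrees_with_saem(self):
        truth = platelet_model(omega=(0.3, 0.2, 0.4), sigma=0.15)
        cohort = platelet_cohort(truth, seed=30, n=25, n_obs=12)
        tmpl = platelet_template(with_splen=False)
        lap = fit_laplace(tmpl, cohort, maxiter=40)
        sa = fit_saem(
            tmpl, cohort, FitSettings(seed=2, n_burnin=300, n_smoothing=200, compute_loglik=False)
        ).estimates
        assert lap.fixed.c0["platelets"] == pytest.approx(sa.fixed.c0["platelets"], rel=0.1)
        assert lap.fixed.r["platelets"] == pytest.approx(sa.fixed.r["platelets"], rel=0.1)
        assert lap.fixed.k == pytest.approx(sa.fixed.k, rel=0.2)
        # the two fitters reach comparable marginal likelihoods
        ll_lap = loglik_is(lap, cohort, 2000, seed=3).value
        ll_sa = loglik_is(sa, cohort, 2000, seed=3).value
        assert abs(ll_lap - ll_sa) < 3.0
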