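"""Population layer: covariate effects, random effects, simulation,
complete-data likelihood, serialization."""

import math

import numpy as np
import pandas as pd
import pytest

from gaucher_ert.population_model import (
    CovariateEffect,
    ErrorModel,
    FixedEffects,
    PatientDesign,
    PopulationModel,
    RandomEffectSpec,
    complete_data_loglik,
    covariate_vector,
    individual_params,
    model_from_config,
    model_to_config,
    reference_joint_model,
    simulate_observations,
)
from gaucher_ert.registry_io import PatientCovariates, PatientRecord, TreatmentEpisode

from _helpers import platelet_model

SPLEN = PatientCovariates("female", 30.0, True, False, False)
NOSPLEN = PatientCovariates("female", 30.0, False, False, False)


class TestIndividualParams:
    def test_zero_eta_gives_population_values(self, joint_truth_no_cov):
        params = individual_params(joint_truth_no_cov, NOSPLEN, None)
        for b in joint_truth_no_cov.biomarkers:
            assert params[b].c0 == pytest.approx(joint_truth_no_cov.fixed.c0[b])
            assert params[b].r == pytest.approx(joint_truth_no_cov.fixed.r[b])
            assert params[b].k == pytest.approx(1.4)

    def test_splenectomy_multiplies_platelet_baseline(self, joint_truth_no_cov):
        # 74300 * exp(beta_splen) = 74300 * 2.5 = 185750
        params = individual_params(joint_truth_no_cov, SPLEN, None)
        assert params["platelets"].c0 == pytest.approx(185750.0, rel=1e-9)
        assert params["platelets"].r == pytest.approx(2.1 * 0.5, rel=1e-9)

    def test_eta_equal_to_omega_scales_by_exp_omega(self, joint_truth_no_cov):
        names = joint_truth_no_cov.param_names()
        omega = joint_truth_no_cov.omega_vector()
        params = individual_params(joint_truth_no_cov, NOSPLEN, omega)
        j = names.index("c0.ferritin")
        expected = joint_truth_no_cov.fixed.c0["ferritin"] * math.exp(omega[j])
        assert params["ferritin"].c0 == pytest.approx(expected, rel=1e-9)

    def test_monotone_in_beta(self):
        base = platelet_model(beta_splen=0.2)
        more = platelet_model(beta_splen=0.7)
        p0 = individual_params(base, SPLEN)["platelets"].c0
        p1 = individual_params(more, SPLEN)["platelets"].c0
        assert p1 == pytest.approx(p0 * math.exp(0.5), rel=1e-9)

    def test_shared_k_is_common_across_biomarkers(self, joint_truth_no_cov):
        rng = np.random.default_rng(0)
        eta = rng.normal(size=len(joint_truth_no_cov.param_names()))
        params = individual_params(joint_truth_no_cov, NOSPLEN, eta)
        ks = {b: p.k for b, p in params.items()}
        assert len(set(ks.values())) == 1

    def test_dimension_mismatch_rejected(self, joint_truth_no_cov):
        with pytest.raises(ValueError):
            individual_params(joint_truth_no_cov, NOSPLEN, np.zeros(3))


def _one_point_design(n):
    cov = NOSPLEN
    return [
        PatientDesign(
            patient_id=f"P{i}",
            covariates=cov,
            episodes=(TreatmentEpisode(0.0, 5.0, 120.0),),
            times={"platelets": np.array([2.0])},
        )
        for i in range(n)
    ]


class TestSimulation:
    def test_degenerate_noise_lies_on_population_curve(self):
        model = platelet_model(omega=(1e-8, 1e-8, 1e-8), sigma=1e-9)
        cohort = simulate_observations(model, _one_point_design(5), seed=1)
        from gaucher_ert.structural_models import predict_profile

        expected = predict_profile(
            individual_params(model, NOSPLEN)["platelets"], 2.0
        )
        for rec in cohort:
            assert rec.observations["value"].iloc[0] == pytest.approx(expected, rel=1e-6)

    def test_proportional_error_scale(self):
        # empirical SD/mean of 10^4 replicate draws at one design point ~ sigma
        model = platelet_model(omega=(1e-8, 1e-8, 1e-8), sigma=0.2)
        design = [
            PatientDesign(
                patient_id="MC",
                covariates=NOSPLEN,
                episodes=(TreatmentEpisode(0.0, 5.0, 120.0),),
                times={"platelets": np.full(10_000, 2.0) + np.arange(10_000) * 1e-9},
            )
        ]
        cohort = simulate_observations(model, design, seed=2)
        y = cohort.observations_frame()["value"].to_numpy()
        assert abs(y.std() / y.mean() - 0.2) < 0.01

    def test_same_seed_identical(self, joint_truth_no_cov):
        d = _one_point_design(8)
        a = simulate_observations(platelet_model(), d, seed=9)
        b = simulate_observations(platelet_model(), d, seed=9)
        pd.testing.assert_frame_equal(a.observations_frame(), b.observations_frame())

    def test_values_positive_even_at_high_noise(self):
        model = platelet_model(sigma=0.61)
        design = [
            PatientDesign(
                patient_id="HN",
                covariates=NOSPLEN,
                episodes=(TreatmentEpisode(0.0, 5.0, 120.0),),
                times={"platelets": np.linspace(0.01, 5.0, 2000)},
            )
        ]
        cohort = simulate_observations(model, design, seed=3)
        assert (cohort.observations_frame()["value"] > 0).all()


def _record_with_obs(rows, cov=NOSPLEN):
    obs = pd.DataFrame(rows, columns=["biomarker", "time_years", "value", "undetectable"])
    return PatientRecord(
        patient_id="Z",
        covariates=cov,
        episodes=[TreatmentEpisode(0.0, 5.0, 120.0)],
        observations=obs,
    )


class TestCompleteDataLoglik:
    def test_observation_at_mode_density(self):
        model = platelet_model(sigma=0.2)
        from gaucher_ert.structural_models import predict_profile

        f = predict_profile(individual_params(model, NOSPLEN)["platelets"], 1.0)
        rec = _record_with_obs([("platelets", 1.0, f, False)])
        ll = complete_data_loglik(model, rec, np.zeros(3))
        expected_obs = -math.log(0.2 * f * math.sqrt(2 * math.pi))
        prior = -0.5 * (
            3 * math.log(2 * math.pi)
            + 2 * math.log(0.42 * 0.31 * 0.9)
        )
        assert ll == pytest.approx(expected_obs + prior, rel=1e-9)

    def test_eta_zero_maximizes_prior(self):
        model = platelet_model()
        rec = _record_with_obs([])
        ll0 = complete_data_loglik(model, rec, np.zeros(3))
        for delta in np.eye(3) * 0.5:
            assert complete_data_loglik(model, rec, delta) < ll0

    def test_excluded_chitotriosidase_row_contributes_nothing(self, joint_truth_no_cov):
        deficient = PatientCovariates("female", 30.0, False, False, True)
        base_rows = [("hemoglobin", 1.0, 12.0, False)]
        rec0 = _record_with_obs(base_rows, cov=deficient)
        rec1 = _record_with_obs(
            base_rows + [("chitotriosidase", 1.0, 5000.0, False)], cov=deficient
        )
        eta = np.zeros(len(joint_truth_no_cov.param_names()))
        assert complete_data_loglik(joint_truth_no_cov, rec0, eta) == pytest.approx(
            complete_data_loglik(joint_truth_no_cov, rec1, eta)
        )


class TestSerialization:
    def test_round_trip(self, joint_truth_cov):
        cfg = model_to_config(joint_truth_cov)
        back = model_from_config(cfg)
        assert back.fixed == joint_truth_cov.fixed
        assert set(e.name for e in back.effects) == set(
            e.name for e in joint_truth_cov.effects
        )
        assert back.random.omega == joint_truth_cov.random.omega
        assert back.error.sigma == joint_truth_cov.error.sigma

    def test_round_trip_with_correlation(self):
        corr = np.array([[1.0, 0.4, 0.0], [0.4, 1.0, 0.0], [0.0, 0.0, 1.0]])
        model = PopulationModel(
            shared_k=True,
            fixed=FixedEffects(c0={"platelets": 7e4}, r={"platelets": 2.0}, k=1.4),
            random=RandomEffectSpec(
                omega={"c0.platelets": 0.4, "r.platelets": 0.3, "k": 0.9},
                correlation=corr,
            ),
            error=ErrorModel(sigma={"platelets": 0.2}),
        )
        back = model_from_config(model_to_config(model))
        np.testing.assert_allclose(back.random.correlation, corr)

    def test_covariate_vector_indicators(self):
        rec = PatientRecord(
            patient_id="S",
            covariates=PatientCovariates("male", 10.0, True, True, False),
            episodes=[TreatmentEpisode(0.0, 5.0, 130.0)],
        )
        x = covariate_vector(rec)
        assert x["male"] == 1.0 and x["under15"] == 1.0
        assert x["splenectomized"] == 1.0 and x["genotype_n370s_hom"] == 1.0
        assert x["dose_init_high"] == 1.0 and x["dose_init_low"] == 0.0

    def test_reference_models_have_nine_omegas(self):
        for with_cov in (True, False):
            model = reference_joint_model(with_cov)
            assert len(model.param_names()) == 9
            assert len(model.random.omega) == 9
            assert len(model.error.sigma) == 4
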