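"""Shared builders for test cohorts and small models."""

from __future__ import annotations

import math

import numpy as np

from gaucher_ert.population_model import (
    CovariateEffect,
    ErrorModel,
    FixedEffects,
    PatientDesign,
    PopulationModel,
    RandomEffectSpec,
    simulate_observations,
)
from gaucher_ert.registry_io import PatientCovariates, TreatmentEpisode


def platelet_model(
    beta_splen: float = 0.0,
    omega=(0.42, 0.31, 0.9),
    sigma: float = 0.2,
) -> PopulationModel:
    """Single-biomarker (platelets) model with optional splenectomy effect
    on the baseline count."""
    effects = ()
    if beta_splen:
        effects = (CovariateEffect("c0", "platelets", "splenectomized", beta_splen),)
    return PopulationModel(
        shared_k=True,
        fixed=FixedEffects(c0={"platelets": 74300.0}, r={"platelets": 2.1}, k=1.4),
        effects=effects,
        random=RandomEffectSpec(
            omega={"c0.platelets": omega[0], "r.platelets": omega[1], "k": omega[2]}
        ),
        error=ErrorModel(sigma={"platelets": sigma}),
    )


def platelet_template(with_splen: bool = True) -> PopulationModel:
    """Deliberately off-truth starting values for fitting."""
    effects = (
        (CovariateEffect("c0", "platelets", "splenectomized", 0.0),) if with_splen else ()
    )
    return PopulationModel(
        shared_k=True,
        fixed=FixedEffects(c0={"platelets": 60000.0}, r={"platelets": 1.5}, k=1.0),
        effects=effects,
        random=RandomEffectSpec(
            omega={"c0.platelets": 0.5, "r.platelets": 0.5, "k": 0.5}
        ),
        error=ErrorModel(sigma={"platelets": 0.3}),
    )


def platelet_cohort(
    truth: PopulationModel,
    seed: int,
    n: int = 80,
    n_obs: int = 6,
    splen_prev: float = 0.3,
    t_max: float = 8.0,
):
    """Simulated platelet cohort: one pre-treatment baseline plus sparse
    on-treatment sampling."""
    rng = np.random.default_rng(seed)
    designs = []
    for i in range(n):
        cov = PatientCovariates(
            sex="female" if rng.random() < 0.5 else "male",
            age_at_init=float(rng.uniform(5.0, 60.0)),
            splenectomized=bool(rng.random() < splen_prev),
            genotype_n370s_hom=bool(rng.random() < 0.13),
            chito_deficient=False,
        )
        t = np.sort(np.concatenate([[-0.5], rng.uniform(0.05, t_max, size=n_obs)]))
        designs.append(
            PatientDesign(
                patient_id=f"P{i:03d}",
                covariates=cov,
                episodes=(TreatmentEpisode(0.0, t_max + 1.0, 120.0),),
                times={"platelets": t},
            )
        )
    return simulate_observations(truth, designs, seed=seed + 10_000)


def dense_joint_cohort(truth: PopulationModel, seed: int, n: int = 60, n_obs: int = 40):
    """Densely sampled cohort of all the model's biomarkers (for residual
    calibration and per-patient recovery)."""
    rng = np.random.default_rng(seed)
    designs = []
    for i in range(n):
        cov = PatientCovariates(
            sex="female" if rng.random() < 0.5 else "male",
            age_at_init=float(rng.uniform(5.0, 60.0)),
            splenectomized=bool(rng.random() < 0.26),
            genotype_n370s_hom=False,
            chito_deficient=False,
        )
        times = {
            b: np.sort(rng.uniform(-1.0, 10.0, size=n_obs)) for b in truth.biomarkers
        }
        designs.append(
            PatientDesign(
                patient_id=f"D{i:03d}",
                covariates=cov,
                episodes=(TreatmentEpisode(0.0, 11.0, 120.0),),
                times=times,
            )
        )
    return simulate_observations(truth, designs, seed=seed + 20_000)
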