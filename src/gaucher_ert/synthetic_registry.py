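"""Synthetic registry cohorts with known ground truth.

The French Gaucher Disease Registry data behind the published analysis are
not distributable, so this module generates cohorts with the same
structure: ~233 patients with the registry's covariate prevalences, sparse
irregular sampling of four biomarkers over up to 19 years of ERT follow-up
(including up to 2 pre-treatment years), occasional treatment
interruptions, dose episodes in IU/kg/month, and chitotriosidase-deficient
patients whose chitotriosidase rows carry the undetectable flag.
Observations are drawn from the population model (lognormal random
effects, proportional error); every draw is recorded in a truth table so
parameter-recovery experiments can compare estimates against the known
individual parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .population_model import (
    PatientDesign,
    PopulationModel,
    draw_etas,
    individual_params,
    reference_joint_model,
    simulate_patient,
)
from .registry_io import (
    BIOMARKERS,
    Cohort,
    PatientCovariates,
    PatientRecord,
    TreatmentEpisode,
)

__all__ = ["GeneratorConfig", "TruthRecord", "generate_cohort", "write_truth"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design parameters of the synthetic registry.

    Prevalences and monitoring rates default to the published registry
    description (233 patients; 50.6% female; 17.6% under 15 at ERT
    initiation; 26.2% splenectomized; 13.4% N370S homozygous among
    genotyped; ferritin/chitotriosidase/hemoglobin/platelets monitored in
    129/142/191/191 patients; initial dose classes 13.1%/81.7%/5.2%).
    The chitotriosidase-deficiency prevalence (6%) is a package choice:
    the registry reports exclusions but no prevalence.  Follow-up is a
    uniform mixture with median ~9 and maximum 19 years; visits are
    roughly annual with +/-1.5 months of jitter plus 0-2 pre-treatment
    baselines; 5% of patients interrupt treatment for more than 6 months.
    """

    n_patients: int = 233
    prevalence_female: float = 0.506
    prevalence_under15: float = 0.176
    prevalence_splenectomy: float = 0.262
    prevalence_n370s_hom: float = 0.134
    prevalence_chito_deficient: float = 0.06
    followup_max_years: float = 19.0
    followup_median_years: float = 9.0
    monitoring_probability: dict[str, float] = field(
        default_factory=lambda: {
            "ferritin": 129 / 233,
            "chitotriosidase": 142 / 233,
            "hemoglobin": 191 / 233,
            "platelets": 191 / 233,
        }
    )
    visits_per_year: float = 1.0
    monitoring_span_max_years: float = 12.0
    max_pre_ert_baselines: int = 2
    interruption_probability: float = 0.05
    dose_class_probabilities: tuple[float, float, float] = (0.131, 0.817, 0.052)
    truth: PopulationModel = field(
        default_factory=lambda: reference_joint_model(with_covariates=True)
    )

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        probs = [
            self.prevalence_female,
            self.prevalence_under15,
            self.prevalence_splenectomy,
            self.prevalence_n370s_hom,
            self.prevalence_chito_deficient,
            self.interruption_probability,
            *self.monitoring_probability.values(),
            *self.dose_class_probabilities,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.dose_class_probabilities) - 1.0) > 1e-9:
            raise ValueError("dose class probabilities must sum to 1")


@dataclass
class TruthRecord:
    """Ground truth of a generated cohort: the generating model, per-patient
    random effects (``etas``) and implied individual parameters
    (``params``, long format patient_id/parameter/true_value)."""

    model: PopulationModel
    etas: pd.DataFrame  # index patient_id, columns eta.<dim>
    params: pd.DataFrame  # patient_id, parameter, true_value
    seed: int


def _draw_covariates(config: GeneratorConfig, rng: np.random.Generator) -> PatientCovariates:
    under15 = rng.random() < config.prevalence_under15
    # age drawn inside the age class; the model uses only the under-15 flag
    age = rng.uniform(1.0, 14.9) if under15 else rng.uniform(15.0, 76.0)
    return PatientCovariates(
        sex="female" if rng.random() < config.prevalence_female else "male",
        age_at_init=float(age),
        splenectomized=bool(rng.random() < config.prevalence_splenectomy),
        genotype_n370s_hom=bool(rng.random() < config.prevalence_n370s_hom),
        chito_deficient=bool(rng.random() < config.prevalence_chito_deficient),
    )


def _draw_dose(cls: int, rng: np.random.Generator) -> float:
    if cls == 0:  # < 90 IU/kg/month
        return float(rng.uniform(28.0, 85.0))
    if cls == 1:  # 90-120, modal dose 120
        return 120.0 if rng.random() < 0.8 else float(rng.choice([90.0, 100.0, 110.0]))
    return float(rng.uniform(125.0, 240.0))  # > 120


def _draw_episodes(
    config: GeneratorConfig, followup: float, rng: np.random.Generator
) -> tuple[TreatmentEpisode, ...]:
    cls = int(rng.choice(3, p=config.dose_class_probabilities))
    dose = _draw_dose(cls, rng)
    interrupted = rng.random() < config.interruption_probability and followup > 3.0
    if not interrupted:
        return (TreatmentEpisode(start=0.0, end=followup, dose=dose),)
    stop = float(rng.uniform(1.0, followup - 1.5))
    gap = float(rng.uniform(0.55, 1.5))  # strictly more than 6 months
    resume = min(stop + gap, followup - 0.5)
    dose2 = _draw_dose(int(rng.choice(3, p=config.dose_class_probabilities)), rng)
    return (
        TreatmentEpisode(start=0.0, end=stop, dose=dose),
        TreatmentEpisode(start=resume, end=followup, dose=dose2),
    )


def _draw_followup(config: GeneratorConfig, rng: np.random.Generator) -> float:
    med, mx = config.followup_median_years, config.followup_max_years
    if rng.random() < 0.5:
        return float(rng.uniform(0.5, med))
    return float(rng.uniform(med, mx))


def _draw_times(
    config: GeneratorConfig, followup: float, rng: np.random.Generator
) -> np.ndarray:
    # biomarkers are monitored over a span shorter than total follow-up,
    # as in the registry (median monitored length ~5-6 y vs 9 y of ERT)
    span_hi = min(followup, config.monitoring_span_max_years)
    span = rng.uniform(min(1.0, span_hi), span_hi) if span_hi > 1.0 else span_hi
    jitter = 1.5 / 12.0
    scheduled = np.arange(0.0, span + 1e-9, 1.0 / config.visits_per_year)
    times = scheduled + rng.uniform(-jitter, jitter, size=scheduled.size)
    times = times[(times <= followup)]
    times = np.maximum(times, 1e-3)
    n_pre = int(rng.integers(0, config.max_pre_ert_baselines + 1))
    pre = -rng.uniform(0.0, 2.0, size=n_pre)
    return np.sort(np.concatenate([pre, times]))


def generate_cohort(
    config: GeneratorConfig | None = None, seed: int = 0
) -> tuple[Cohort, TruthRecord]:
    """Generate a registry-like cohort and its ground truth.

    Deterministic for fixed (config, seed). Chitotriosidase rows of
    chito-deficient patients are stored with the undetectable flag (value
    0) and are therefore excluded from likelihood computations, mirroring
    how undetectable activity is handled in the registry analysis.
    """
    config = config if config is not None else GeneratorConfig()
    model = config.truth
    rng = np.random.default_rng(seed)

    designs: list[PatientDesign] = []
    for i in range(config.n_patients):
        pid = f"P{i + 1:04d}"
        cov = _draw_covariates(config, rng)
        followup = _draw_followup(config, rng)
        episodes = _draw_episodes(config, followup, rng)
        times = {}
        for b in model.biomarkers:
            if rng.random() < config.monitoring_probability[b]:
                t = _draw_times(config, followup, rng)
                times[b] = t
            else:
                times[b] = np.array([])
        designs.append(
            PatientDesign(patient_id=pid, covariates=cov, episodes=episodes, times=times)
        )

    etas = draw_etas(model, len(designs), rng)
    patients: dict[str, PatientRecord] = {}
    eta_rows, param_rows = [], []
    dims = model.param_names()
    for i, dsg in enumerate(designs):
        rec = simulate_patient(model, dsg, etas[i], rng)
        if dsg.covariates.chito_deficient:
            obs = rec.observations.copy()
            mask = obs["biomarker"] == "chitotriosidase"
            obs.loc[mask, "value"] = 0.0
            obs.loc[mask, "undetectable"] = True
            rec = PatientRecord(
                patient_id=rec.patient_id,
                covariates=rec.covariates,
                episodes=rec.episodes,
                observations=obs,
            )
        patients[dsg.patient_id] = rec
        eta_rows.append(
            {"patient_id": dsg.patient_id, **{f"eta.{d}": etas[i, j] for j, d in enumerate(dims)}}
        )
        pars = individual_params(model, rec, etas[i])
        for b, p in pars.items():
            param_rows.append({"patient_id": dsg.patient_id, "parameter": f"c0.{b}", "true_value": p.c0})
            param_rows.append({"patient_id": dsg.patient_id, "parameter": f"r.{b}", "true_value": p.r})
        k_i = next(iter(pars.values())).k if model.shared_k else None
        if model.shared_k:
            param_rows.append({"patient_id": dsg.patient_id, "parameter": "k", "true_value": k_i})
        else:
            for b, p in pars.items():
                param_rows.append({"patient_id": dsg.patient_id, "parameter": f"k.{b}", "true_value": p.k})

    truth = TruthRecord(
        model=model,
        etas=pd.DataFrame(eta_rows).set_index("patient_id"),
        params=pd.DataFrame(param_rows),
        seed=seed,
    )
    return Cohort(patients), truth


def write_truth(truth: TruthRecord, path) -> None:
    """Write the long-format truth table (patient_id, parameter, true_value)."""
    truth.params.to_csv(path, index=False)
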