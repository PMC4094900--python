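"""Population layer of the nonlinear mixed-effects model.

Each structural parameter (c0 and r per biomarker, the normalization rate
constant k) carries a lognormal random effect: for patient i,

    theta_i = theta_pop * exp(sum_j beta_j * x_ij) * exp(eta_i)

with eta ~ N(0, Omega) on the log scale and binary covariate indicators
x_ij (splenectomy, male sex, age under 15 at ERT initiation, N370S/N370S
genotype, dose-class indicators against the modal 90-120 IU/kg/month
class).  Observations have proportional residual error:

    y = f(theta_i, t) * (1 + eps),   eps ~ N(0, sigma_b^2)

per biomarker b.  With a shared k the random-effect vector has one entry
per (c0, r) x biomarker plus a single k entry (9 dimensions for the full
four-biomarker model); with per-biomarker k, 12.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .registry_io import (
    BIOMARKERS,
    Cohort,
    PatientCovariates,
    PatientRecord,
    TreatmentEpisode,
    DoseClass,
    assign_dose_classes,
)
from .structural_models import IndividualParams

__all__ = [
    "COVARIATE_NAMES",
    "FixedEffects",
    "CovariateEffect",
    "RandomEffectSpec",
    "ErrorModel",
    "PopulationModel",
    "PatientDesign",
    "covariate_vector",
    "individual_params",
    "simulate_observations",
    "complete_data_loglik",
    "model_to_config",
    "model_from_config",
    "reference_joint_model",
]

#: binary covariate indicators available to the model
COVARIATE_NAMES = (
    "male",
    "under15",
    "splenectomized",
    "genotype_n370s_hom",
    "dose_init_low",
    "dose_init_high",
    "dose_y3_low",
    "dose_y3_high",
)

_LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class FixedEffects:
    """Population-typical values: c0 and r per biomarker, k shared or per
    biomarker (units: biomarker units, dimensionless ratio, 1/year)."""

    c0: dict[str, float]
    r: dict[str, float]
    k: float | dict[str, float]

    def k_for(self, biomarker: str) -> float:
        return self.k[biomarker] if isinstance(self.k, dict) else self.k


@dataclass(frozen=True)
class CovariateEffect:
    """Multiplicative covariate effect exp(beta) on one structural
    parameter. ``biomarker`` is None for an effect on a shared k."""

    parameter: str  # "c0" | "r" | "k"
    biomarker: str | None
    covariate: str
    beta: float

    def __post_init__(self) -> None:
        if self.parameter not in ("c0", "r", "k"):
            raise ValueError(f"unknown parameter {self.parameter!r}")
        if self.covariate not in COVARIATE_NAMES:
            raise ValueError(f"unknown covariate {self.covariate!r}")
        if not math.isfinite(self.beta):
            raise ValueError("beta must be finite")

    @property
    def name(self) -> str:
        bm = self.biomarker if self.biomarker is not None else ""
        return f"beta.{self.parameter}.{bm}.{self.covariate}"


@dataclass(frozen=True)
class RandomEffectSpec:
    """Log-scale random-effect SDs omega per parameter dimension (reported
    in tables as percentages, 100*omega) and an optional correlation matrix
    over the dimensions (identity when None)."""

    omega: dict[str, float]
    correlation: np.ndarray | None = None

    def __post_init__(self) -> None:
        if any(not v > 0 for v in self.omega.values()):
            raise ValueError("all omegas must be positive")
        if self.correlation is not None:
            c = np.asarray(self.correlation, float)
            if not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1.0):
                raise ValueError("correlation must be symmetric with unit diagonal")
            if np.linalg.eigvalsh(c).min() <= 0:
                raise ValueError("correlation must be positive definite")


@dataclass(frozen=True)
class ErrorModel:
    """Proportional residual error SD per biomarker (fraction; tables
    report 100*sigma)."""

    sigma: dict[str, float]

    def __post_init__(self) -> None:
        if any(not v > 0 for v in self.sigma.values()):
            raise ValueError("all sigmas must be positive")


@dataclass(frozen=True)
class PopulationModel:
    """Structural + stochastic population model.

    ``model_kind`` selects the time course: ``"exponential"`` (the
    default pathophysiological model; third parameter is the rate
    constant k) or ``"emax"`` (the hyperbolic comparator; the third
    parameter slot holds T50 in years).
    """

    shared_k: bool
    fixed: FixedEffects
    effects: tuple[CovariateEffect, ...] = ()
    random: RandomEffectSpec = None  # type: ignore[assignment]
    error: ErrorModel = None  # type: ignore[assignment]
    model_kind: str = "exponential"

    def __post_init__(self) -> None:
        if self.model_kind not in ("exponential", "emax"):
            raise ValueError(f"unknown model_kind {self.model_kind!r}")
        names = set(self.param_names())
        if self.random is not None and set(self.random.omega) != names:
            raise ValueError(
                f"omega keys {sorted(self.random.omega)} do not match parameter "
                f"dimensions {sorted(names)}"
            )
        if self.error is not None and set(self.error.sigma) != set(self.biomarkers):
            raise ValueError("sigma keys must match the model's biomarkers")
        seen = set()
        for e in self.effects:
            key = (e.parameter, e.biomarker, e.covariate)
            if key in seen:
                raise ValueError(f"duplicate covariate effect {key}")
            seen.add(key)

    @property
    def biomarkers(self) -> tuple[str, ...]:
        return tuple(b for b in BIOMARKERS if b in self.fixed.c0)

    def param_names(self) -> list[str]:
        """Ordered random-effect / structural-parameter dimensions."""
        third = "k" if self.model_kind == "exponential" else "t50"
        names = []
        for b in self.biomarkers:
            names.append(f"c0.{b}")
            names.append(f"r.{b}")
        if self.shared_k:
            names.append(third)
        else:
            names.extend(f"{third}.{b}" for b in self.biomarkers)
        return names

    def pop_value(self, dim: str) -> float:
        part = dim.split(".")
        if part[0] == "c0":
            return self.fixed.c0[part[1]]
        if part[0] == "r":
            return self.fixed.r[part[1]]
        return self.fixed.k if len(part) == 1 else self.fixed.k[part[1]]

    def effects_on(self, dim: str) -> list[CovariateEffect]:
        part = dim.split(".")
        bm = part[1] if len(part) > 1 else None
        return [
            e for e in self.effects if e.parameter == part[0] and e.biomarker == bm
        ]

    def omega_vector(self) -> np.ndarray:
        return np.array([self.random.omega[d] for d in self.param_names()])

    def omega_matrix(self) -> np.ndarray:
        w = self.omega_vector()
        corr = (
            np.eye(len(w))
            if self.random.correlation is None
            else np.asarray(self.random.correlation, float)
        )
        return corr * np.outer(w, w)


def covariate_vector(patient: PatientRecord | PatientCovariates) -> dict[str, float]:
    """0/1 indicator values for every modelled covariate.

    Dose-class indicators need dosing episodes, so they are zero (reference
    class) when only :class:`PatientCovariates` is given or the patient has
    no episodes.
    """
    if isinstance(patient, PatientCovariates):
        cov, initial, third = patient, None, None
    else:
        cov = patient.covariates
        initial, third = (
            assign_dose_classes(patient) if patient.episodes else (None, None)
        )
    return {
        "male": float(cov.sex == "male"),
        "under15": float(cov.under15),
        "splenectomized": float(cov.splenectomized),
        "genotype_n370s_hom": float(cov.genotype_n370s_hom),
        "dose_init_low": float(initial is DoseClass.low),
        "dose_init_high": float(initial is DoseClass.high),
        "dose_y3_low": float(third is DoseClass.low),
        "dose_y3_high": float(third is DoseClass.high),
    }


def _eta_array(model: PopulationModel, eta) -> np.ndarray:
    names = model.param_names()
    if eta is None:
        return np.zeros(len(names))
    if isinstance(eta, dict):
        return np.array([eta.get(d, 0.0) for d in names], float)
    eta = np.asarray(eta, float)
    if eta.shape != (len(names),):
        raise ValueError(f"eta must have {len(names)} entries, got shape {eta.shape}")
    return eta


def prior_log_means(model: PopulationModel, patient) -> np.ndarray:
    """log theta_pop + X beta for every parameter dimension of one patient."""
    x = covariate_vector(patient)
    out = np.empty(len(model.param_names()))
    for j, dim in enumerate(model.param_names()):
        m = math.log(model.pop_value(dim))
        for e in model.effects_on(dim):
            m += e.beta * x[e.covariate]
        out[j] = m
    return out


def individual_params(model: PopulationModel, patient, eta=None) -> dict:
    """Individual structural parameters per biomarker.

    ``patient`` is a :class:`PatientRecord` or :class:`PatientCovariates`;
    ``eta`` a vector/dict of log-scale random effects (zeros when omitted).
    With a shared k, one eta entry drives k for all biomarkers. For an
    Emax model the values are :class:`EmaxParams` (T50 in the third slot).
    """
    from .structural_models import EmaxParams

    names = model.param_names()
    third = "k" if model.model_kind == "exponential" else "t50"
    phi = prior_log_means(model, patient) + _eta_array(model, eta)
    theta = dict(zip(names, np.exp(phi)))
    out = {}
    for b in model.biomarkers:
        val3 = theta[third] if model.shared_k else theta[f"{third}.{b}"]
        if model.model_kind == "exponential":
            out[b] = IndividualParams(c0=theta[f"c0.{b}"], r=theta[f"r.{b}"], k=val3)
        else:
            out[b] = EmaxParams(c0=theta[f"c0.{b}"], r=theta[f"r.{b}"], t50=val3)
    return out


def predict_any(params, t):
    """Dispatch prediction on the parameter type (exponential or Emax)."""
    from .structural_models import EmaxParams, predict_emax, predict_profile

    if isinstance(params, EmaxParams):
        return predict_emax(params, t)
    return predict_profile(params, t)


# ---------------------------------------------------------------------------
# simulation


@dataclass(frozen=True)
class PatientDesign:
    """Sampling design of one simulated patient: covariates, dosing
    episodes and measurement times (years) per biomarker."""

    patient_id: str
    covariates: PatientCovariates
    episodes: tuple[TreatmentEpisode, ...]
    times: dict[str, np.ndarray]


def predict_for_params(params: dict, times: dict[str, np.ndarray]):
    return {b: np.asarray(predict_any(params[b], t)) for b, t in times.items()}


def simulate_patient(
    model: PopulationModel,
    design: PatientDesign,
    eta: np.ndarray,
    rng: np.random.Generator,
) -> PatientRecord:
    """One patient's observations under the model at a given eta.

    Proportional-error draws that would give y <= 0 are resampled so stored
    values stay physically valid; the likelihood remains the untruncated
    normal.
    """
    record = PatientRecord(
        patient_id=design.patient_id,
        covariates=design.covariates,
        episodes=list(design.episodes),
    )
    params = individual_params(model, record, eta)
    rows = []
    for b in model.biomarkers:
        t = np.asarray(design.times.get(b, ()), float)
        if t.size == 0:
            continue
        f = np.asarray(predict_any(params[b], t), float)
        sig = model.error.sigma[b]
        y = f * (1.0 + rng.normal(0.0, sig, size=t.size))
        bad = y <= 0
        while bad.any():
            y[bad] = f[bad] * (1.0 + rng.normal(0.0, sig, size=int(bad.sum())))
            bad = y <= 0
        for ti, yi in zip(t, y):
            rows.append(
                {
                    "biomarker": b,
                    "time_years": float(ti),
                    "value": float(yi),
                    "undetectable": False,
                }
            )
    obs = pd.DataFrame(rows, columns=["biomarker", "time_years", "value", "undetectable"])
    if not rows:
        obs = obs.astype({"time_years": float, "value": float, "undetectable": bool})
    return PatientRecord(
        patient_id=design.patient_id,
        covariates=design.covariates,
        episodes=list(design.episodes),
        observations=obs,
    )


def draw_etas(
    model: PopulationModel, n: int, rng: np.random.Generator
) -> np.ndarray:
    omega = model.omega_matrix()
    chol = np.linalg.cholesky(omega)
    return rng.standard_normal((n, omega.shape[0])) @ chol.T


def simulate_observations(
    model: PopulationModel, design: list[PatientDesign], seed
) -> Cohort:
    """Simulate a cohort under the full stochastic model (eta ~ N(0, Omega),
    proportional error). Reproducible for a fixed seed."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    etas = draw_etas(model, len(design), rng)
    patients = {
        d.patient_id: simulate_patient(model, d, etas[i], rng)
        for i, d in enumerate(design)
    }
    return Cohort(patients)


# ---------------------------------------------------------------------------
# likelihood


def observation_loglik(
    model: PopulationModel, patient: PatientRecord, eta
) -> float:
    """Log-density of the patient's likelihood-eligible observations at a
    given eta (excluded chitotriosidase rows contribute nothing)."""
    params = individual_params(model, patient, eta)
    obs = patient.eligible_observations()
    total = 0.0
    for b in model.biomarkers:
        sel = obs[obs["biomarker"] == b]
        if sel.empty:
            continue
        f = np.asarray(predict_any(params[b], sel["time_years"].to_numpy()), float)
        if np.any(f <= 0):
            raise ValueError("model prediction must be positive")
        sd = model.error.sigma[b] * f
        z = (sel["value"].to_numpy() - f) / sd
        total += float(np.sum(-0.5 * z**2 - np.log(sd) - 0.5 * _LOG2PI))
    return total


def complete_data_loglik(
    model: PopulationModel, patient: PatientRecord, eta
) -> float:
    """Joint log-density log p(y, eta) = log p(y | eta) + log p(eta)."""
    eta = _eta_array(model, eta)
    omega = model.omega_matrix()
    sign, logdet = np.linalg.slogdet(omega)
    quad = float(eta @ np.linalg.solve(omega, eta))
    prior = -0.5 * (len(eta) * _LOG2PI + logdet + quad)
    return observation_loglik(model, patient, eta) + prior


# ---------------------------------------------------------------------------
# serialization


def model_to_config(model: PopulationModel) -> dict[str, object]:
    """Flat key-value form (round-trippable with :func:`model_from_config`).

    Keys: shared_k, c0_pop.<b>, r_pop.<b>, k_pop[.<b>], omega.<dim>,
    sigma.<b>, beta.<param>.<biomarker>.<covariate>, corr.<dim>.<dim>.
    """
    third = "k_pop" if model.model_kind == "exponential" else "t50_pop"
    cfg: dict[str, object] = {"shared_k": model.shared_k, "model_kind": model.model_kind}
    for b in model.biomarkers:
        cfg[f"c0_pop.{b}"] = model.fixed.c0[b]
        cfg[f"r_pop.{b}"] = model.fixed.r[b]
    if model.shared_k:
        cfg[third] = model.fixed.k
    else:
        for b in model.biomarkers:
            cfg[f"{third}.{b}"] = model.fixed.k[b]
    for dim in model.param_names():
        cfg[f"omega.{dim}"] = model.random.omega[dim]
    for b in model.biomarkers:
        cfg[f"sigma.{b}"] = model.error.sigma[b]
    for e in model.effects:
        cfg[e.name] = e.beta
    if model.random.correlation is not None:
        names = model.param_names()
        corr = np.asarray(model.random.correlation, float)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                if corr[i, j] != 0.0:
                    cfg[f"corr.{names[i]}.{names[j]}"] = float(corr[i, j])
    return cfg


def model_from_config(cfg: dict[str, object]) -> PopulationModel:
    shared_k = bool(cfg["shared_k"])
    model_kind = str(cfg.get("model_kind", "exponential"))
    third = "k_pop" if model_kind == "exponential" else "t50_pop"
    bms = [b for b in BIOMARKERS if f"c0_pop.{b}" in cfg]
    c0 = {b: float(cfg[f"c0_pop.{b}"]) for b in bms}
    r = {b: float(cfg[f"r_pop.{b}"]) for b in bms}
    k = float(cfg[third]) if shared_k else {b: float(cfg[f"{third}.{b}"]) for b in bms}
    fixed = FixedEffects(c0=c0, r=r, k=k)
    effects = []
    for key, val in cfg.items():
        if key.startswith("beta."):
            _, param, bm, covname = key.split(".")
            effects.append(
                CovariateEffect(
                    parameter=param,
                    biomarker=bm or None,
                    covariate=covname,
                    beta=float(val),
                )
            )
    model_stub = PopulationModel(
        shared_k=shared_k, fixed=fixed, effects=tuple(effects), model_kind=model_kind
    )
    names = model_stub.param_names()
    omega = {d: float(cfg[f"omega.{d}"]) for d in names}
    corr = None
    corr_keys = [kk for kk in cfg if kk.startswith("corr.")]
    if corr_keys:
        corr = np.eye(len(names))
        idx = {d: i for i, d in enumerate(names)}
        for kk in corr_keys:
            body = kk[len("corr."):]
            for d1 in names:
                if body.startswith(d1 + "."):
                    d2 = body[len(d1) + 1 :]
                    corr[idx[d1], idx[d2]] = corr[idx[d2], idx[d1]] = float(cfg[kk])
                    break
    sigma = {b: float(cfg[f"sigma.{b}"]) for b in bms}
    return PopulationModel(
        shared_k=shared_k,
        fixed=fixed,
        effects=tuple(effects),
        random=RandomEffectSpec(omega=omega, correlation=corr),
        error=ErrorModel(sigma=sigma),
        model_kind=model_kind,
    )


# ---------------------------------------------------------------------------
# reference estimates


def reference_joint_model(with_covariates: bool = True) -> PopulationModel:
    """Published joint-model estimates for the four biomarkers with a shared
    normalization rate constant, used as the synthetic generator's default
    ground truth.

    ``with_covariates=True`` returns the final covariate model (splenectomy,
    male sex and age-under-15 effects); ``False`` the covariate-free model
    (splenectomy on platelet baseline/amplitude only).
    """
    if with_covariates:
        fixed = FixedEffects(
            c0={"ferritin": 603.0, "chitotriosidase": 8140.0, "hemoglobin": 11.6, "platelets": 68400.0},
            r={"ferritin": 0.3, "chitotriosidase": 0.1, "hemoglobin": 1.2, "platelets": 2.2},
            k=1.4,
        )
        effects = (
            CovariateEffect("c0", "ferritin", "splenectomized", math.log(1.9)),
            CovariateEffect("c0", "ferritin", "under15", math.log(0.3)),
            CovariateEffect("c0", "hemoglobin", "male", math.log(1.1)),
            CovariateEffect("c0", "hemoglobin", "under15", math.log(0.9)),
            CovariateEffect("c0", "platelets", "splenectomized", math.log(2.7)),
            CovariateEffect("c0", "platelets", "under15", math.log(1.4)),
            CovariateEffect("r", "ferritin", "splenectomized", math.log(0.5)),
            CovariateEffect("r", "ferritin", "male", math.log(1.7)),
            CovariateEffect("r", "hemoglobin", "splenectomized", math.log(0.9)),
            CovariateEffect("r", "platelets", "splenectomized", math.log(0.7)),
        )
        omega = {
            "c0.ferritin": 0.63, "r.ferritin": 0.70,
            "c0.chitotriosidase": 1.22, "r.chitotriosidase": 1.13,
            "c0.hemoglobin": 0.12, "r.hemoglobin": 0.09,
            "c0.platelets": 0.40, "r.platelets": 0.31,
            "k": 0.97,
        }
        sigma = {"ferritin": 0.29, "chitotriosidase": 0.61, "hemoglobin": 0.07, "platelets": 0.20}
    else:
        fixed = FixedEffects(
            c0={"ferritin": 598.0, "chitotriosidase": 7920.0, "hemoglobin": 11.6, "platelets": 74300.0},
            r={"ferritin": 0.4, "chitotriosidase": 0.1, "hemoglobin": 1.2, "platelets": 2.1},
            k=1.4,
        )
        effects = (
            CovariateEffect("c0", "platelets", "splenectomized", math.log(2.5)),
            CovariateEffect("r", "platelets", "splenectomized", math.log(0.5)),
        )
        omega = {
            "c0.ferritin": 0.83, "r.ferritin": 0.67,
            "c0.chitotriosidase": 1.20, "r.chitotriosidase": 1.17,
            "c0.hemoglobin": 0.13, "r.hemoglobin": 0.10,
            "c0.platelets": 0.42, "r.platelets": 0.31,
            "k": 0.90,
        }
        sigma = {"ferritin": 0.30, "chitotriosidase": 0.61, "hemoglobin": 0.07, "platelets": 0.20}
    return PopulationModel(
        shared_k=True,
        fixed=fixed,
        effects=effects,
        random=RandomEffectSpec(omega=omega),
        error=ErrorModel(sigma=sigma),
    )
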