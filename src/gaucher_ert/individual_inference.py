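"""Empirical-Bayes individual parameters and derived clinical quantities.

Individual random effects are estimated as maximum a posteriori (MAP)
modes of their conditional distribution given the population estimates.
From the individual parameters the package derives the quantities used to
characterize a patient's response: normalization half-life ln2/k, time to
95% of response ln20/k (= 4.32 half-lives), steady-state biomarker values
c0*r, and whether each steady state is inside the usual-value limits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .estimation import FitResult, LikelihoodProblem, conditional_mode
from .population_model import PopulationModel, individual_params, prior_log_means
from .registry_io import Cohort, PatientRecord
from .structural_models import HALF_LIVES_TO_95, IndividualParams, half_life, steady_state, time_to_fraction

__all__ = [
    "NormalLimits",
    "IndividualSummary",
    "map_estimate",
    "cohort_map_estimates",
    "summarize_individual",
    "cohort_response_summary",
]


@dataclass(frozen=True)
class NormalLimits:
    """Usual-value limits: upper limits for the biomarkers that fall under
    treatment, lower limits for those that rise."""

    ferritin_upper: float = 250.0  # ug/L
    chito_upper: float = 100.0  # nmol/mL/h
    hemoglobin_lower: float = 12.0  # g/dL
    platelets_lower: float = 150_000.0  # /mm3

    def normalized(self, biomarker: str, value: float) -> bool:
        """Strict comparison against the limit for this biomarker."""
        if biomarker == "ferritin":
            return value < self.ferritin_upper
        if biomarker == "chitotriosidase":
            return value < self.chito_upper
        if biomarker == "hemoglobin":
            return value > self.hemoglobin_lower
        if biomarker == "platelets":
            return value > self.platelets_lower
        raise ValueError(f"unknown biomarker {biomarker!r}")


@dataclass
class IndividualSummary:
    patient_id: str
    k: float
    half_life_years: float
    time_to_95_years: float
    steady_state: dict[str, float]
    ratio_pct: dict[str, float]  # 100 * individual r
    normalized: dict[str, bool]


def map_estimate(
    model_or_fit: PopulationModel | FitResult,
    patient: PatientRecord,
    n_restarts: int = 3,
    seed: int = 0,
) -> tuple[np.ndarray, dict[str, IndividualParams]]:
    """MAP random effects and implied individual parameters of one patient.

    A patient without likelihood-eligible observations gets eta = 0, i.e.
    the covariate-adjusted population parameters (the prior mode). The
    optimizer runs from eta = 0 plus seeded random restarts.
    """
    model = model_or_fit.estimates if isinstance(model_or_fit, FitResult) else model_or_fit
    single = Cohort({patient.patient_id: patient})
    eligible = patient.eligible_observations()
    if eligible.empty:
        eta = np.zeros(len(model.param_names()))
        return eta, individual_params(model, patient, eta)
    problem = LikelihoodProblem(model, single)
    m_i = prior_log_means(model, patient)
    omega_mat = model.omega_matrix()
    sigma = np.array([model.error.sigma[b] for b in problem.biomarkers])
    W = np.linalg.inv(omega_mat)

    def negloglik(eta):
        ll, grad = problem.patient_obs_loglik_grad(0, m_i + eta, sigma)
        weta = W @ eta
        if not np.isfinite(ll):
            return 1e12 + float(eta @ eta), eta
        return -(ll - 0.5 * eta @ weta), -(grad - weta)

    rng = np.random.default_rng(seed)
    omega = model.omega_vector()
    best = None
    starts = [np.zeros(problem.d)] + [
        rng.standard_normal(problem.d) * omega for _ in range(n_restarts)
    ]
    for x0 in starts:
        res = optimize.minimize(negloglik, x0, jac=True, method="L-BFGS-B")
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError(f"MAP optimization failed for patient {patient.patient_id}")
    eta = best.x
    return eta, individual_params(model, patient, eta)


def cohort_map_estimates(
    model_or_fit: PopulationModel | FitResult, cohort: Cohort, seed: int = 0
) -> pd.DataFrame:
    """MAP individual parameters for every patient, one row per patient
    with columns c0.<biomarker>, r.<biomarker>, k[.<biomarker>] and the
    eta entries (eta.<dim>)."""
    model = model_or_fit.estimates if isinstance(model_or_fit, FitResult) else model_or_fit
    rows = []
    for rec in cohort:
        eta, params = map_estimate(model, rec, seed=seed)
        row: dict[str, object] = {"patient_id": rec.patient_id}
        for b, p in params.items():
            row[f"c0.{b}"] = p.c0
            row[f"r.{b}"] = p.r
            if not model.shared_k:
                row[f"k.{b}"] = p.k
        if model.shared_k:
            row["k"] = next(iter(params.values())).k
        for dname, e in zip(model.param_names(), eta):
            row[f"eta.{dname}"] = e
        rows.append(row)
    return pd.DataFrame(rows).set_index("patient_id")


def summarize_individual(
    patient_id: str,
    params: dict[str, IndividualParams],
    limits: NormalLimits = NormalLimits(),
) -> IndividualSummary:
    """Derived response characteristics from individual parameters.

    With a shared k across biomarkers the patient has a single half-life
    and time to 95% of response; steady states and normalization flags are
    per biomarker.
    """
    first = next(iter(params.values()))
    if not isinstance(first, IndividualParams):
        raise TypeError(
            "individual response summaries are defined for the exponential model"
        )
    k = first.k
    ss = {b: steady_state(p) for b, p in params.items()}
    return IndividualSummary(
        patient_id=patient_id,
        k=k,
        half_life_years=half_life(k),
        time_to_95_years=time_to_fraction(k, 0.95),
        steady_state=ss,
        ratio_pct={b: 100.0 * p.r for b, p in params.items()},
        normalized={b: limits.normalized(b, v) for b, v in ss.items()},
    )


def cohort_response_summary(summaries: list[IndividualSummary]) -> pd.DataFrame:
    """Median (range) of the derived quantities and normalization counts,
    mirroring an individual-characteristics results table."""
    if not summaries:
        raise ValueError("no individual summaries")
    rows = []

    def med_range(label, values, unit=""):
        v = np.asarray(values, float)
        rows.append(
            {
                "quantity": label,
                "unit": unit,
                "median": float(np.median(v)),
                "min": float(v.min()),
                "max": float(v.max()),
                "n_normalized": np.nan,
                "pct_normalized": np.nan,
            }
        )

    med_range("half_life", [s.half_life_years for s in summaries], "years")
    med_range("time_to_95", [s.time_to_95_years for s in summaries], "years")
    biomarkers = list(summaries[0].steady_state)
    for b in biomarkers:
        med_range(f"ratio.{b}", [s.ratio_pct[b] for s in summaries], "%")
    for b in biomarkers:
        vals = [s.steady_state[b] for s in summaries]
        n_norm = sum(s.normalized[b] for s in summaries)
        v = np.asarray(vals, float)
        rows.append(
            {
                "quantity": f"steady_state.{b}",
                "unit": "",
                "median": float(np.median(v)),
                "min": float(v.min()),
                "max": float(v.max()),
                "n_normalized": n_norm,
                "pct_normalized": 100.0 * n_norm / len(summaries),
            }
        )
    return pd.DataFrame(rows)
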