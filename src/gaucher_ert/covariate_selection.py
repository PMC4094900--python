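"""Two-step covariate model building.

Step 1 (screening): empirical-Bayes parameter estimates from the
covariate-free model are tested for univariate association with each
candidate covariate — Wilcoxon rank-sum for binary covariates, Spearman
rank correlation for the ordered dose classes — and pairs with p below a
liberal threshold (default 0.2) become candidates.

Step 2 (multivariate): forward selection adds, at each round, the
candidate whose refitted Wald test is most significant, stopping when no
addition reaches the significance level (default 0.05).  For the joint
model, backward elimination removes the weakest included effect until all
retained effects are significant.  Both steps log every decision in a
replayable trace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .estimation import FitSettings, fit_saem, standard_errors
from .population_model import CovariateEffect, PopulationModel
from .registry_io import Cohort, DoseClass, assign_dose_classes

__all__ = [
    "Candidate",
    "screen_covariates",
    "candidate_covariate_table",
    "forward_select",
    "backward_eliminate",
]

#: binary covariates screened against every parameter
BINARY_COVARIATES = ("male", "under15", "splenectomized", "genotype_n370s_hom")
#: ordered covariates (dose classes ranked low < mid < high)
ORDERED_COVARIATES = ("dose_init", "dose_y3")

_DOSE_RANK = {DoseClass.low: 1, DoseClass.mid: 2, DoseClass.high: 3}


@dataclass(frozen=True)
class Candidate:
    """A (parameter dimension, covariate) pair proposed for the model."""

    parameter: str  # "c0" | "r" | "k"
    biomarker: str | None
    covariate: str
    p_screen: float

    def effect(self, beta: float = 0.0) -> CovariateEffect:
        return CovariateEffect(
            parameter=self.parameter,
            biomarker=self.biomarker,
            covariate=self.covariate,
            beta=beta,
        )


def candidate_covariate_table(cohort: Cohort) -> pd.DataFrame:
    """Per-patient covariate values used by the screening tests: binary
    indicators plus ordered dose-class ranks (third-year rank is NaN for
    patients without 3 years of treated follow-up)."""
    rows = []
    for rec in cohort:
        c = rec.covariates
        initial, third = assign_dose_classes(rec) if rec.episodes else (None, None)
        rows.append(
            {
                "patient_id": rec.patient_id,
                "male": float(c.sex == "male"),
                "under15": float(c.under15),
                "splenectomized": float(c.splenectomized),
                "genotype_n370s_hom": float(c.genotype_n370s_hom),
                "dose_init": _DOSE_RANK[initial] if initial else np.nan,
                "dose_y3": _DOSE_RANK[third] if third else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("patient_id")


def _wilcoxon_p(values: np.ndarray, group: np.ndarray) -> float:
    """Two-sample Wilcoxon rank-sum p; exact when either group has fewer
    than 10 patients, normal approximation with tie correction otherwise."""
    a = values[group > 0.5]
    b = values[group <= 0.5]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("fewer than 3 patients per group")
    method = "exact" if min(len(a), len(b)) < 10 else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def screen_covariates(
    ebes: pd.DataFrame,
    covariates: pd.DataFrame,
    alpha_screen: float = 0.2,
    parameters=None,
) -> list[Candidate]:
    """Univariate screening of EBEs against covariates.

    ``ebes``: one row per patient, columns are individual parameter values
    (e.g. ``c0.platelets``, ``r.ferritin``, ``k``); rank tests make the
    result invariant to monotone transformations of these columns.
    ``covariates``: output of :func:`candidate_covariate_table`.
    Returns candidates with p < alpha_screen (strict), sorted by p.
    """
    common = ebes.index.intersection(covariates.index)
    ebes = ebes.loc[common]
    covariates = covariates.loc[common]
    param_cols = (
        parameters
        if parameters is not None
        else [c for c in ebes.columns if c.split(".")[0] in ("c0", "r", "k")]
    )
    out: list[Candidate] = []
    for col in param_cols:
        part = col.split(".")
        pname, bm = part[0], (part[1] if len(part) > 1 else None)
        values = ebes[col].to_numpy(float)
        for cov in BINARY_COVARIATES:
            p = _wilcoxon_p(values, covariates[cov].to_numpy(float))
            if p < alpha_screen:
                out.append(Candidate(pname, bm, cov, p))
        for cov in ORDERED_COVARIATES:
            ranks = covariates[cov].to_numpy(float)
            ok = ~np.isnan(ranks)
            if ok.sum() < 6 or len(np.unique(ranks[ok])) < 2:
                continue
            rho, p = stats.spearmanr(ranks[ok], values[ok])
            if p < alpha_screen:
                out.append(Candidate(pname, bm, cov, float(p)))
    return sorted(out, key=lambda c: (c.p_screen, c.covariate, str(c.biomarker)))


def expand_candidates(candidates: list[Candidate]) -> list[Candidate]:
    """Ordered dose-class candidates become two indicator candidates
    (low and high against the modal 90-120 IU/kg/month reference)."""
    out = []
    for c in candidates:
        if c.covariate in ORDERED_COVARIATES:
            out.append(replace(c, covariate=f"{c.covariate}_low"))
            out.append(replace(c, covariate=f"{c.covariate}_high"))
        else:
            out.append(c)
    return out


@dataclass
class SelectionStep:
    step: int
    candidate: str
    test: str
    p_value: float
    decision: str
    bic: float | None


def _with_effect(model: PopulationModel, eff: CovariateEffect) -> PopulationModel:
    return replace(model, effects=model.effects + (eff,))


def _without_effect(model: PopulationModel, name: str) -> PopulationModel:
    return replace(model, effects=tuple(e for e in model.effects if e.name != name))


def _fit_and_wald(model, cohort, settings, want_loglik=False):
    s = replace(settings, compute_loglik=want_loglik)
    fit = fit_saem(model, cohort, s)
    fit = standard_errors(fit, cohort, method="linearization")
    return fit


def forward_select(
    base: PopulationModel,
    candidates: list[Candidate],
    cohort: Cohort,
    alpha: float = 0.05,
    settings: FitSettings = FitSettings(),
) -> tuple[PopulationModel, pd.DataFrame]:
    """Forward selection by Wald test among screened candidates.

    Each round refits the model with every remaining candidate added in
    turn and keeps the one with the smallest Wald p if it is below alpha
    (ties broken by larger |beta|/se, then name). Returns the selected
    model and the full decision trace.
    """
    candidates = expand_candidates(candidates)
    model = base
    remaining = list(candidates)
    trace: list[SelectionStep] = []
    step = 0
    while remaining:
        results = []
        for cand in remaining:
            eff = cand.effect()
            try:
                fit = _fit_and_wald(_with_effect(model, eff), cohort, settings)
            except Exception as exc:  # refit failure: record and skip
                trace.append(
                    SelectionStep(step, eff.name, "wald", math.nan, f"skipped ({exc})", None)
                )
                continue
            p = fit.wald.get(eff.name, math.nan)
            est_eff = next(e for e in fit.estimates.effects if e.name == eff.name)
            zstat = abs(est_eff.beta) / fit.se[eff.name] if fit.se.get(eff.name) else 0.0
            results.append((cand, fit, p, zstat))
        if not results:
            break
        results.sort(key=lambda r: (r[2], -r[3], r[0].effect().name))
        best_cand, best_fit, best_p, _ = results[0]
        for cand, fit, p, _ in results[1:]:
            trace.append(
                SelectionStep(step, cand.effect().name, "wald", p, "not best", fit.bic)
            )
        if best_p < alpha:
            model = best_fit.estimates
            trace.append(
                SelectionStep(step, best_cand.effect().name, "wald", best_p, "kept", best_fit.bic)
            )
            remaining = [c for c in remaining if c != best_cand]
            step += 1
        else:
            trace.append(
                SelectionStep(step, best_cand.effect().name, "wald", best_p, "stopped", best_fit.bic)
            )
            break
    return model, _trace_frame(trace)


def backward_eliminate(
    full: PopulationModel,
    cohort: Cohort,
    alpha: float = 0.05,
    settings: FitSettings = FitSettings(),
) -> tuple[PopulationModel, pd.DataFrame]:
    """Backward elimination: refit, drop the included effect with the
    largest Wald p >= alpha, repeat until every retained effect is
    significant. Removal order follows descending p."""
    model = full
    trace: list[SelectionStep] = []
    step = 0
    while model.effects:
        fit = _fit_and_wald(model, cohort, settings)
        ps = {e.name: fit.wald.get(e.name, math.nan) for e in model.effects}
        worst = max(ps, key=lambda nm: (ps[nm], nm))
        if not math.isnan(ps[worst]) and ps[worst] >= alpha:
            trace.append(SelectionStep(step, worst, "wald", ps[worst], "dropped", fit.bic))
            model = _without_effect(fit.estimates, worst)
            step += 1
        else:
            for nm, p in sorted(ps.items()):
                trace.append(SelectionStep(step, nm, "wald", p, "kept", fit.bic))
            model = fit.estimates
            break
    return model, _trace_frame(trace)


def _trace_frame(steps: list[SelectionStep]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "step": s.step,
                "candidate": s.candidate,
                "test": s.test,
                "p_value": s.p_value,
                "decision": s.decision,
                "bic": s.bic,
            }
            for s in steps
        ],
        columns=["step", "candidate", "test", "p_value", "decision", "bic"],
    )
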