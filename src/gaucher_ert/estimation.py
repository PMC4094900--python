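"""Estimation of the joint biomarker mixed-effects model.

The marginal likelihood of a nonlinear mixed-effects model has no closed
form, so population parameters are estimated by stochastic-approximation
EM (SAEM): at each iteration the individual log-parameters are refreshed
by a few Metropolis-Hastings transitions targeting their conditional
posterior, sufficient statistics are smoothed with a decreasing step size,
and the M-step updates fixed effects, random-effect SDs and residual SDs
in closed form (everything is estimated on the log scale, so positivity is
automatic and the M-step is linear-Gaussian).

The marginal log-likelihood itself is estimated by importance sampling
with a per-patient Laplace proposal, and model comparison uses
BIC = -2 logL + k log(N) with N the number of patients contributing data.

Standard errors: ``linearization`` (default) computes the expected Fisher
information of the model linearized around each patient's conditional
mode; ``stochastic_fisher`` uses Monte-Carlo conditional expectations of
the complete-data score (Louis' identity, empirical Fisher across
patients); ``bootstrap`` refits on case-resampled cohorts.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logsumexp

from .registry_io import Cohort, PatientRecord
from .population_model import (
    CovariateEffect,
    ErrorModel,
    FixedEffects,
    PopulationModel,
    RandomEffectSpec,
    covariate_vector,
    prior_log_means,
)

__all__ = [
    "FitSettings",
    "FitResult",
    "LogLikEstimate",
    "fit_saem",
    "fit_laplace",
    "loglik_is",
    "bic",
    "wald_p",
    "standard_errors",
    "compare_models",
    "initial_model_from_data",
    "parameter_table",
]

_LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class FitSettings:
    """SAEM schedule and Monte-Carlo sizes.

    Defaults follow common SAEM practice: an exploratory phase with step
    size 1 followed by a smoothing phase with step size m^(-0.7) at
    smoothing iteration m, two MH transitions per iteration.
    """

    seed: int = 0
    n_burnin: int = 300
    n_smoothing: int = 200
    mcmc_transitions: int = 2
    step_exponent: float = 0.7
    is_samples: int = 1000
    convergence_window: int = 50
    compute_loglik: bool = True

    def __post_init__(self) -> None:
        for name in ("n_burnin", "n_smoothing", "mcmc_transitions", "is_samples", "convergence_window"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0.5 < self.step_exponent <= 1.0:
            raise ValueError("step_exponent must lie in (0.5, 1]")


@dataclass(frozen=True)
class LogLikEstimate:
    """Importance-sampling estimate of the marginal log-likelihood."""

    value: float
    se: float
    n_samples: int

    def __float__(self) -> float:
        return self.value


@dataclass
class FitResult:
    estimates: PopulationModel
    loglik: float | None
    loglik_se: float | None
    bic: float | None
    n_parameters: int
    n_patients: int
    trace: pd.DataFrame
    settings: FitSettings
    seed: int
    data_fingerprint: str
    converged: bool
    se: dict[str, float] = field(default_factory=dict)
    rse_pct: dict[str, float] = field(default_factory=dict)
    wald: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# flat likelihood problem


class LikelihoodProblem:
    """Cohort flattened into arrays for vectorized likelihood work.

    Observation o of patient i maps to the parameter dimensions holding its
    biomarker's log c0, log r and log k, so predictions for all patients are
    computed in one shot from the (N, d) matrix of individual log-parameters.
    """

    def __init__(self, model: PopulationModel, cohort: Cohort):
        self.model = model
        self.kind = model.model_kind
        self.dims = model.param_names()
        self.d = len(self.dims)
        dim_idx = {dname: j for j, dname in enumerate(self.dims)}
        third = "k" if self.kind == "exponential" else "t50"
        self.biomarkers = list(model.biomarkers)
        b_idx = {b: i for i, b in enumerate(self.biomarkers)}

        self.patient_ids = list(cohort.patients)
        self.patients = [cohort.patients[pid] for pid in self.patient_ids]
        self.N = len(self.patients)
        if self.N == 0:
            raise ValueError("empty cohort")

        ys, ts, pats, c0d, rd, kd, bidx = [], [], [], [], [], [], []
        for i, rec in enumerate(self.patients):
            obs = rec.eligible_observations()
            for b in self.biomarkers:
                sel = obs[obs["biomarker"] == b]
                if sel.empty:
                    continue
                nloc = len(sel)
                ys.append(sel["value"].to_numpy(float))
                ts.append(sel["time_years"].to_numpy(float))
                pats.append(np.full(nloc, i))
                c0d.append(np.full(nloc, dim_idx[f"c0.{b}"]))
                rd.append(np.full(nloc, dim_idx[f"r.{b}"]))
                kd.append(np.full(nloc, dim_idx[third if model.shared_k else f"{third}.{b}"]))
                bidx.append(np.full(nloc, b_idx[b]))
        if not ys:
            raise ValueError("no likelihood-eligible observations")
        self.y = np.concatenate(ys)
        self.t = np.concatenate(ts)
        self.tpos = np.maximum(self.t, 0.0)
        self.pat = np.concatenate(pats).astype(np.intp)
        self.c0d = np.concatenate(c0d).astype(np.intp)
        self.rd = np.concatenate(rd).astype(np.intp)
        self.kd = np.concatenate(kd).astype(np.intp)
        self.bidx = np.concatenate(bidx).astype(np.intp)
        order = np.argsort(self.pat, kind="stable")
        for name in ("y", "t", "tpos", "pat", "c0d", "rd", "kd", "bidx"):
            setattr(self, name, getattr(self, name)[order])
        self.n_obs = self.y.size
        self.n_obs_b = np.bincount(self.bidx, minlength=len(self.biomarkers))
        starts = np.searchsorted(self.pat, np.arange(self.N + 1))
        self.starts = starts

        # per-dimension covariate design matrices and column names
        xvecs = [covariate_vector(recp) for recp in self.patients]
        self.X: list[np.ndarray] = []
        self.col_names: list[list[str]] = []
        for dname in self.dims:
            effs = model.effects_on(dname)
            cols = [_intercept_name(dname)] + [e.name for e in effs]
            mat = np.ones((self.N, 1 + len(effs)))
            for c, e in enumerate(effs, start=1):
                mat[:, c] = [x[e.covariate] for x in xvecs]
            self.X.append(mat)
            self.col_names.append(cols)
        self.XtX = [x.T @ x for x in self.X]

        # observation subsets touched by each parameter dimension
        self.dim_obs: list[np.ndarray] = []
        for j in range(self.d):
            mask = (self.c0d == j) | (self.rd == j) | (self.kd == j)
            self.dim_obs.append(np.nonzero(mask)[0])

        h = hashlib.sha256()
        for arr in (self.y, self.t, self.pat, self.bidx):
            h.update(np.ascontiguousarray(arr).tobytes())
        self.fingerprint = h.hexdigest()[:16]

    # -- predictions -------------------------------------------------------

    def predict(self, phi: np.ndarray, idx=None) -> np.ndarray:
        """f for observations ``idx`` (all when None) at log-params phi (N,d)."""
        if idx is None:
            c0 = np.exp(phi[self.pat, self.c0d])
            r = np.exp(phi[self.pat, self.rd])
            kk = np.exp(phi[self.pat, self.kd])
            tp = self.tpos
        else:
            p = self.pat[idx]
            c0 = np.exp(phi[p, self.c0d[idx]])
            r = np.exp(phi[p, self.rd[idx]])
            kk = np.exp(phi[p, self.kd[idx]])
            tp = self.tpos[idx]
        if self.kind == "emax":
            return c0 * (1.0 + (r - 1.0) * tp / (kk + tp))  # kk holds T50
        return c0 * (r + (1.0 - r) * np.exp(-kk * tp))

    def obs_terms(self, f: np.ndarray, sigma: np.ndarray, idx=None) -> np.ndarray:
        """Per-observation log-density terms."""
        y = self.y if idx is None else self.y[idx]
        b = self.bidx if idx is None else self.bidx[idx]
        sd = sigma[b] * f
        z = (y - f) / sd
        return -0.5 * z**2 - np.log(sd) - 0.5 * _LOG2PI

    def obs_loglik_by_patient(self, phi: np.ndarray, sigma: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        f = self.predict(phi)
        terms = self.obs_terms(f, sigma)
        return np.bincount(self.pat, weights=terms, minlength=self.N), f

    # -- per-patient likelihood (for MAP / importance sampling) ------------

    def patient_arrays(self, i: int):
        s, e = self.starts[i], self.starts[i + 1]
        return (
            self.y[s:e],
            self.tpos[s:e],
            self.c0d[s:e],
            self.rd[s:e],
            self.kd[s:e],
            self.bidx[s:e],
        )

    def patient_obs_loglik_grad(self, i: int, phi_i: np.ndarray, sigma: np.ndarray):
        """(loglik, gradient wrt phi_i) of patient i's observations.

        Returns (-inf, zeros) when the parameters overflow; optimizers
        treat that as an infeasible step.
        """
        y, tp, c0d, rd, kd, bidx = self.patient_arrays(i)
        grad = np.zeros(self.d)
        if y.size == 0:
            return 0.0, grad
        if np.any(np.abs(phi_i) > 300.0):
            return -np.inf, grad
        c0 = np.exp(phi_i[c0d])
        r = np.exp(phi_i[rd])
        kk = np.exp(phi_i[kd])
        if self.kind == "emax":
            frac = tp / (kk + tp)
            f = c0 * (1.0 + (r - 1.0) * frac)
            df_dlr = c0 * r * frac
            df_dlk = -c0 * (r - 1.0) * frac * kk / (kk + tp)
        else:
            E = np.exp(-kk * tp)
            f = c0 * (r + (1.0 - r) * E)
            df_dlr = c0 * r * (1.0 - E)
            df_dlk = -c0 * (1.0 - r) * kk * tp * E
        sig = sigma[bidx]
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            sd = sig * f
            z = (y - f) / sd
            ll = float(np.sum(-0.5 * z**2 - np.log(sd) - 0.5 * _LOG2PI))
            # dl/df, then chain to log-parameters
            dldf = (y - f) / (sig**2 * f**2) + (y - f) ** 2 / (sig**2 * f**3) - 1.0 / f
            df_dlc0 = f
            np.add.at(grad, c0d, dldf * df_dlc0)
            np.add.at(grad, rd, dldf * df_dlr)
            np.add.at(grad, kd, dldf * df_dlk)
        if not math.isfinite(ll) or not np.all(np.isfinite(grad)):
            return -np.inf, np.zeros(self.d)
        return ll, grad

    def patient_obs_loglik_multi(self, i: int, phi_many: np.ndarray, sigma: np.ndarray) -> np.ndarray:
        """Observation log-likelihood of patient i at many phi rows (M, d)."""
        y, tp, c0d, rd, kd, bidx = self.patient_arrays(i)
        if y.size == 0:
            return np.zeros(phi_many.shape[0])
        c0 = np.exp(phi_many[:, c0d])
        r = np.exp(phi_many[:, rd])
        kk = np.exp(phi_many[:, kd])
        if self.kind == "emax":
            f = c0 * (1.0 + (r - 1.0) * tp[None, :] / (kk + tp[None, :]))
        else:
            f = c0 * (r + (1.0 - r) * np.exp(-kk * tp[None, :]))
        sd = sigma[bidx][None, :] * f
        z = (y[None, :] - f) / sd
        return np.sum(-0.5 * z**2 - np.log(sd) - 0.5 * _LOG2PI, axis=1)

    def prior_means(self, coefs: list[np.ndarray]) -> np.ndarray:
        """(N, d) prior log-means from per-dimension regression coefficients."""
        m = np.empty((self.N, self.d))
        for j in range(self.d):
            m[:, j] = self.X[j] @ coefs[j]
        return m


def _intercept_name(dim: str) -> str:
    part = dim.split(".")
    return f"{part[0]}_pop" if len(part) == 1 else f"{part[0]}_pop.{part[1]}"


def _coefs_from_model(problem: LikelihoodProblem, model: PopulationModel) -> list[np.ndarray]:
    coefs = []
    for j, dname in enumerate(problem.dims):
        effs = model.effects_on(dname)
        coefs.append(
            np.array([math.log(model.pop_value(dname))] + [e.beta for e in effs])
        )
    return coefs


def _model_from_state(
    template: PopulationModel,
    problem: LikelihoodProblem,
    coefs: list[np.ndarray],
    omega: np.ndarray,
    sigma: np.ndarray,
    corr: np.ndarray | None,
) -> PopulationModel:
    c0, r = {}, {}
    k: float | dict[str, float]
    kdict: dict[str, float] = {}
    kshared = None
    new_effects = []
    for j, dname in enumerate(problem.dims):
        val = math.exp(coefs[j][0])
        part = dname.split(".")
        if part[0] == "c0":
            c0[part[1]] = val
        elif part[0] == "r":
            r[part[1]] = val
        elif len(part) == 1:  # shared k or T50
            kshared = val
        else:
            kdict[part[1]] = val
        for e, b in zip(template.effects_on(dname), coefs[j][1:]):
            new_effects.append(replace(e, beta=float(b)))
    k = kshared if template.shared_k else kdict
    omega_d = {dname: float(w) for dname, w in zip(problem.dims, omega)}
    sigma_d = {b: float(s) for b, s in zip(problem.biomarkers, sigma)}
    return PopulationModel(
        shared_k=template.shared_k,
        fixed=FixedEffects(c0=c0, r=r, k=k),
        effects=tuple(new_effects),
        random=RandomEffectSpec(omega=omega_d, correlation=corr),
        error=ErrorModel(sigma=sigma_d),
        model_kind=template.model_kind,
    )


def _natural_values(
    problem: LikelihoodProblem,
    coefs: list[np.ndarray],
    omega: np.ndarray,
    sigma: np.ndarray,
) -> dict[str, float]:
    out: dict[str, float] = {}
    for j, cols in enumerate(problem.col_names):
        out[cols[0]] = math.exp(coefs[j][0])
        for name, b in zip(cols[1:], coefs[j][1:]):
            out[name] = float(b)
    for dname, w in zip(problem.dims, omega):
        out[f"omega.{dname}"] = float(w)
    for b, s in zip(problem.biomarkers, sigma):
        out[f"sigma.{b}"] = float(s)
    return out


# ---------------------------------------------------------------------------
# SAEM


def fit_saem(
    template: PopulationModel,
    cohort: Cohort,
    settings: FitSettings,
    fixed_parameters=(),
) -> FitResult:
    """Fit the model by SAEM. ``template`` provides the structure (which
    biomarkers, shared k, which covariate effects) and the initial values;
    names in ``fixed_parameters`` (e.g. ``"sigma.ferritin"``, ``"k_pop"``)
    are held at their template values. Deterministic for a fixed seed.
    """
    problem = LikelihoodProblem(template, cohort)
    missing = [
        b for b, n in zip(problem.biomarkers, problem.n_obs_b) if n == 0
    ]
    if missing:
        raise ValueError(f"no observations for biomarker(s): {missing}")
    full_omega = template.random.correlation is not None
    if full_omega and any(len(c) > 1 for c in problem.col_names):
        raise ValueError(
            "full random-effect correlation is only supported without covariate effects"
        )
    fixed = frozenset(fixed_parameters)
    rng = np.random.default_rng(settings.seed)

    coefs = _coefs_from_model(problem, template)
    omega = template.omega_vector().copy()
    sigma = np.array([template.error.sigma[b] for b in problem.biomarkers])
    corr = (
        np.asarray(template.random.correlation, float).copy() if full_omega else None
    )

    free_cols = [
        np.array([name not in fixed for name in cols])
        for cols in problem.col_names
    ]
    free_omega = np.array([f"omega.{dname}" not in fixed for dname in problem.dims])
    free_sigma = np.array([f"sigma.{b}" not in fixed for b in problem.biomarkers])

    N, d = problem.N, problem.d
    m = problem.prior_means(coefs)
    phi = m.copy()
    oll, f_cur = problem.obs_loglik_by_patient(phi, sigma)
    rw_scale = 0.4 * omega.copy()

    s_xy = [x.T @ phi[:, j] for j, x in enumerate(problem.X)]
    s_yy = np.array([float(phi[:, j] @ phi[:, j]) for j in range(d)])
    s_err = np.zeros(len(problem.biomarkers))
    s1 = phi.sum(axis=0)
    s2 = phi.T @ phi
    res = (problem.y - f_cur) / f_cur
    s_err = np.bincount(problem.bidx, weights=res**2, minlength=len(problem.biomarkers))

    trace_rows: list[dict[str, float]] = []
    n_iter = settings.n_burnin + settings.n_smoothing

    for it in range(1, n_iter + 1):
        omega_mat = None
        if full_omega:
            omega_mat = corr * np.outer(omega, omega)
            chol = np.linalg.cholesky(omega_mat)
            W = np.linalg.inv(omega_mat)
        for _ in range(settings.mcmc_transitions):
            # independence proposal from the prior
            if full_omega:
                prop = m + rng.standard_normal((N, d)) @ chol.T
            else:
                prop = m + rng.standard_normal((N, d)) * omega
            f_prop = problem.predict(prop)
            terms = problem.obs_terms(f_prop, sigma)
            oll_prop = np.bincount(problem.pat, weights=terms, minlength=N)
            accept = np.log(rng.uniform(size=N)) < (oll_prop - oll)
            if accept.any():
                phi[accept] = prop[accept]
                oll[accept] = oll_prop[accept]
                acc_obs = accept[problem.pat]
                f_cur[acc_obs] = f_prop[acc_obs]

            # componentwise random walk
            for j in range(d):
                idx = problem.dim_obs[j]
                delta = rw_scale[j] * rng.standard_normal(N)
                new_col = phi[:, j] + delta
                phi_new = phi.copy()
                phi_new[:, j] = new_col
                f_new = problem.predict(phi_new, idx)
                t_new = problem.obs_terms(f_new, sigma, idx)
                t_old = problem.obs_terms(f_cur[idx], sigma, idx)
                d_oll = np.bincount(
                    problem.pat[idx], weights=t_new - t_old, minlength=N
                )
                e = phi - m
                if full_omega:
                    we_j = (e @ W)[:, j]
                    d_prior = -(delta * we_j + 0.5 * delta**2 * W[j, j])
                else:
                    d_prior = -0.5 * ((e[:, j] + delta) ** 2 - e[:, j] ** 2) / omega[j] ** 2
                accept = np.log(rng.uniform(size=N)) < (d_oll + d_prior)
                if accept.any():
                    phi[accept, j] = new_col[accept]
                    oll += np.where(accept, d_oll, 0.0)
                    acc_obs = accept[problem.pat[idx]]
                    f_cur[idx[acc_obs]] = f_new[acc_obs]
                if it <= settings.n_burnin:
                    rate = float(accept.mean())
                    rw_scale[j] *= math.exp(0.4 * (rate - 0.35))

        # stochastic approximation of sufficient statistics
        a = 1.0 if it <= settings.n_burnin else (it - settings.n_burnin) ** (
            -settings.step_exponent
        )
        for j in range(d):
            s_xy[j] = (1 - a) * s_xy[j] + a * (problem.X[j].T @ phi[:, j])
            s_yy[j] = (1 - a) * s_yy[j] + a * float(phi[:, j] @ phi[:, j])
        res = (problem.y - f_cur) / f_cur
        err_cur = np.bincount(problem.bidx, weights=res**2, minlength=len(problem.biomarkers))
        s_err = (1 - a) * s_err + a * err_cur
        if full_omega:
            s1 = (1 - a) * s1 + a * phi.sum(axis=0)
            s2 = (1 - a) * s2 + a * (phi.T @ phi)

        # M-step
        if full_omega:
            mu = s1 / N
            for j in range(d):
                if free_cols[j][0]:
                    coefs[j][0] = mu[j]
            cov = s2 / N - np.outer(s1 / N, s1 / N)
            cov = 0.5 * (cov + cov.T)
            w_eig, v_eig = np.linalg.eigh(cov)
            cov = (v_eig * np.maximum(w_eig, 1e-8)) @ v_eig.T
            new_omega = np.sqrt(np.diag(cov))
            omega = np.where(free_omega, new_omega, omega)
            corr = cov / np.outer(np.sqrt(np.diag(cov)), np.sqrt(np.diag(cov)))
            np.fill_diagonal(corr, 1.0)
        else:
            for j in range(d):
                fc = free_cols[j]
                A = problem.XtX[j]
                b = coefs[j]
                if fc.any():
                    rhs = s_xy[j][fc] - A[np.ix_(fc, ~fc)] @ b[~fc]
                    b[fc] = np.linalg.solve(A[np.ix_(fc, fc)], rhs)
                if free_omega[j]:
                    rss = s_yy[j] - 2 * b @ s_xy[j] + b @ A @ b
                    omega[j] = math.sqrt(max(rss / N, 1e-8))
        new_sigma = np.sqrt(np.maximum(s_err / problem.n_obs_b, 1e-10))
        sigma = np.where(free_sigma, new_sigma, sigma)
        m = problem.prior_means(coefs)
        # keep cached obs likelihoods consistent with the new sigma
        oll, f_cur = problem.obs_loglik_by_patient(phi, sigma)

        trace_rows.append(_natural_values(problem, coefs, omega, sigma))

    trace = pd.DataFrame(trace_rows)
    trace.index.name = "iteration"
    converged = _trace_converged(trace, settings.convergence_window)
    if not converged:
        warnings.warn(
            "SAEM trace not settled over the final window; inspect FitResult.trace",
            RuntimeWarning,
            stacklevel=2,
        )
    estimates = _model_from_state(template, problem, coefs, omega, sigma, corr)

    n_params = (
        int(sum(fc.sum() for fc in free_cols))
        + int(free_omega.sum())
        + int(free_sigma.sum())
        + (d * (d - 1) // 2 if full_omega else 0)
    )
    contributing = int(np.unique(problem.pat).size)

    ll = ll_se = bic_val = None
    if settings.compute_loglik:
        est = loglik_is(
            estimates, cohort, is_samples=settings.is_samples, seed=settings.seed + 1
        )
        ll, ll_se = est.value, est.se
        bic_val = bic(ll, n_params, contributing)

    return FitResult(
        estimates=estimates,
        loglik=ll,
        loglik_se=ll_se,
        bic=bic_val,
        n_parameters=n_params,
        n_patients=contributing,
        trace=trace,
        settings=settings,
        seed=settings.seed,
        data_fingerprint=problem.fingerprint,
        converged=converged,
    )


def _trace_converged(trace: pd.DataFrame, window: int) -> bool:
    if len(trace) < 2 * window:
        window = max(len(trace) // 2, 1)
    tail = trace.iloc[-2 * window :]
    first = tail.iloc[:window].mean()
    second = tail.iloc[window:].mean()
    rel = (second - first).abs() / (first.abs() + 1e-8)
    return bool((rel < 0.10).all())


# ---------------------------------------------------------------------------
# conditional modes (shared by importance sampling, EBEs, diagnostics)


def conditional_mode(
    problem: LikelihoodProblem,
    i: int,
    m_i: np.ndarray,
    omega_mat: np.ndarray,
    sigma: np.ndarray,
):
    """MAP random effect of patient i: argmax over eta of
    log p(y_i | m_i + eta) + log N(eta; 0, Omega)."""
    W = np.linalg.inv(omega_mat)

    def negloglik(eta):
        ll, grad = problem.patient_obs_loglik_grad(i, m_i + eta, sigma)
        weta = W @ eta
        if not math.isfinite(ll):
            return 1e12 + float(eta @ eta), eta  # push back toward the prior
        return -(ll - 0.5 * eta @ weta), -(grad - weta)

    res = optimize.minimize(
        negloglik, np.zeros(problem.d), jac=True, method="L-BFGS-B"
    )
    return res.x


def _mode_hessian(problem, i, m_i, omega_mat, sigma, eta_hat, h=1e-4):
    """Negative Hessian of the joint log-density at the mode (finite
    differences of the analytic gradient)."""
    d = problem.d
    W = np.linalg.inv(omega_mat)

    def grad(eta):
        _, g = problem.patient_obs_loglik_grad(i, m_i + eta, sigma)
        return g - W @ eta

    H = np.empty((d, d))
    for j in range(d):
        step = np.zeros(d)
        step[j] = h
        H[:, j] = (grad(eta_hat + step) - grad(eta_hat - step)) / (2 * h)
    H = -0.5 * (H + H.T)
    w_eig, v = np.linalg.eigh(H)
    return (v * np.maximum(w_eig, 1e-8)) @ v.T


def loglik_is(
    model: PopulationModel, cohort: Cohort, is_samples: int = 1000, seed: int = 0
) -> LogLikEstimate:
    """Marginal log-likelihood by importance sampling.

    Per patient the proposal is a multivariate t (5 df) centred on the
    conditional mode with the Laplace covariance; the estimate is
    logsumexp of the weights. Returns value and Monte-Carlo SE.
    """
    problem = LikelihoodProblem(model, cohort)
    rng = np.random.default_rng(seed)
    omega_mat = model.omega_matrix()
    sign, logdet_om = np.linalg.slogdet(omega_mat)
    W = np.linalg.inv(omega_mat)
    sigma = np.array([model.error.sigma[b] for b in problem.biomarkers])
    df = 5.0
    d = problem.d

    total = 0.0
    var_total = 0.0
    for i, rec in enumerate(problem.patients):
        m_i = prior_log_means(model, rec)
        if problem.starts[i + 1] == problem.starts[i]:
            continue  # no data: marginal contribution is 1
        eta_hat = conditional_mode(problem, i, m_i, omega_mat, sigma)
        H = _mode_hessian(problem, i, m_i, omega_mat, sigma, eta_hat)
        cov = np.linalg.inv(H)
        try:
            L = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(f"degenerate proposal for patient {rec.patient_id}") from exc
        z = rng.standard_normal((is_samples, d))
        u = rng.chisquare(df, size=is_samples) / df
        etas = eta_hat + (z @ L.T) / np.sqrt(u)[:, None]
        # proposal log-density (multivariate t)
        sign, logdet_cov = np.linalg.slogdet(cov)
        diff = etas - eta_hat
        quad = np.einsum("ij,jk,ik->i", diff, H, diff)
        log_q = (
            math.lgamma((df + d) / 2)
            - math.lgamma(df / 2)
            - 0.5 * d * math.log(df * math.pi)
            - 0.5 * logdet_cov
            - 0.5 * (df + d) * np.log1p(quad / df)
        )
        log_prior = -0.5 * (
            d * _LOG2PI + logdet_om + np.einsum("ij,jk,ik->i", etas, W, etas)
        )
        log_obs = problem.patient_obs_loglik_multi(i, m_i + etas, sigma)
        log_w = log_obs + log_prior - log_q
        mx = np.max(log_w)
        w = np.exp(log_w - mx)
        ll_i = mx + math.log(np.mean(w))
        total += ll_i
        wbar = np.mean(w)
        var_total += float(np.var(w) / (is_samples * wbar**2))
    return LogLikEstimate(
        value=float(total), se=float(math.sqrt(var_total)), n_samples=is_samples
    )


# ---------------------------------------------------------------------------
# information criteria and tests


def bic(loglik: float, n_parameters: int, n_patients: int) -> float:
    """Bayesian information criterion, -2 logL + k log(N), N = patients."""
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    return -2.0 * float(loglik) + n_parameters * math.log(n_patients)


def wald_p(beta: float, se: float) -> float:
    """Two-sided Wald p-value, 2 (1 - Phi(|beta| / se))."""
    if not se > 0:
        raise ValueError("se must be positive")
    return float(2.0 * stats.norm.sf(abs(beta) / se))


def compare_models(fits: list[FitResult], names=None) -> pd.DataFrame:
    """Rank fits of the same data by BIC (ascending; lower is better)."""
    if not fits:
        raise ValueError("no fits to compare")
    prints = {f.data_fingerprint for f in fits}
    if len(prints) > 1:
        raise ValueError("fits were obtained on different data")
    if any(f.bic is None for f in fits):
        raise ValueError("all fits need a BIC (run with compute_loglik=True)")
    names = names if names is not None else [f"model_{i}" for i in range(len(fits))]
    df = pd.DataFrame(
        {
            "model": names,
            "bic": [f.bic for f in fits],
            "loglik": [f.loglik for f in fits],
            "n_parameters": [f.n_parameters for f in fits],
        }
    ).sort_values("bic", kind="stable", ignore_index=True)
    df["delta_bic"] = df["bic"] - df["bic"].iloc[0]
    return df


# ---------------------------------------------------------------------------
# standard errors


def _est_vector(problem, coefs, omega, sigma):
    """Estimation-scale parameter vector and names (log intercepts, raw
    betas, log omegas, log sigmas)."""
    vals, names = [], []
    for j, cols in enumerate(problem.col_names):
        vals.append(coefs[j][0])
        names.append(cols[0])
        for name, b in zip(cols[1:], coefs[j][1:]):
            vals.append(b)
            names.append(name)
    for dname, w in zip(problem.dims, omega):
        vals.append(math.log(w))
        names.append(f"omega.{dname}")
    for b, s in zip(problem.biomarkers, sigma):
        vals.append(math.log(s))
        names.append(f"sigma.{b}")
    return np.array(vals), names


def _unpack_est_vector(problem, theta):
    coefs, pos = [], 0
    for cols in problem.col_names:
        q = len(cols)
        coefs.append(theta[pos : pos + q].copy())
        pos += q
    omega = np.exp(theta[pos : pos + problem.d])
    pos += problem.d
    sigma = np.exp(theta[pos : pos + len(problem.biomarkers)])
    return coefs, omega, sigma


def standard_errors(
    fit: FitResult, cohort: Cohort, method: str = "linearization", n_boot: int = 20
) -> FitResult:
    """Fill ``se``, ``rse_pct`` and per-beta Wald p-values of a fit.

    ``linearization``: expected Fisher information of the Gaussian marginal
    obtained by linearizing the model around each patient's conditional
    mode. ``stochastic_fisher``: empirical Fisher from Monte-Carlo
    conditional expectations of the complete-data score (diagonal Omega
    only). ``bootstrap``: case resampling with refits (n_boot replicates).
    """
    model = fit.estimates
    if model.random.correlation is not None and method != "bootstrap":
        raise NotImplementedError(
            "analytic standard errors are implemented for diagonal Omega only"
        )
    problem = LikelihoodProblem(model, cohort)
    coefs = _coefs_from_model(problem, model)
    omega = model.omega_vector()
    sigma = np.array([model.error.sigma[b] for b in problem.biomarkers])
    theta0, names = _est_vector(problem, coefs, omega, sigma)

    if method == "linearization":
        cov = _fisher_linearization(problem, theta0)
    elif method == "stochastic_fisher":
        cov = _fisher_stochastic(problem, theta0, seed=fit.seed + 2)
    elif method == "bootstrap":
        cov = _cov_bootstrap(fit, cohort, n_boot)
    else:
        raise ValueError(f"unknown method {method!r}")

    se_est = np.sqrt(np.maximum(np.diag(cov), 0.0))
    se, rse, wald = {}, {}, {}
    natural = _natural_values(problem, coefs, omega, sigma)
    for name, s in zip(names, se_est):
        val = natural[name]
        if name.startswith("beta."):
            se[name] = s
            rse[name] = 100.0 * s / abs(val) if val != 0 else math.inf
            # report precision of the multiplicative effect exp(beta) too
            se[f"exp({name})"] = abs(math.exp(val)) * s
            wald[name] = wald_p(val, s) if s > 0 else math.nan
        else:
            # log-scale SE -> natural scale by the delta method
            se[name] = abs(val) * s
            rse[name] = 100.0 * s
    return replace(fit, se=se, rse_pct=rse, wald=wald)


def _patient_linearization(problem, i, m, coefs, omega, sigma):
    """Marginal mean and covariance of patient i's data under the model
    linearized at the stored conditional mode ``problem._modes[i]``."""
    eta_hat = problem._modes[i]
    phi_i = m[i] + eta_hat
    y, tp, c0d, rd, kd, bidx = problem.patient_arrays(i)
    c0 = np.exp(phi_i[c0d])
    r = np.exp(phi_i[rd])
    kk = np.exp(phi_i[kd])
    if problem.kind == "emax":
        frac = tp / (kk + tp)
        f = c0 * (1.0 + (r - 1.0) * frac)
        j_r = c0 * r * frac
        j_k = -c0 * (r - 1.0) * frac * kk / (kk + tp)
    else:
        E = np.exp(-kk * tp)
        f = c0 * (r + (1.0 - r) * E)
        j_r = c0 * r * (1.0 - E)
        j_k = -c0 * (1.0 - r) * kk * tp * E
    J = np.zeros((y.size, problem.d))
    rows = np.arange(y.size)
    np.add.at(J, (rows, c0d), f)
    np.add.at(J, (rows, rd), j_r)
    np.add.at(J, (rows, kd), j_k)
    mu = f - J @ eta_hat
    V = J @ (np.diag(omega**2)) @ J.T + np.diag((sigma[bidx] * f) ** 2)
    return mu, V


def _fisher_linearization(problem, theta0, h=1e-4):
    # conditional modes at the central estimates, held fixed under perturbation
    coefs, omega, sigma = _unpack_est_vector(problem, theta0)
    m = problem.prior_means(coefs)
    omega_mat = np.diag(omega**2)
    problem._modes = [
        conditional_mode(problem, i, m[i], omega_mat, sigma)
        if problem.starts[i + 1] > problem.starts[i]
        else np.zeros(problem.d)
        for i in range(problem.N)
    ]
    active = [i for i in range(problem.N) if problem.starts[i + 1] > problem.starts[i]]

    def marginal(theta):
        coefs, omega, sigma = _unpack_est_vector(problem, theta)
        m = problem.prior_means(coefs)
        return [
            _patient_linearization(problem, i, m, coefs, omega, sigma) for i in active
        ]

    P = theta0.size
    n_mean = sum(len(c) for c in problem.col_names)  # intercepts + betas
    base = marginal(theta0)
    d_mu = [[None] * P for _ in active]
    d_V = [[None] * P for _ in active]
    for p in range(P):
        step = np.zeros(P)
        step[p] = h
        plus = marginal(theta0 + step)
        minus = marginal(theta0 - step)
        for a in range(len(active)):
            d_mu[a][p] = (plus[a][0] - minus[a][0]) / (2 * h)
            d_V[a][p] = (plus[a][1] - minus[a][1]) / (2 * h)

    # Block-diagonal expected information: mean parameters inform through
    # the mean channel only, variance parameters (omega, sigma) through the
    # covariance channel only.  The proportional-error marginal covariance
    # also varies with the mean parameters, but that channel reflects the
    # linearization rather than information the latent-variable likelihood
    # actually delivers, so it is excluded (the usual block assumption).
    fim = np.zeros((P, P))
    is_mean = np.arange(P) < n_mean
    for a in range(len(active)):
        _, V = base[a]
        Vinv = np.linalg.inv(V)
        dmu = np.stack(d_mu[a])  # (P, n)
        dmu[~is_mean] = 0.0
        B = dmu @ Vinv  # (P, n)
        fim += B @ dmu.T
        A = np.stack([Vinv @ d_V[a][p] if not is_mean[p] else np.zeros_like(V) for p in range(P)])
        fim += 0.5 * np.einsum("pij,qji->pq", A, A)
    return np.linalg.inv(fim)


def _fisher_stochastic(problem, theta0, seed, n_draws=400):
    """Empirical Fisher from conditional expectations of the complete-data
    score, with the expectation taken by importance sampling at the modes."""
    coefs, omega, sigma = _unpack_est_vector(problem, theta0)
    m = problem.prior_means(coefs)
    omega_mat = np.diag(omega**2)
    rng = np.random.default_rng(seed)
    P = theta0.size
    d = problem.d
    nb = len(problem.biomarkers)
    fim = np.zeros((P, P))
    for i in range(problem.N):
        if problem.starts[i + 1] == problem.starts[i]:
            continue
        eta_hat = conditional_mode(problem, i, m[i], omega_mat, sigma)
        H = _mode_hessian(problem, i, m[i], omega_mat, sigma, eta_hat)
        L = np.linalg.cholesky(np.linalg.inv(H))
        etas = eta_hat + rng.standard_normal((n_draws, d)) @ L.T
        log_obs = problem.patient_obs_loglik_multi(i, m[i] + etas, sigma)
        log_prior = -0.5 * np.sum((etas / omega) ** 2, axis=1)
        diff = etas - eta_hat
        log_q = -0.5 * np.einsum("ij,jk,ik->i", diff, H, diff)
        log_w = log_obs + log_prior - log_q
        w = np.exp(log_w - logsumexp(log_w))
        # complete-data scores on the estimation scale
        scores = np.zeros((n_draws, P))
        pos = 0
        for j, x in enumerate(problem.X):
            q = x.shape[1]
            scores[:, pos : pos + q] = np.outer(
                etas[:, j] / omega[j] ** 2, x[i]
            )
            pos += q
        scores[:, pos : pos + d] = (etas / omega) ** 2 - 1.0
        pos += d
        y, tp, c0d, rd, kd, bidx = problem.patient_arrays(i)
        c0 = np.exp((m[i] + etas)[:, c0d])
        r = np.exp((m[i] + etas)[:, rd])
        kk = np.exp((m[i] + etas)[:, kd])
        f = c0 * (r + (1.0 - r) * np.exp(-kk * tp[None, :]))
        z = (y[None, :] - f) / (sigma[bidx][None, :] * f)
        for bi in range(nb):
            sel = bidx == bi
            scores[:, pos + bi] = np.sum(z[:, sel] ** 2 - 1.0, axis=1)
        g = w @ scores
        fim += np.outer(g, g)
    return np.linalg.inv(fim)


def _cov_bootstrap(fit, cohort, n_boot):
    rng = np.random.default_rng(fit.seed + 3)
    ids = list(cohort.patients)
    draws = []
    problem = LikelihoodProblem(fit.estimates, cohort)
    for b in range(n_boot):
        chosen = rng.choice(ids, size=len(ids), replace=True)
        patients = {}
        for rep, pid in enumerate(chosen):
            rec = cohort.patients[pid]
            patients[f"{pid}__{rep}"] = replace(rec, patient_id=f"{pid}__{rep}")
        boot = Cohort(patients)
        boot_settings = replace(fit.settings, seed=fit.seed + 100 + b, compute_loglik=False)
        res = fit_saem(fit.estimates, boot, boot_settings)
        bp = LikelihoodProblem(res.estimates, boot)
        coefs = _coefs_from_model(bp, res.estimates)
        omega = res.estimates.omega_vector()
        sigma = np.array([res.estimates.error.sigma[bm] for bm in bp.biomarkers])
        vec, _ = _est_vector(bp, coefs, omega, sigma)
        draws.append(vec)
    return np.cov(np.array(draws).T, ddof=1)


# ---------------------------------------------------------------------------
# deterministic Laplace fitter (cross-check for small models)


def fit_laplace(
    template: PopulationModel,
    cohort: Cohort,
    fixed_parameters=(),
    maxiter: int = 300,
) -> PopulationModel:
    """Maximize the Laplace-approximated marginal likelihood.

    Deterministic alternative to SAEM for small problems; used as a
    cross-check, not as the production fitter. Diagonal Omega only.
    """
    if template.random.correlation is not None:
        raise NotImplementedError("Laplace fitter supports diagonal Omega only")
    problem = LikelihoodProblem(template, cohort)
    fixed = frozenset(fixed_parameters)
    coefs0 = _coefs_from_model(problem, template)
    omega0 = template.omega_vector()
    sigma0 = np.array([template.error.sigma[b] for b in problem.biomarkers])
    theta0, names = _est_vector(problem, coefs0, omega0, sigma0)
    free = np.array([nm not in fixed for nm in names])
    warm = [np.zeros(problem.d) for _ in range(problem.N)]

    def objective(theta_free):
        theta = theta0.copy()
        theta[free] = theta_free
        coefs, omega, sigma = _unpack_est_vector(problem, theta)
        m = problem.prior_means(coefs)
        omega_mat = np.diag(omega**2)
        W = np.linalg.inv(omega_mat)
        total = 0.0
        for i in range(problem.N):
            if problem.starts[i + 1] == problem.starts[i]:
                continue

            def negloglik(eta, i=i, m_i=m[i]):
                ll, grad = problem.patient_obs_loglik_grad(i, m_i + eta, sigma)
                weta = W @ eta
                if not math.isfinite(ll):
                    return 1e12 + float(eta @ eta), eta
                return -(ll - 0.5 * eta @ weta), -(grad - weta)

            res = optimize.minimize(negloglik, warm[i], jac=True, method="L-BFGS-B")
            warm[i] = res.x
            eta_hat = res.x
            ll, _ = problem.patient_obs_loglik_grad(i, m[i] + eta_hat, sigma)
            ll += -0.5 * float(np.sum((eta_hat / omega) ** 2)) - float(
                np.sum(np.log(omega))
            ) - 0.5 * problem.d * _LOG2PI
            H = _mode_hessian(problem, i, m[i], omega_mat, sigma, eta_hat)
            sign, logdet = np.linalg.slogdet(H)
            total += ll + 0.5 * problem.d * _LOG2PI - 0.5 * logdet
        return -total

    res = optimize.minimize(
        objective,
        theta0[free],
        method="Powell",
        options={"maxiter": maxiter, "xtol": 1e-5, "ftol": 1e-7},
    )
    theta = theta0.copy()
    theta[free] = res.x
    coefs, omega, sigma = _unpack_est_vector(problem, theta)
    return _model_from_state(template, problem, coefs, omega, sigma, None)


# ---------------------------------------------------------------------------
# initial values and reporting


def initial_model_from_data(
    cohort: Cohort,
    shared_k: bool = True,
    effects: tuple[CovariateEffect, ...] = (),
    model_kind: str = "exponential",
) -> PopulationModel:
    """Crude data-driven initial values: baseline from early observations,
    amplitude from the late/early ratio, k = 1/year (T50 = 0.7 years for
    the Emax comparator), generous variabilities."""
    from .registry_io import BIOMARKERS

    obs = cohort.observations_frame()
    obs = obs[~obs["excluded"]]
    c0, r = {}, {}
    for b in BIOMARKERS:
        sel = obs[obs["biomarker"] == b]
        if sel.empty:
            continue
        early = sel[sel["time_years"] <= 0.25]["value"]
        late = sel[sel["time_years"] >= 2.0]["value"]
        base = float(np.exp(np.log(early).mean())) if len(early) else float(
            np.exp(np.log(sel["value"]).mean())
        )
        c0[b] = base
        r[b] = float(np.exp(np.log(late).mean()) / base) if len(late) else 1.0
        r[b] = min(max(r[b], 0.02), 50.0)
    k_init = 1.0 if model_kind == "exponential" else 0.7
    k = k_init if shared_k else {b: k_init for b in c0}
    stub = PopulationModel(
        shared_k=shared_k,
        fixed=FixedEffects(c0=c0, r=r, k=k),
        effects=effects,
        model_kind=model_kind,
    )
    omega = {dname: 0.5 for dname in stub.param_names()}
    sigma = {b: 0.3 for b in c0}
    return PopulationModel(
        shared_k=shared_k,
        fixed=FixedEffects(c0=c0, r=r, k=k),
        effects=effects,
        random=RandomEffectSpec(omega=omega),
        error=ErrorModel(sigma=sigma),
        model_kind=model_kind,
    )


def parameter_table(fit: FitResult) -> pd.DataFrame:
    """Fixed effects and variabilities with RSE% and Wald p-values, in the
    layout of a population-model results table."""
    model = fit.estimates
    rows = []
    for b in model.biomarkers:
        rows.append((f"c0_pop.{b}", model.fixed.c0[b]))
        for e in model.effects_on(f"c0.{b}"):
            rows.append((e.name, math.exp(e.beta)))
    for b in model.biomarkers:
        rows.append((f"r_pop.{b}", model.fixed.r[b]))
        for e in model.effects_on(f"r.{b}"):
            rows.append((e.name, math.exp(e.beta)))
    third = "k" if model.model_kind == "exponential" else "t50"
    if model.shared_k:
        rows.append((f"{third}_pop", model.fixed.k))
        for e in model.effects_on(third):
            rows.append((e.name, math.exp(e.beta)))
    else:
        for b in model.biomarkers:
            rows.append((f"{third}_pop.{b}", model.fixed.k[b]))
    for dname in model.param_names():
        rows.append((f"omega.{dname}", 100.0 * model.random.omega[dname]))
    for b in model.biomarkers:
        rows.append((f"sigma.{b}", 100.0 * model.error.sigma[b]))
    df = pd.DataFrame(rows, columns=["parameter", "estimate"])
    df["rse_pct"] = [fit.rse_pct.get(p, math.nan) for p in df["parameter"]]
    df["p_value"] = [fit.wald.get(p, math.nan) for p in df["parameter"]]
    return df
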