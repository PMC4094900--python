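"""Goodness-of-fit diagnostics: individual weighted residuals and the
visual predictive check (VPC).

IWRES for an observation y with individual (MAP) prediction f is
(y - f) / (sigma_b * f); under a correct model it is approximately
standard normal.  The VPC simulates many replicate cohorts on the actual
design at the estimated parameters and compares observed percentiles per
time bin with the simulated percentile bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimation import FitResult, LikelihoodProblem, _coefs_from_model
from .individual_inference import map_estimate
from .population_model import PopulationModel, predict_any
from .registry_io import Cohort

__all__ = ["VpcResult", "iwres", "vpc", "plot_vpc", "plot_iwres"]


def _model_of(model_or_fit) -> PopulationModel:
    return model_or_fit.estimates if isinstance(model_or_fit, FitResult) else model_or_fit


def iwres(model_or_fit, cohort: Cohort, seed: int = 0) -> pd.DataFrame:
    """Individual weighted residuals from MAP parameters, one row per
    likelihood-eligible observation (excluded rows are absent)."""
    model = _model_of(model_or_fit)
    rows = []
    for rec in cohort:
        obs = rec.eligible_observations()
        if obs.empty:
            continue
        _, params = map_estimate(model, rec, seed=seed)
        for b in model.biomarkers:
            sel = obs[obs["biomarker"] == b]
            if sel.empty:
                continue
            t = sel["time_years"].to_numpy(float)
            y = sel["value"].to_numpy(float)
            f = np.asarray(predict_any(params[b], t), float)
            if np.any(f <= 0):
                raise ValueError("non-positive individual prediction")
            res = (y - f) / (model.error.sigma[b] * f)
            for ti, yi, fi, ri in zip(t, y, f, res):
                rows.append(
                    {
                        "patient_id": rec.patient_id,
                        "biomarker": b,
                        "time_years": ti,
                        "value": yi,
                        "prediction": fi,
                        "iwres": ri,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["patient_id", "biomarker", "time_years", "value", "prediction", "iwres"],
    )


@dataclass
class VpcResult:
    """Observed vs simulated percentiles per biomarker and time bin.

    ``table`` columns: biomarker, bin, t_lo, t_hi, t_mid, n_obs, merged,
    obs_p5, obs_p50, obs_p95, and for each simulated percentile the median
    and 2.5/97.5% Monte-Carlo band (sim_p50_lo etc.).  ``coverage_90`` is
    the fraction of observations inside the simulated per-observation
    5-95% envelope, per biomarker.
    """

    table: pd.DataFrame
    n_sim: int
    seed: int
    percentiles: tuple[float, float, float] = (5.0, 50.0, 95.0)
    coverage_90: dict[str, float] | None = None


def _time_bins(times: np.ndarray, n_bins: int, min_per_bin: int):
    """Decile-style bins of on-treatment times; pre-treatment times form
    their own bin. Bins with fewer than ``min_per_bin`` observations are
    merged with a neighbor and flagged."""
    bins: list[tuple[float, float, bool]] = []
    pre = times[times <= 0]
    post = np.sort(times[times > 0])
    if pre.size:
        bins.append((float(pre.min()), 0.0, pre.size < min_per_bin))
    if post.size:
        qs = np.unique(np.quantile(post, np.linspace(0, 1, n_bins + 1)))
        raw = [(float(qs[i]), float(qs[i + 1])) for i in range(len(qs) - 1)]
        counts = []
        for i, (lo, hi) in enumerate(raw):
            inbin = (post > lo) & (post <= hi) if i > 0 else (post >= lo) & (post <= hi)
            counts.append(int(inbin.sum()))
        merged = [False] * len(raw)
        i = 0
        while i < len(raw) and len(raw) > 1:
            if counts[i] < min_per_bin:
                tgt = i - 1 if i > 0 else 1
                lo = min(raw[tgt][0], raw[i][0])
                hi = max(raw[tgt][1], raw[i][1])
                raw[tgt] = (lo, hi)
                counts[tgt] += counts[i]
                merged[tgt] = True
                del raw[i], counts[i], merged[i]
                i = max(i - 1, 0)
            else:
                i += 1
        bins.extend((lo, hi, fl) for (lo, hi), fl in zip(raw, merged))
    return bins


def _bin_index(times: np.ndarray, bins) -> np.ndarray:
    idx = np.full(times.size, -1)
    post_bins = [b for b in bins if b[1] > 0]
    first_post_lo = min(b[0] for b in post_bins) if post_bins else None
    for bi, (lo, hi, _) in enumerate(bins):
        if hi <= 0:
            sel = times <= 0
        else:
            sel = (times > lo) & (times <= hi)
            if lo == first_post_lo:
                sel |= times == lo
        idx[(idx < 0) & sel] = bi
    return idx


def vpc(
    model_or_fit,
    cohort: Cohort,
    n_sim: int = 500,
    seed: int = 0,
    n_bins: int = 10,
    min_per_bin: int = 5,
    percentiles=(5.0, 50.0, 95.0),
) -> VpcResult:
    """Visual predictive check on the cohort's own design.

    Simulates ``n_sim`` replicates (new random effects and residual noise;
    same patients, covariates and sampling times — covariate heterogeneity
    is carried by the design, with no prediction correction), bins
    observation times per biomarker, and reports observed percentiles next
    to the simulated percentile bands.
    """
    model = _model_of(model_or_fit)
    rng = np.random.default_rng(seed)
    problem = LikelihoodProblem(model, cohort)
    m = problem.prior_means(_coefs_from_model(problem, model))
    chol = np.linalg.cholesky(model.omega_matrix())
    sigma = np.array([model.error.sigma[b] for b in problem.biomarkers])
    sig_obs = sigma[problem.bidx]

    sims = np.empty((n_sim, problem.n_obs))
    for s in range(n_sim):
        etas = rng.standard_normal((problem.N, problem.d)) @ chol.T
        f = problem.predict(m + etas)
        y = f * (1.0 + rng.normal(0.0, sig_obs))
        bad = y <= 0
        while bad.any():  # same positivity rule as the data generator
            y[bad] = f[bad] * (1.0 + rng.normal(0.0, sig_obs[bad]))
            bad = y <= 0
        sims[s] = y

    rows = []
    coverage: dict[str, float] = {}
    for bi_idx, b in enumerate(problem.biomarkers):
        sel = problem.bidx == bi_idx
        if not sel.any():
            continue
        times = problem.t[sel]
        values = problem.y[sel]
        sims_b = sims[:, sel]
        lo_env = np.percentile(sims_b, percentiles[0], axis=0)
        hi_env = np.percentile(sims_b, percentiles[2], axis=0)
        coverage[b] = float(np.mean((values >= lo_env) & (values <= hi_env)))

        bins = _time_bins(times, n_bins, min_per_bin)
        idx = _bin_index(times, bins)
        for bi, (lo, hi, merged) in enumerate(bins):
            inbin = idx == bi
            if not inbin.any():
                continue
            row = {
                "biomarker": b,
                "bin": bi,
                "t_lo": lo,
                "t_hi": hi,
                "t_mid": float(np.median(times[inbin])),
                "n_obs": int(inbin.sum()),
                "merged": merged,
            }
            for p, tag in zip(percentiles, ("p5", "p50", "p95")):
                row[f"obs_{tag}"] = float(np.percentile(values[inbin], p))
                sim_stat = np.percentile(sims_b[:, inbin], p, axis=1)
                row[f"sim_{tag}"] = float(np.median(sim_stat))
                row[f"sim_{tag}_lo"] = float(np.percentile(sim_stat, 2.5))
                row[f"sim_{tag}_hi"] = float(np.percentile(sim_stat, 97.5))
            rows.append(row)
    return VpcResult(
        table=pd.DataFrame(rows),
        n_sim=n_sim,
        seed=seed,
        percentiles=tuple(percentiles),
        coverage_90=coverage,
    )


def plot_iwres(residuals: pd.DataFrame, path, table_path=None) -> None:
    """IWRES versus time, one panel per biomarker; the underlying numbers
    are written as CSV next to the figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    biomarkers = sorted(residuals["biomarker"].unique())
    fig, axes = plt.subplots(
        1, len(biomarkers), figsize=(4 * len(biomarkers), 3.2), squeeze=False
    )
    for ax, b in zip(axes[0], biomarkers):
        sel = residuals[residuals["biomarker"] == b]
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.scatter(sel["time_years"], sel["iwres"], s=6, alpha=0.5)
        ax.set_title(b)
        ax.set_xlabel("time since ERT start (years)")
    axes[0][0].set_ylabel("IWRES")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    residuals.to_csv(table_path or str(path) + ".csv", index=False)


def plot_vpc(result: VpcResult, path, table_path=None) -> None:
    """Observed percentiles over the simulated bands, one panel per
    biomarker; the underlying numbers are written as CSV next to the
    figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = result.table
    biomarkers = sorted(table["biomarker"].unique())
    fig, axes = plt.subplots(
        1, len(biomarkers), figsize=(4 * len(biomarkers), 3.2), squeeze=False
    )
    for ax, b in zip(axes[0], biomarkers):
        sel = table[table["biomarker"] == b].sort_values("t_mid")
        for tag, style in (("p5", "--"), ("p50", "-"), ("p95", "--")):
            ax.fill_between(
                sel["t_mid"], sel[f"sim_{tag}_lo"], sel[f"sim_{tag}_hi"],
                alpha=0.2, lw=0,
            )
            ax.plot(sel["t_mid"], sel[f"obs_{tag}"], style, color="k", lw=1)
        ax.set_yscale("log")
        ax.set_title(b)
        ax.set_xlabel("time since ERT start (years)")
    axes[0][0].set_ylabel("biomarker value")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    table.to_csv(table_path or str(path) + ".csv", index=False)
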