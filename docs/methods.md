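# Methods and implementation notes

## Structural model

Each biomarker is assumed to be produced at a rate that tracks the
macrophage substrate burden and eliminated by a first-order process with
rate constant λ. Under ERT the substrate burden decays exponentially
with rate constant k, so the turnover ODE

    dC/dt = R(t) − λ C,    R(t) = λ C0 [r + (1 − r) e^(−k t)],  C(0) = C0

has the closed-form solution implemented in
`structural_models.turnover_profile`. The production term is anchored so
the system starts at equilibrium (R(0) = λC0) and its quasi-steady-state
equals the simplified model exactly; this anchoring is a reconstruction
of the mechanistic scheme, chosen so the fast-elimination limit is
exact. Because biomarker elimination is fast relative to substrate
normalization (λ ≫ k), the quasi-steady-state limit

    C(t) = C0 [r + (1 − r) e^(−k t)]

is used for all inference (`predict_profile`). The two printed forms of
the model — the "decreasing" form above and the "increasing" form
C0[1 + (r−1)(1−e^(−kt))] — are algebraically identical; one formula
serves both directions, and the direction is a property of r alone
(r < 1 falls, r > 1 rises). The sup-norm deviation between the turnover
model and its limit is below 1 % at λ/k = 1000 and decreases
monotonically in λ/k (tested at 10/100/1000).

Pre-treatment prediction is the constant C0 for t ≤ 0: the model has no
pre-ERT dynamics, but pre-ERT observations (back to −2 years) enter the
fit and inform C0 directly.

Derived quantities: steady state C0·r; half-life ln2/k; time to a
fraction f of response −ln(1−f)/k, so time to 95 % is ln20/k = 4.32
half-lives (reported displays round this to 4.3). The Emax comparator is
parameterized with the same C0 and r (plus T50) so that BIC comparisons
involve equal parameter counts; the full population machinery (SAEM,
importance-sampling likelihood, BIC) accepts either structural model via
`PopulationModel.model_kind`, with T50 occupying the third parameter
slot. Individual response summaries (half-life, time to 95 %,
normalization) are defined for the exponential model only.

## Population model

All structural parameters are lognormal:
log θ_i = log θ_pop + Σ_j β_j x_ij + η_i, with η ~ N(0, Ω) and binary
covariate indicators x (male, under-15 at ERT initiation, splenectomy,
N370S/N370S, dose-class indicators low/high against the modal 90–120
IU/kg/month class). Residual error is proportional, y = f(1 + ε),
ε ~ N(0, σ_b²) per biomarker. With a shared k the random-effect vector
has 9 dimensions for the four-biomarker model (c0 and r per biomarker
plus one k), matching the 9 ω entries of the reference parameter table;
with per-biomarker k, 12.

Ω is diagonal by default. A full correlation matrix is supported in
simulation always, and in estimation only for models without covariate
effects (where the M-step stays a closed-form multivariate regression);
correlated-random-effect models with covariates would need a coupled
GLS M-step and are out of scope.

Simulated proportional-error draws that would give y ≤ 0 are rejected
and resampled so stored values stay physically valid; the likelihood
remains the untruncated normal. This matters only where σ is large: at
σ = 0.61 (the chitotriosidase residual SD of the reference estimates)
about 5 % of draws are truncated, which biases the refitted σ for that
biomarker downward by roughly 20 % (≈9 % of it attributable to the
truncated residual SD itself, the rest to empirical-Bayes absorption).
At σ ≤ 0.3 the effect is negligible and σ is recovered without bias.
Parameter-recovery results for the chitotriosidase σ must be read with
this generator/likelihood mismatch in mind.

## Estimation

SAEM with an MCMC E-step, all parameters estimated on the log scale:

* E-step kernel per iteration (default 2 transitions): one independence
  proposal from the prior N(m_i, Ω) for every patient, then one
  componentwise random-walk sweep over the 9 (or 12) dimensions, with
  per-dimension step sizes adapted toward ~35 % acceptance during the
  exploratory phase only (so the smoothing phase is a fixed kernel).
* Schedule: 300 exploratory iterations with step size 1, then 200
  smoothing iterations with step size m^(−0.7); both phases and the
  exponent are settable in `FitSettings`.
* Sufficient statistics: per dimension, X'φ and φ'φ (X the per-dimension
  covariate design); the M-step is a per-dimension linear regression for
  (log θ_pop, β) and a residual variance for ω²; σ_b² is the smoothed
  mean squared proportional residual. Parameters named in
  `fixed_parameters` are held at their template values.
* Everything is driven by one `numpy` Generator seeded from
  `FitSettings.seed`; two runs with the same seed and settings are
  bit-identical. A trace of all parameters per iteration is stored, and
  a settled-trace check over the final window sets the `converged` flag
  (a warning, not an error).

Initial values come from `initial_model_from_data` (geometric mean of
early observations for C0, late/early ratio for r, k = 1/year, ω = 0.5,
σ = 0.3), not from any known truth.

Marginal log-likelihood: per-patient importance sampling with a
multivariate-t (5 df) proposal centred at the conditional mode with the
inverse-Hessian covariance (the mode found by L-BFGS with the analytic
gradient of the complete-data log-density; the Hessian by central
differences of that gradient). The estimator reports its Monte-Carlo SE;
it agrees with adaptive 64-node Gauss–Hermite quadrature within 0.01
log-units on one-dimensional problems. BIC uses the number of patients
contributing any likelihood-eligible data as N.

Standard errors (`standard_errors`):

* `linearization` (default): expected Fisher information of the Gaussian
  marginal obtained by linearizing the model around each patient's
  conditional mode, assembled block-diagonally — mean parameters
  (log θ_pop, β) inform through the mean channel only, variance
  parameters (ω, σ) through the covariance channel only. The
  proportional-error marginal covariance also varies with the mean
  parameters, but that channel reflects the linearization rather than
  information the latent-variable likelihood actually delivers;
  including it understates SEs of covariate coefficients by a factor
  ~2 in simulation, so it is excluded (the usual block assumption).
  Reported SEs match the replicate SD of the estimator within ~30–40 %
  in simulation, and Wald tests at 0.05 hold their level approximately.
* `stochastic_fisher`: empirical Fisher information from Monte-Carlo
  conditional expectations of the complete-data score (Louis identity),
  diagonal Ω only.
* `bootstrap`: case resampling with refits; only practical for small
  problems.

SEs are mapped to the natural scale by the delta method; RSE % is
100·SE/|estimate|. Wald p-values for covariate coefficients are
two-sided normal and unadjusted for multiplicity.

A deterministic Laplace-approximation fitter (`fit_laplace`, Powell over
the marginal Laplace objective with warm-started inner modes) serves as
a cross-check for small models; SAEM is authoritative.

## Covariate model building

Step 1 screens empirical-Bayes estimates from the covariate-free model:
two-sample Wilcoxon rank-sum (exact for group sizes < 10, normal
approximation with tie correction otherwise) for binary covariates,
Spearman rank correlation over class ranks 1/2/3 for the ordered dose
classes; pairs with p < 0.2 (strict) become candidates. Rank tests make
screening invariant to monotone transformations of the EBEs. Ordered
dose-class candidates expand into the two indicator effects (low, high
vs the 90–120 reference) before model fitting.

Step 2 is forward selection: every remaining candidate is refitted in
turn, the smallest Wald p wins if below 0.05, ties broken by larger
|β|/SE then name (so the procedure is deterministic); refit failures are
recorded in the trace and the candidate skipped. Backward elimination
removes the largest p ≥ 0.05 and refits until all retained effects are
significant. The full decision trace (candidate, p, decision, BIC) is a
DataFrame that completely determines the final model.

## Individual inference and diagnostics

MAP random effects maximize the complete-data log-density at the
population estimates (L-BFGS with analytic gradient from η = 0 plus 3
seeded random restarts; the posterior is near-unimodal here). A patient
without eligible observations gets η = 0, i.e. the covariate-adjusted
population parameters. Derived per-patient quantities: half-life ln2/k,
time to 95 % ln20/k, steady states C0·r, and normalization defined by
strict comparison against the usual-value limits (ferritin < 250 µg/L,
chitotriosidase < 100 nmol/mL/h, hemoglobin > 12 g/dL, platelets
> 150,000/mm³).

IWRES is (y − f_MAP)/(σ_b f_MAP). On densely sampled self-simulated data
it is standard normal to good approximation (mean within ±0.05, SD
within [0.9, 1.1]); on sparse registry-like designs empirical-Bayes
shrinkage compresses it (SD ≈ 0.8), which is expected behaviour of this
diagnostic, not a model defect.

The VPC simulates replicates of the cohort's own design (same patients,
covariates and times; new η and ε, with the same positivity resampling
as the generator; no prediction correction — covariate heterogeneity is
carried by the design). Times are binned per biomarker into deciles of
observed on-treatment times, pre-treatment times forming their own bin,
and bins with fewer than 5 observations merged and flagged. The table
reports observed 5/50/95th percentiles next to the simulated percentile
medians with 2.5–97.5 % Monte-Carlo intervals, plus the fraction of
observations inside the per-observation 5–95 % envelope (≈90 % when the
model is correct).

## Synthetic registry generator

The generator emulates the registry cohort the published analysis used,
which is not distributable: 233 patients; covariate prevalences 50.6 %
female, 17.6 % under 15 at ERT start, 26.2 % splenectomized, 13.4 %
N370S/N370S; monitoring probabilities set so the expected monitored
counts are ≈129/142/191/191 of 233 for ferritin/chitotriosidase/
hemoglobin/platelets; follow-up a 50/50 uniform mixture on [1, 9] and
[9, 19] years (median 9, max 19); per-biomarker monitoring spans drawn
shorter than total follow-up (uniform up to 12 years) so observation
totals land near the registry's; roughly annual visits jittered by ±1.5
months plus 0–2 pre-ERT baselines within −2..0 years; 5 % of patients
interrupt treatment by more than 6 months (so windowing is exercised);
initial dose classes drawn with probabilities 0.131/0.817/0.052 and the
modal dose 120 IU/kg/month. The chitotriosidase-deficiency prevalence
(6 %) is a configuration choice — the source analysis reports exclusions
but no prevalence — and deficient patients' chitotriosidase rows carry
the undetectable flag (value stored as 0) and are excluded from all
likelihood computations. Covariates are drawn independently (marginals
only). Ground truth defaults to the final published joint model with
covariates; the covariate-free variant is available for recovery
experiments. Every draw (η per patient, implied individual parameters,
design) is recorded in a `TruthRecord`.

What the generator does not emulate: real visit-frequency patterns,
covariate correlations (e.g. splenectomy × age), dose changes tied to
clinical response, assay changes over 19 years, informative dropout.
Passing recovery and diagnostic tests on generated cohorts therefore
shows the estimation machinery is correct under the stated model, not
that the model fits any particular real registry.

## Problem sizes used in the tests

The test suite exercises the full pipeline at sizes chosen to keep a
complete run in the minutes range on one CPU: parameter recovery uses 10
replicate 200-patient cohorts at the full SAEM schedule; the shared-k
model-selection experiment uses 20 replicate 60-patient cohorts with a
shortened schedule; the covariate-procedure experiment uses 20 replicate
80-patient single-biomarker cohorts; diagnostics calibration uses a
40-patient densely sampled cohort and the 233-patient registry design.
These are the package's own choices of experiment size; the same
functions run unchanged at larger sizes.

## Known limitations

* Correlated random effects cannot be combined with covariate effects in
  estimation (diagonal Ω is the default throughout).
* The σ of a biomarker with very large proportional error (σ ≈ 0.6) is
  structurally under-recovered from generated data because of the
  positivity truncation described above.
* Analytic SEs assume diagonal Ω; bootstrap is the only SE route for
  correlation models.
* No inter-occasion variability, continuous covariates, or combined
  additive+proportional error; dose enters only through its classes.
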