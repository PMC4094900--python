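"""Deterministic time-course models for biomarker response to ERT.

Gaucher disease drives ferritin and chitotriosidase up and hemoglobin and
platelets down through macrophage substrate accumulation.  Under enzyme
replacement therapy (ERT) the substrate burden decays and each biomarker
relaxes exponentially from its pre-treatment baseline ``c0`` toward a
treatment steady state ``c0 * r``:

    C(t) = c0 * (r + (1 - r) * exp(-k * t))        for t > 0
    C(t) = c0                                      for t <= 0

``r`` is the amplitude of variation (steady state / baseline; ``r < 1`` for
biomarkers that fall under treatment, ``r > 1`` for those that rise) and
``k`` (1/year) is the rate constant of normalization, with half-life
``ln 2 / k``.  The same formula covers both directions: it is algebraically
identical to ``c0 * (1 + (r - 1) * (1 - exp(-k t)))``.

Two reference models accompany the exponential model:

* :func:`turnover_profile` — the mechanistic turnover (production/elimination)
  parent model the exponential form is the fast-elimination limit of;
* :func:`predict_emax` — the empirical hyperbolic-in-time Emax comparator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "IndividualParams",
    "EmaxParams",
    "TurnoverParams",
    "predict_profile",
    "steady_state",
    "half_life",
    "time_to_fraction",
    "predict_emax",
    "turnover_profile",
]

#: multiple of the half-life after which 95% of the response is reached,
#: ln(20)/ln(2) = 4.3219...
HALF_LIVES_TO_95 = math.log(20.0) / math.log(2.0)


@dataclass(frozen=True)
class IndividualParams:
    """Parameters of the exponential response model for one biomarker.

    c0 : baseline value in biomarker units (> 0)
    r  : amplitude of variation, steady state / baseline (> 0)
    k  : normalization rate constant, 1/year (> 0)
    """

    c0: float
    r: float
    k: float

    def __post_init__(self) -> None:
        if not (self.c0 > 0 and self.r > 0 and self.k > 0):
            raise ValueError(
                f"c0, r and k must be positive (got {self.c0}, {self.r}, {self.k})"
            )


@dataclass(frozen=True)
class EmaxParams:
    """Hyperbolic (Emax) comparator: c0 baseline, r asymptote ratio,
    t50 time to half response in years. Same parameter count as the
    exponential model so BIC comparisons are on an equal footing."""

    c0: float
    r: float
    t50: float

    def __post_init__(self) -> None:
        if not (self.c0 > 0 and self.r > 0 and self.t50 > 0):
            raise ValueError("c0, r and t50 must be positive")


@dataclass(frozen=True)
class TurnoverParams:
    """Turnover (indirect-response) parent model.

    The biomarker is produced at rate R(t) and eliminated at first-order
    rate ``lam`` (1/year); the system starts at equilibrium R(0) = lam*c0
    and the production rate tracks the substrate burden,
    R(t) = lam * c0 * (r + (1-r) * exp(-k t)), so the quasi-steady-state
    of this model is exactly the simplified exponential profile.  This
    anchoring is a reconstruction of the mechanistic scheme, chosen so the
    fast-elimination limit is exact.
    """

    c0: float
    r: float
    k: float
    lam: float

    def __post_init__(self) -> None:
        if not (self.c0 > 0 and self.r > 0 and self.k > 0 and self.lam > 0):
            raise ValueError("c0, r, k and lam must be positive")


def predict_profile(params: IndividualParams, t):
    """Biomarker value at time ``t`` (years since ERT initiation).

    Pre-treatment times (t <= 0) return the baseline ``c0``; the model has
    no pre-ERT dynamics, so baseline observations inform ``c0`` directly.
    Accepts scalars or arrays.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("t must be finite")
    tp = np.maximum(t, 0.0)
    value = params.c0 * (params.r + (1.0 - params.r) * np.exp(-params.k * tp))
    return value if value.ndim else float(value)


def steady_state(params: IndividualParams) -> float:
    """Corrected biomarker value at treatment steady state, c0 * r."""
    return params.c0 * params.r


def half_life(k: float) -> float:
    """Normalization half-life ln(2)/k in years."""
    if k <= 0:
        raise ValueError("k must be positive")
    return math.log(2.0) / k


def time_to_fraction(k: float, f: float) -> float:
    """Years until a fraction ``f`` of the total response is reached.

    -ln(1-f)/k; for f = 0.95 this is ln(20)/k, i.e. 4.32 half-lives.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if not 0.0 < f < 1.0:
        raise ValueError("f must lie in (0, 1)")
    return -math.log1p(-f) / k


def predict_emax(params: EmaxParams, t):
    """Emax comparator value at time ``t``: response builds hyperbolically,
    reaching half its span at t50 (and 90% only at 9*t50)."""
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("t must be finite")
    tp = np.maximum(t, 0.0)
    value = params.c0 * (1.0 + (params.r - 1.0) * tp / (params.t50 + tp))
    return value if value.ndim else float(value)


def turnover_profile(params: TurnoverParams, t):
    """Solution of dC/dt = R(t) - lam*C with C(0) = c0.

    Closed form (lam != k):
        C(t) = c0*r + c0*(1-r) * (lam*e^(-k t) - k*e^(-lam t)) / (lam - k)

    Converges pointwise to :func:`predict_profile` as lam/k -> infinity,
    which quantifies the fast-elimination simplification.
    """
    if params.lam == params.k:
        raise ValueError("closed form requires lam != k")
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("t must be finite")
    tp = np.maximum(t, 0.0)
    c0, r, k, lam = params.c0, params.r, params.k, params.lam
    value = c0 * r + c0 * (1.0 - r) * (
        lam * np.exp(-k * tp) - k * np.exp(-lam * tp)
    ) / (lam - k)
    return value if value.ndim else float(value)
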