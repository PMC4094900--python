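"""Registry-structured longitudinal data: reading, validation, windowing.

Data layout follows rare-disease registry practice: three long-format tables
(observations, per-patient covariates, dosing episodes) keyed by patient id.
Times are continuous years relative to ERT initiation; negative times are
pre-treatment.  Biomarker units: ferritin ug/L, chitotriosidase nmol/h.mL,
hemoglobin g/dL, platelets /mm3.

Inclusion rules implemented here:

* observations from 2 years before ERT initiation onward are analyzable;
* a treatment interruption of more than 6 months ends the analysis window
  (shorter gaps count as continuous treatment);
* chitotriosidase measurements of patients with undetectable activity
  (probable chitotriosidase-gene deficiency) are retained in the data model
  but excluded from all likelihood computations.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "BIOMARKERS",
    "DoseClass",
    "TreatmentEpisode",
    "PatientCovariates",
    "PatientRecord",
    "Cohort",
    "RegistryError",
    "classify_dose",
    "read_cohort",
    "write_cohort",
    "select_analysis_window",
    "apply_analysis_window",
    "assign_dose_classes",
    "cohort_summary",
]

BIOMARKERS = ("ferritin", "chitotriosidase", "hemoglobin", "platelets")

OBS_COLUMNS = ["patient_id", "biomarker", "time_years", "value", "undetectable"]
COV_COLUMNS = [
    "patient_id",
    "sex",
    "age_at_init",
    "splenectomized",
    "genotype_n370s_hom",
    "chito_deficient",
]
EPI_COLUMNS = ["patient_id", "start_years", "end_years", "dose_iu_kg_month"]


class RegistryError(ValueError):
    """Raised when registry tables violate the data contract."""


class DoseClass(enum.Enum):
    """ERT dose classes in IU/kg/month: <90, 90-120, >120."""

    low = "low"
    mid = "mid"
    high = "high"


def classify_dose(dose: float) -> DoseClass:
    """Class of a positive dose. The modal 120 IU/kg/month dose falls in
    the middle class (90 <= dose <= 120)."""
    if not dose > 0:
        raise ValueError(f"dose must be positive, got {dose}")
    if dose < 90.0:
        return DoseClass.low
    if dose <= 120.0:
        return DoseClass.mid
    return DoseClass.high


@dataclass(frozen=True)
class TreatmentEpisode:
    """Continuous dosing episode: [start, end) years relative to ERT
    initiation at a constant dose (IU/kg/month). ``end=None`` means the
    episode is ongoing at last follow-up."""

    start: float
    end: float | None
    dose: float

    def __post_init__(self) -> None:
        if self.end is not None and not self.end > self.start:
            raise ValueError(f"episode end {self.end} must exceed start {self.start}")
        if not self.dose > 0:
            raise ValueError("dose must be positive")

    @property
    def end_or_inf(self) -> float:
        return math.inf if self.end is None else self.end


@dataclass(frozen=True)
class PatientCovariates:
    sex: str  # "female" | "male"
    age_at_init: float  # years at ERT initiation
    splenectomized: bool  # before ERT initiation
    genotype_n370s_hom: bool  # N370S/N370S homozygote
    chito_deficient: bool  # undetectable chitotriosidase activity

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if not self.age_at_init > 0:
            raise ValueError("age_at_init must be positive")

    @property
    def under15(self) -> bool:
        return self.age_at_init < 15.0


@dataclass
class PatientRecord:
    """Covariates, dosing episodes and observations of one patient.

    ``observations`` columns: biomarker, time_years, value, undetectable,
    excluded. ``excluded`` marks rows outside the likelihood (undetectable
    or chitotriosidase rows of chito-deficient patients).
    """

    patient_id: str
    covariates: PatientCovariates
    episodes: list[TreatmentEpisode] = field(default_factory=list)
    observations: pd.DataFrame = field(
        default_factory=lambda: _empty_observations()
    )

    def __post_init__(self) -> None:
        eps = sorted(self.episodes, key=lambda e: e.start)
        for a, b in zip(eps, eps[1:]):
            if a.end_or_inf > b.start:
                raise RegistryError(
                    f"patient {self.patient_id}: overlapping episodes"
                )
        self.episodes = eps
        self.observations = _normalize_observations(
            self.observations, self.covariates.chito_deficient
        )

    def eligible_observations(self) -> pd.DataFrame:
        """Observations that enter the likelihood."""
        return self.observations[~self.observations["excluded"]]


def _empty_observations() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "biomarker": pd.Series(dtype=str),
            "time_years": pd.Series(dtype=float),
            "value": pd.Series(dtype=float),
            "undetectable": pd.Series(dtype=bool),
            "excluded": pd.Series(dtype=bool),
        }
    )


def _normalize_observations(obs: pd.DataFrame, chito_deficient: bool) -> pd.DataFrame:
    obs = obs.copy()
    if "undetectable" not in obs.columns:
        obs["undetectable"] = False
    obs["undetectable"] = obs["undetectable"].astype(bool)
    bad = ~obs["biomarker"].isin(BIOMARKERS)
    if bad.any():
        raise RegistryError(f"unknown biomarker(s): {sorted(obs.loc[bad, 'biomarker'].unique())}")
    if not np.isfinite(obs["time_years"].to_numpy(float)).all():
        raise RegistryError("non-finite observation time")
    nonpos = (~obs["undetectable"]) & ~(obs["value"] > 0)
    if nonpos.any():
        raise RegistryError("non-positive biomarker value without undetectable flag")
    is_chito = obs["biomarker"] == "chitotriosidase"
    obs["excluded"] = obs["undetectable"] | (is_chito & chito_deficient)
    return obs.sort_values(["biomarker", "time_years"], kind="stable").reset_index(drop=True)


@dataclass
class Cohort:
    """Collection of :class:`PatientRecord` with unique ids."""

    patients: dict[str, PatientRecord]

    def __post_init__(self) -> None:
        for pid, rec in self.patients.items():
            if rec.patient_id != pid:
                raise RegistryError(f"patient id mismatch: {pid} vs {rec.patient_id}")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients.values())

    def __getitem__(self, pid: str) -> PatientRecord:
        return self.patients[pid]

    def observations_frame(self) -> pd.DataFrame:
        """All observations as one long table (with patient_id)."""
        frames = []
        for rec in self:
            df = rec.observations.copy()
            df.insert(0, "patient_id", rec.patient_id)
            frames.append(df)
        if not frames:
            return _empty_observations().assign(patient_id=pd.Series(dtype=str))
        return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# reading / writing


def _require_columns(df: pd.DataFrame, required: list[str], table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise RegistryError(f"{table} table is missing column(s): {missing}")


def read_cohort(observations_table, covariates_table, episodes_table) -> Cohort:
    """Read and validate the three registry tables (CSV/TSV paths or buffers).

    Raises :class:`RegistryError` on missing columns, duplicate
    (patient, biomarker, time) rows, non-positive values without the
    undetectable flag, or observations referencing unknown patients.
    """
    obs = _read_table(observations_table)
    cov = _read_table(covariates_table)
    epi = _read_table(episodes_table)

    _require_columns(obs, [c for c in OBS_COLUMNS if c != "undetectable"], "observations")
    _require_columns(cov, COV_COLUMNS, "covariates")
    _require_columns(epi, EPI_COLUMNS, "episodes")
    if "undetectable" not in obs.columns:
        obs["undetectable"] = 0

    dup = obs.duplicated(subset=["patient_id", "biomarker", "time_years"])
    if dup.any():
        raise RegistryError(
            f"duplicate (patient, biomarker, time) rows: {int(dup.sum())}"
        )
    if cov["patient_id"].duplicated().any():
        raise RegistryError("duplicate patient_id in covariates table")

    cov = cov.set_index("patient_id")
    known = set(cov.index.astype(str))
    orphans = set(obs["patient_id"].astype(str)) - known
    if orphans:
        raise RegistryError(f"observations reference unknown patient(s): {sorted(orphans)}")
    orphan_epi = set(epi["patient_id"].astype(str)) - known
    if orphan_epi:
        raise RegistryError(f"episodes reference unknown patient(s): {sorted(orphan_epi)}")

    obs_by_pid = {str(k): g for k, g in obs.groupby(obs["patient_id"].astype(str))}
    epi_by_pid = {str(k): g for k, g in epi.groupby(epi["patient_id"].astype(str))}

    patients: dict[str, PatientRecord] = {}
    for pid, row in cov.iterrows():
        pid = str(pid)
        covariates = PatientCovariates(
            sex=str(row["sex"]),
            age_at_init=float(row["age_at_init"]),
            splenectomized=_as_bool(row["splenectomized"]),
            genotype_n370s_hom=_as_bool(row["genotype_n370s_hom"]),
            chito_deficient=_as_bool(row["chito_deficient"]),
        )
        episodes = []
        for _, e in epi_by_pid.get(pid, pd.DataFrame(columns=EPI_COLUMNS)).iterrows():
            end = e["end_years"]
            end = None if pd.isna(end) else float(end)
            episodes.append(
                TreatmentEpisode(
                    start=float(e["start_years"]), end=end, dose=float(e["dose_iu_kg_month"])
                )
            )
        o = obs_by_pid.get(pid)
        if o is None:
            o = _empty_observations()
        else:
            o = o[["biomarker", "time_years", "value", "undetectable"]].astype(
                {"time_years": float, "value": float}
            )
            o["undetectable"] = o["undetectable"].astype(float).astype(bool)
        patients[pid] = PatientRecord(
            patient_id=pid, covariates=covariates, episodes=episodes, observations=o
        )
    return Cohort(patients)


def _read_table(src) -> pd.DataFrame:
    sep = None
    if isinstance(src, str) and src.endswith(".tsv"):
        sep = "\t"
    return pd.read_csv(src, sep=sep if sep else ",")


def _as_bool(x) -> bool:
    if isinstance(x, str):
        return x.strip().lower() in ("1", "true", "yes")
    return bool(int(x))


def write_cohort(cohort: Cohort, observations_path, covariates_path, episodes_path) -> None:
    """Write the three registry tables (CSV); inverse of :func:`read_cohort`."""
    obs_rows, cov_rows, epi_rows = [], [], []
    for rec in cohort:
        c = rec.covariates
        cov_rows.append(
            {
                "patient_id": rec.patient_id,
                "sex": c.sex,
                "age_at_init": c.age_at_init,
                "splenectomized": int(c.splenectomized),
                "genotype_n370s_hom": int(c.genotype_n370s_hom),
                "chito_deficient": int(c.chito_deficient),
            }
        )
        for e in rec.episodes:
            epi_rows.append(
                {
                    "patient_id": rec.patient_id,
                    "start_years": e.start,
                    "end_years": "" if e.end is None else e.end,
                    "dose_iu_kg_month": e.dose,
                }
            )
        for _, o in rec.observations.iterrows():
            obs_rows.append(
                {
                    "patient_id": rec.patient_id,
                    "biomarker": o["biomarker"],
                    "time_years": o["time_years"],
                    "value": o["value"],
                    "undetectable": int(o["undetectable"]),
                }
            )
    pd.DataFrame(obs_rows, columns=OBS_COLUMNS).to_csv(observations_path, index=False)
    pd.DataFrame(cov_rows, columns=COV_COLUMNS).to_csv(covariates_path, index=False)
    pd.DataFrame(epi_rows, columns=EPI_COLUMNS).to_csv(episodes_path, index=False)


# ---------------------------------------------------------------------------
# analysis window and dose classes


def continuous_treatment_end(
    patient: PatientRecord, gap_threshold_months: float = 6.0
) -> float:
    """End of the continuous-treatment span: the end of the episode before
    the first inter-episode gap strictly exceeding the threshold (inf when
    treatment is never interrupted that long)."""
    threshold_years = gap_threshold_months / 12.0
    eps = patient.episodes
    for a, b in zip(eps, eps[1:]):
        if b.start - a.end_or_inf > threshold_years:
            return a.end_or_inf
    return eps[-1].end_or_inf if eps else math.inf


def select_analysis_window(
    patient: PatientRecord,
    gap_threshold_months: float = 6.0,
    pre_window_years: float = 2.0,
) -> PatientRecord:
    """Restrict observations to the analysis window.

    Drops observations earlier than ``pre_window_years`` before ERT
    initiation and observations after the start of the first treatment
    interruption longer than ``gap_threshold_months`` (strictly; a gap of
    exactly the threshold counts as continuous treatment).  Idempotent.
    """
    if not patient.episodes or patient.episodes[0].start != 0.0:
        raise RegistryError(
            f"patient {patient.patient_id}: first episode must start at time 0"
        )
    end = continuous_treatment_end(patient, gap_threshold_months)
    obs = patient.observations
    keep = (obs["time_years"] >= -pre_window_years) & (obs["time_years"] <= end)
    return replace(patient, observations=obs[keep].reset_index(drop=True))


def apply_analysis_window(cohort: Cohort, **kwargs) -> Cohort:
    """Window every patient of a cohort (see :func:`select_analysis_window`)."""
    return Cohort({pid: select_analysis_window(rec, **kwargs) for pid, rec in cohort.patients.items()})


def assign_dose_classes(
    patient: PatientRecord,
) -> tuple[DoseClass, DoseClass | None]:
    """Initial dose class and (when treated follow-up reaches 3 years) the
    class of the time-weighted mean dose over the third treatment year."""
    initial = None
    for e in patient.episodes:
        if e.start <= 0.0 < e.end_or_inf:
            initial = classify_dose(e.dose)
            break
    if initial is None:
        raise RegistryError(f"patient {patient.patient_id}: no episode covering t=0")

    if continuous_treatment_end(patient) < 3.0:
        return initial, None
    weighted = 0.0
    total = 0.0
    for e in patient.episodes:
        lo = max(e.start, 2.0)
        hi = min(e.end_or_inf, 3.0)
        if hi > lo:
            weighted += e.dose * (hi - lo)
            total += hi - lo
    if total == 0.0:
        return initial, None
    return initial, classify_dose(weighted / total)


def cohort_summary(cohort: Cohort) -> pd.DataFrame:
    """Characteristics table: counts and percentages of the covariates and
    dose classes, plus per-biomarker monitoring and observation totals."""
    if len(cohort) == 0:
        raise RegistryError("empty cohort")
    n = len(cohort)
    rows: list[dict] = []

    def frac_row(group: str, label: str, count: int, denom: int = n) -> None:
        rows.append(
            {
                "group": group,
                "category": label,
                "n": count,
                "percent": 100.0 * count / denom if denom else float("nan"),
            }
        )

    covs = [rec.covariates for rec in cohort]
    frac_row("sex", "female", sum(c.sex == "female" for c in covs))
    frac_row("sex", "male", sum(c.sex == "male" for c in covs))
    frac_row("age", "under 15 at ERT initiation", sum(c.under15 for c in covs))
    frac_row("splenectomy", "splenectomized", sum(c.splenectomized for c in covs))
    frac_row("genotype", "N370S/N370S", sum(c.genotype_n370s_hom for c in covs))
    frac_row("chitotriosidase", "deficient", sum(c.chito_deficient for c in covs))

    initial_classes, third_classes = [], []
    for rec in cohort:
        ini, third = assign_dose_classes(rec)
        initial_classes.append(ini)
        if third is not None:
            third_classes.append(third)
    for dc in DoseClass:
        frac_row("initial dose", dc.value, sum(c is dc for c in initial_classes))
    for dc in DoseClass:
        frac_row(
            "third-year dose",
            dc.value,
            sum(c is dc for c in third_classes),
            denom=len(third_classes),
        )

    for b in BIOMARKERS:
        monitored = sum(
            (rec.observations["biomarker"] == b).any() for rec in cohort
        )
        total_obs = int(
            sum((rec.observations["biomarker"] == b).sum() for rec in cohort)
        )
        rows.append(
            {"group": "monitoring", "category": b, "n": monitored, "percent": 100.0 * monitored / n}
        )
        rows.append(
            {"group": "observations", "category": b, "n": total_obs, "percent": float("nan")}
        )
    return pd.DataFrame(rows)
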