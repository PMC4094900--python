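"""Registry tables: validation, analysis window, dose classes, summaries."""

import io
import math

import numpy as np
import pandas as pd
import pytest

from gaucher_ert.registry_io import (
    Cohort,
    DoseClass,
    PatientCovariates,
    PatientRecord,
    RegistryError,
    TreatmentEpisode,
    assign_dose_classes,
    classify_dose,
    cohort_summary,
    read_cohort,
    select_analysis_window,
    write_cohort,
)
from gaucher_ert.synthetic_registry import GeneratorConfig, generate_cohort


def _tables(obs_rows, cov_rows, epi_rows):
    def buf(rows, cols):
        return io.StringIO(pd.DataFrame(rows, columns=cols).to_csv(index=False))

    return (
        buf(obs_rows, ["patient_id", "biomarker", "time_years", "value", "undetectable"]),
        buf(
            cov_rows,
            ["patient_id", "sex", "age_at_init", "splenectomized", "genotype_n370s_hom", "chito_deficient"],
        ),
        buf(epi_rows, ["patient_id", "start_years", "end_years", "dose_iu_kg_month"]),
    )


COVS = [
    ("A", "female", 30.0, 0, 0, 0),
    ("B", "male", 12.0, 1, 0, 0),
    ("C", "female", 50.0, 0, 1, 1),
]
EPIS = [("A", 0.0, 5.0, 120.0), ("B", 0.0, 4.0, 60.0), ("C", 0.0, 6.0, 130.0)]
OBS = [
    ("A", "ferritin", -0.5, 600.0, 0),
    ("A", "ferritin", 1.0, 300.0, 0),
    ("B", "platelets", 0.5, 90000.0, 0),
    ("C", "chitotriosidase", 1.0, 0.0, 1),
    ("C", "hemoglobin", 1.0, 12.5, 0),
]


class TestReadCohort:
    def test_toy_round_trip_identity(self, tmp_path):
        cohort = read_cohort(*_tables(OBS, COVS, EPIS))
        assert len(cohort) == 3
        assert len(cohort.observations_frame()) == len(OBS)
        paths = [tmp_path / f"{n}.csv" for n in ("obs", "cov", "epi")]
        write_cohort(cohort, *paths)
        again = read_cohort(*paths)
        pd.testing.assert_frame_equal(
            cohort.observations_frame(), again.observations_frame()
        )
        for pid in cohort.patients:
            assert cohort[pid].covariates == again[pid].covariates
            assert cohort[pid].episodes == again[pid].episodes

    def test_undetectable_chitotriosidase_retained_but_excluded(self):
        cohort = read_cohort(*_tables(OBS, COVS, EPIS))
        obs_c = cohort["C"].observations
        chito = obs_c[obs_c["biomarker"] == "chitotriosidase"]
        assert len(chito) == 1 and bool(chito["excluded"].iloc[0])
        # the deficiency flag propagates, but other biomarkers stay eligible
        eligible = cohort["C"].eligible_observations()
        assert set(eligible["biomarker"]) == {"hemoglobin"}

    def test_orphan_observation_rejected(self):
        bad = OBS + [("ZZ", "ferritin", 1.0, 100.0, 0)]
        with pytest.raises(RegistryError, match="unknown patient"):
            read_cohort(*_tables(bad, COVS, EPIS))

    def test_missing_column_rejected(self):
        obs_buf, cov_buf, epi_buf = _tables(OBS, COVS, EPIS)
        broken = io.StringIO(pd.read_csv(obs_buf).drop(columns="value").to_csv(index=False))
        with pytest.raises(RegistryError, match="missing column"):
            read_cohort(broken, cov_buf, epi_buf)

    def test_duplicate_row_rejected(self):
        with pytest.raises(RegistryError, match="duplicate"):
            read_cohort(*_tables(OBS + [OBS[0]], COVS, EPIS))

    def test_nonpositive_value_without_flag_rejected(self):
        bad = OBS + [("A", "hemoglobin", 2.0, 0.0, 0)]
        with pytest.raises(RegistryError, match="non-positive"):
            read_cohort(*_tables(bad, COVS, EPIS))


def _patient(times, episodes, pid="X"):
    obs = pd.DataFrame(
        {
            "biomarker": ["ferritin"] * len(times),
            "time_years": times,
            "value": [100.0] * len(times),
            "undetectable": [False] * len(times),
        }
    )
    cov = PatientCovariates("female", 30.0, False, False, False)
    return PatientRecord(patient_id=pid, covariates=cov, episodes=episodes, observations=obs)


class TestAnalysisWindow:
    def test_pre_window_cutoff(self):
        p = _patient([-2.5, -1.9, 1.0], [TreatmentEpisode(0.0, 5.0, 120.0)])
        w = select_analysis_window(p)
        assert w.observations["time_years"].tolist() == [-1.9, 1.0]

    def test_long_interruption_ends_window(self):
        # 7-month gap: window ends at 3 years, later observations dropped
        eps = [TreatmentEpisode(0.0, 3.0, 120.0), TreatmentEpisode(3.0 + 7 / 12, 6.0, 120.0)]
        p = _patient([1.0, 4.0], eps)
        w = select_analysis_window(p)
        assert w.observations["time_years"].tolist() == [1.0]

    def test_short_interruption_is_continuous(self):
        # 5-month gap: still under treatment, observation at 4 retained
        eps = [TreatmentEpisode(0.0, 3.0, 120.0), TreatmentEpisode(3.0 + 5 / 12, 6.0, 120.0)]
        p = _patient([1.0, 4.0], eps)
        w = select_analysis_window(p)
        assert w.observations["time_years"].tolist() == [1.0, 4.0]

    def test_exactly_six_months_is_continuous(self):
        eps = [TreatmentEpisode(0.0, 3.0, 120.0), TreatmentEpisode(3.5, 6.0, 120.0)]
        p = _patient([4.0], eps)
        assert len(select_analysis_window(p).observations) == 1

    def test_idempotent(self):
        eps = [TreatmentEpisode(0.0, 3.0, 120.0), TreatmentEpisode(4.0, 6.0, 120.0)]
        p = _patient([-2.5, 1.0, 5.0], eps)
        once = select_analysis_window(p)
        twice = select_analysis_window(once)
        pd.testing.assert_frame_equal(once.observations, twice.observations)

    def test_requires_episode_at_zero(self):
        p = _patient([1.0], [TreatmentEpisode(0.5, 3.0, 120.0)])
        with pytest.raises(RegistryError):
            select_analysis_window(p)

    def test_window_bounds_property(self):
        eps = [TreatmentEpisode(0.0, 2.0, 120.0), TreatmentEpisode(4.0, 8.0, 120.0)]
        p = _patient(list(np.linspace(-3, 7, 40)), eps)
        w = select_analysis_window(p)
        t = w.observations["time_years"]
        assert (t >= -2.0).all() and (t <= 2.0).all()


class TestDoseClasses:
    @pytest.mark.parametrize(
        "dose, expected",
        [(120.0, DoseClass.mid), (89.9, DoseClass.low), (90.0, DoseClass.mid), (120.1, DoseClass.high)],
    )
    def test_boundaries(self, dose, expected):
        assert classify_dose(dose) is expected

    def test_time_weighted_third_year_mean(self):
        eps = [
            TreatmentEpisode(0.0, 2.0, 80.0),
            TreatmentEpisode(2.0, 2.5, 100.0),
            TreatmentEpisode(2.5, 6.0, 140.0),
        ]
        p = _patient([1.0], eps)
        initial, third = assign_dose_classes(p)
        assert initial is DoseClass.low
        assert third is DoseClass.mid  # (100*0.5 + 140*0.5) / 1 = 120

    def test_third_year_absent_without_three_years(self):
        p = _patient([1.0], [TreatmentEpisode(0.0, 2.5, 120.0)])
        assert assign_dose_classes(p) == (DoseClass.mid, None)

    def test_no_initial_episode_is_error(self):
        p = _patient([1.0], [TreatmentEpisode(1.0, 3.0, 120.0)])
        with pytest.raises(RegistryError):
            assign_dose_classes(p)


class TestCohortSummary:
    def test_sex_fractions(self):
        covs = [
            ("A", "female", 30.0, 0, 0, 0),
            ("B", "female", 30.0, 0, 0, 0),
            ("C", "male", 30.0, 0, 0, 0),
            ("D", "male", 30.0, 0, 0, 0),
        ]
        epis = [(p, 0.0, 5.0, 120.0) for p, *_ in covs]
        obs = [("A", "ferritin", 1.0, 100.0, 0), ("B", "ferritin", 1.0, 100.0, 0), ("C", "ferritin", 1.0, 100.0, 0)]
        cohort = read_cohort(*_tables(obs, covs, epis))
        s = cohort_summary(cohort)
        female = s[(s["group"] == "sex") & (s["category"] == "female")].iloc[0]
        assert female["percent"] == pytest.approx(50.0)
        monitored = s[(s["group"] == "monitoring") & (s["category"] == "ferritin")].iloc[0]
        assert monitored["n"] == 3

    def test_empty_cohort_rejected(self):
        with pytest.raises(RegistryError):
            cohort_summary(Cohort({}))

    def test_synthetic_default_female_fraction(self):
        # registry prevalence: 50.6% female (stochastic tolerance)
        fracs = []
        for s in range(8):
            cohort, _ = generate_cohort(GeneratorConfig(), seed=1000 + s)
            summary = cohort_summary(cohort)
            row = summary[(summary["group"] == "sex") & (summary["category"] == "female")]
            fracs.append(float(row["percent"].iloc[0]))
        assert abs(np.mean(fracs) - 50.6) < 3.0
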