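"""Shared fixtures: hand-made tiny cohorts and one reusable simulated cohort."""

import numpy as np
import pandas as pd
import pytest

from radcohort.cohort_data import Cohort
from radcohort.err_engine import RiskSet
from radcohort.synthetic_cohort import (
    BaselineHazard,
    SimulationConfig,
    simulate_cohort,
)


@pytest.fixture
def toy_risk_sets():
    """Two-risk-set toy with a closed-form maximum at (sqrt(2)-1)/10."""
    return [
        RiskSet(10.0, ("s",), "a", np.arange(3),
                np.array([10.0, 0.0, 0.0])),
        RiskSet(12.0, ("s",), "b", np.arange(2),
                np.array([0.0, 10.0])),
    ]


@pytest.fixture
def tiny_cohort():
    """Three persons, four exams, one outcome; dates chosen by hand."""
    persons = pd.DataFrame({
        "person_id": ["p1", "p2", "p3"],
        "sex": ["male", "female", "male"],
        "country": ["UK", "UK", "SE"],
        "birth_date": [1990.0, 1992.0, 1991.0],
        "registry_start": [1971.0, 1971.0, 1958.0],
        "death_date": [np.nan, np.nan, np.nan],
        "emigration_date": [np.nan, np.nan, np.nan],
        "admin_end_date": [2016.0, 2016.0, 2016.0],
        "ses": [np.nan, np.nan, np.nan],
        "transplant": [0, 0, 0],
        "low_reporting_hospital": [0, 0, 0],
        "vital_status_known": [1, 1, 1],
    })
    exams = pd.DataFrame({
        "exam_id": ["e1", "e2", "e3", "e4"],
        "person_id": ["p1", "p1", "p2", "p3"],
        "age_at_exam": [6.0, 9.0, 5.0, 7.0],
        "calendar_year": [1996, 1999, 1997, 1998],
        "body_region": ["head_neck", "chest", "head_neck", "head_neck"],
        "hospital_id": ["UK-H1", "UK-H1", "UK-H2", "SE-H1"],
    })
    outcomes = pd.DataFrame({
        "person_id": ["p1"],
        "age_at_diagnosis": [14.0],
        "morphology_code": ["9650"],
        "behavior_code": [3],
    })
    dose_summary = pd.DataFrame({
        "exam_id": ["e1", "e2", "e3", "e4"],
        "abm_dose_mean": [10.0, 5.0, 8.0, 6.0],
        "abm_dose_median": [9.0, 4.5, 7.5, 5.5],
    })
    return Cohort(persons, exams, outcomes, dose_summary=dose_summary)


@pytest.fixture(scope="session")
def small_sim():
    """One moderate simulated cohort shared across engine tests.

    The baseline hazard is inflated so that a few-thousand-person cohort
    yields a usable number of cases.
    """
    cfg = SimulationConfig(n_persons=25_000, seed=42, n_realizations=1,
                           baseline_hazard=BaselineHazard().scaled(25),
                           true_beta=0.02)
    return simulate_cohort(cfg)
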