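"""Shared fixtures: small seeded cohorts and fitted schemas."""

import numpy as np
import pandas as pd
import pytest

from ohca_counterfactual import (
    EncodingOptions,
    GroundTruthConfig,
    fit_schema,
    generate_cohort,
)
from ohca_counterfactual.synthetic import RECORD_COLUMNS


def make_record(**overrides) -> dict:
    """A complete, valid record; fields overridable per test."""
    base = {
        "prefecture": 1,
        "age": 70,
        "sex": "male",
        "onset_year": 2018,
        "onset_month": 6,
        "witnessed": "no",
        "witness_type": "none",
        "bystander_cpr": "no",
        "bystander_ventilation": "no",
        "bystander_defib": "no",
        "ems_witnessed": "no",
        "initial_rhythm": "asystole",
        "etiology": "cardiogenic",
        "airway_device": "yes",
        "time_call_to_contact": 9.0,
        "time_contact_to_hospital": 23.0,
        "time_contact_to_defib": np.nan,
        "n_defib": 0,
        "time_contact_to_drug": np.nan,
        "n_drug_doses": 0,
        "rosc": "no",
        "cpc12": 0,
    }
    base.update(overrides)
    return base


def table_of(*records) -> pd.DataFrame:
    return pd.DataFrame(list(records), columns=RECORD_COLUMNS)


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """Seeded 6,000-record cohort with informative effects (no missingness,
    so the generative oracle applies to every record)."""
    cfg = GroundTruthConfig(n_records=6_000, seed=11, missingness_rates={})
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort_config() -> GroundTruthConfig:
    cfg = GroundTruthConfig(n_records=6_000, seed=11, missingness_rates={})
    generate_cohort(cfg)  # resolves the intercept
    return cfg


@pytest.fixture(scope="session")
def small_schema(small_cohort):
    return fit_schema(small_cohort, EncodingOptions())
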