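"""Shared fixtures: toy record builders and a small simulated population."""

from __future__ import annotations

from datetime import date, timedelta

import pytest

from upcode_screen import (
    CohortConfig,
    HDCRecord,
    SimConfig,
    WeightTable,
    build_hospitals,
    build_patients,
    extract_cohort,
    simulate,
)
from upcode_screen.synthetic_data import default_cohort_config


def make_record(
    event_id="E1",
    patient_id="P1",
    hospital_id="H1",
    admission=date(2014, 3, 1),
    los=5,
    age=70,
    diagnosis=("4280",),
    procedures=(),
    drg="D1",
    cost=1000.0,
    ownership="public",
) -> HDCRecord:
    return HDCRecord(
        event_id=event_id,
        patient_id=patient_id,
        hospital_id=hospital_id,
        admission_date=admission,
        discharge_date=admission + timedelta(days=los),
        age=age,
        diagnosis_codes=tuple(diagnosis),
        procedure_codes=tuple(procedures),
        drg_code=drg,
        cost=cost,
        ownership=ownership,
    )


@pytest.fixture(scope="session")
def weights() -> WeightTable:
    return WeightTable.load_default()


@pytest.fixture(scope="session")
def toy_config() -> CohortConfig:
    return CohortConfig(
        disease_codes=frozenset({"428"}),
        drg_family=frozenset({"D1", "D2", "D3", "D1C", "D2C", "D3C"}),
        cc_drg_codes=frozenset({"D1C", "D2C", "D3C"}),
        window_start=date(2013, 1, 1),
        window_end=date(2015, 12, 31),
    )


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated population with planted deviants, fully aggregated."""
    config = SimConfig(
        n_hospitals=40,
        n_groups=4,
        n_drg_pairs=8,
        n_planted_upcoders=2,
        n_planted_complex=1,
        hf_episodes_range=(50.0, 70.0),
        seed=7,
    )
    records, truth = simulate(config)
    cohort = extract_cohort(records, default_cohort_config(config))
    w = WeightTable.load_default()
    patients = build_patients(cohort, w)
    profiles, fm = build_hospitals(cohort, patients, w)
    return {
        "config": config,
        "records": records,
        "truth": truth,
        "cohort": cohort,
        "patients": patients,
        "profiles": profiles,
        "matrix": fm,
    }
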