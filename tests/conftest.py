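import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests/oracles.py

from icuward.records import (  # noqa: E402
    ChannelSeries,
    ClinicalEvent,
    PatientRecord,
    UrineOutput,
    empty_observations,
)


def make_record(patient_id="P0", age=60.0, sex="F", discharge=72.0,
                death=None, **channels):
    """Bare record with the given channel series, e.g.
    make_record(creatinine=([0, 24], [1.0, 1.35]))."""
    obs = empty_observations()
    for name, (times, values) in channels.items():
        times = np.asarray(times, dtype=float)
        obs[name] = ChannelSeries(times, np.asarray(values, dtype=float),
                                  np.zeros(len(times), dtype=bool))
    return PatientRecord(patient_id=patient_id, age=age, sex=sex,
                         discharge_time=discharge, observations=obs,
                         death_time=death)


def add_events(record, *events):
    """events: (kind, time) or (kind, time, detail) tuples."""
    for ev in events:
        record.clinical_events.append(ClinicalEvent(*ev))
    return record


def set_urine(record, end_times, rates, weight=70.0):
    end_times = np.asarray(end_times, dtype=float)
    rates = np.asarray(rates, dtype=float)
    record.urine = UrineOutput(end_times, rates * weight, rates)
    return record


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-patient missingness-free cohort shared across tests."""
    from icuward.synthetic import GeneratorConfig, generate_cohort
    config = GeneratorConfig(n_patients=300, missing_rate={}, seed=42)
    return generate_cohort(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
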