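import datetime as dt

import numpy as np
import pandas as pd
import pytest

import trajmine as tm


def make_registry(patients, events):
    """Build a registry from (id, sex, birth, death) and (id, code, date) rows."""
    pat_records = [
        tm.PatientRecord(pid, sex, birth, death) for pid, sex, birth, death in patients
    ]
    evt_records = [
        tm.DiagnosisEvent(pid, code, date, "inpatient") for pid, code, date in events
    ]
    return tm.registry_from_records(pat_records, evt_records)


def random_registry(rng, n_patients=200, codes=("A00", "B00", "C00", "D20"),
                    events_per_patient=3.0, start=dt.date(2000, 1, 1), span_days=6000):
    """Small random registry for oracle-equivalence tests."""
    rows = []
    counts = rng.poisson(events_per_patient, size=n_patients)
    for i in range(n_patients):
        for _ in range(counts[i]):
            code = codes[rng.integers(len(codes))]
            day = int(rng.integers(span_days))
            rows.append((f"P{i:04d}", start + dt.timedelta(days=day), code))
    patients = pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(n_patients)],
            "sex": ["male" if rng.random() < 0.5 else "female" for _ in range(n_patients)],
            "birth_date": [start - dt.timedelta(days=int(rng.integers(5000, 30000)))
                           for _ in range(n_patients)],
            "death_date": pd.NaT,
        }
    )
    events = pd.DataFrame(rows, columns=["patient_id", "date", "code"])
    events["discharge_type"] = "inpatient"
    return tm.Registry(patients, events)


def mk_pair(d1, d2, rr=5.0):
    """PairStatistics stub for trajectory/network construction tests."""
    return tm.PairStatistics(
        d1=d1,
        d2=d2,
        n_exposed=100,
        c_exposed=20,
        control_counts=np.array([4, 4, 4, 4]),
        rr=rr,
        p_cooccurrence=1e-12,
        n_d1_first=30,
        n_d2_first=2,
        p_direction=1e-7,
    )


@pytest.fixture(scope="session")
def default_config():
    return tm.SimulationConfig()


@pytest.fixture(scope="session")
def planted_registry(default_config):
    """Default 20k-patient registry with the five planted progression rules."""
    return tm.simulate_registry(default_config, seed=0)


@pytest.fixture(scope="session")
def planted_mining(planted_registry):
    return tm.mine_directional_pairs(
        planted_registry, tm.ThresholdConfig(n_controls=100), seed=0
    )


@pytest.fixture
def tiny_registry():
    """Eight hand-built patients with known first-occurrence structure."""
    d = dt.date
    patients = [
        ("p1", "male", d(1950, 1, 1), d(2006, 6, 1)),
        ("p2", "female", d(1940, 3, 2), None),
        ("p3", "male", d(1960, 7, 9), None),
        ("p4", "female", d(1955, 11, 30), d(2010, 2, 2)),
        ("p5", "male", d(1948, 5, 5), None),
        ("p6", "female", d(1970, 9, 9), None),
        ("p7", "male", d(1935, 1, 15), d(2001, 1, 1)),
        ("p8", "female", d(1965, 4, 4), None),
    ]
    events = [
        ("p1", "I10", d(2000, 1, 10)),
        ("p1", "I50", d(2003, 2, 20)),
        ("p2", "I10", d(2001, 5, 1)),
        ("p2", "I50", d(2002, 5, 1)),
        ("p2", "N18", d(2004, 8, 1)),
        ("p3", "I50", d(2001, 1, 1)),
        ("p3", "I10", d(2003, 1, 1)),
        ("p4", "I10", d(2000, 9, 9)),
        ("p5", "I10", d(1999, 12, 31)),
        ("p5", "I50", d(2000, 1, 31)),
        ("p5", "N18", d(2000, 3, 31)),
        ("p6", "Z00", d(2005, 6, 6)),
        ("p7", "Q90", d(2000, 10, 10)),
        ("p8", "I10", d(2002, 2, 2)),
        ("p8", "I50", d(2002, 2, 2)),  # same-day pair: no direction
    ]
    return make_registry(patients, events)
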