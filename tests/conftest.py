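import datetime as dt

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from daysgained import (
    ImagingObservation,
    Modality,
    PatientRecord,
    Sex,
    write_cohort,
)

START = dt.date(2015, 6, 1)


def day(offset: int) -> dt.date:
    """Calendar date at an integer day offset from the treatment start."""
    return START + dt.timedelta(days=offset)


def make_patient(pid="P1", cytotoxic_dates=(), **kwargs) -> PatientRecord:
    defaults = dict(
        patient_id=pid,
        treatment_start=START,
        age_at_start=55.0,
        sex=Sex.M,
        cytotoxic_dates=tuple(cytotoxic_dates),
        os_time_days=300.0,
        os_event=True,
        pfs_time_days=150.0,
        pfs_event=True,
    )
    defaults.update(kwargs)
    return PatientRecord(**defaults)


def make_observations(pid, modality, day_volume_pairs):
    return [
        ImagingObservation(pid, day(d), modality, float(v))
        for d, v in day_volume_pairs
    ]


@pytest.fixture
def single_patient_cohort():
    """One patient, 3 scans x 2 modalities, growing tumor."""
    observations = []
    for modality, volumes in [
        (Modality.T1GD, [9000.0, 12000.0, 13000.0]),
        (Modality.FLAIR, [20000.0, 26000.0, 27000.0]),
    ]:
        observations += make_observations(
            "P1", modality, list(zip([-100, -30, 45], volumes))
        )
    return observations, [make_patient("P1")]


@pytest.fixture
def cohort_files(tmp_path, single_patient_cohort):
    observations, patients = single_patient_cohort
    long_path = tmp_path / "longitudinal.csv"
    pat_path = tmp_path / "patients.csv"
    write_cohort(observations, patients, long_path, pat_path)
    return long_path, pat_path
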