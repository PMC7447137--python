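"""Cohort data model: longitudinal imaging and patient tables.

One imaging row carries a segmented tumor-abnormality volume (necrosis
included) for a (patient, scan date, MRI sequence) triple.  The patient
table carries the start of the anti-angiogenic (bevacizumab) therapy,
demographics, concurrent-cytotoxic dosing dates and OS/PFS outcomes.

Eligibility for Days Gained scoring requires two pre-treatment scans and
one post-treatment scan per modality; treatment groups (bevacizumab alone
vs. bevacizumab plus a concurrent cytotoxic agent) are assigned from
whether a cytotoxic dose falls inside the DG evaluation window
(second pre-treatment scan date, first post-treatment scan date].
"""

from __future__ import annotations

import datetime as dt
import enum
import warnings
from dataclasses import dataclass, field

import pandas as pd

LONGITUDINAL_COLUMNS = ["patient_id", "scan_date", "modality", "volume_mm3"]
PATIENT_COLUMNS = [
    "patient_id",
    "treatment_start",
    "age_at_start",
    "sex",
    "cytotoxic_dates",
    "os_time_days",
    "os_event",
    "pfs_time_days",
    "pfs_event",
]


class Modality(str, enum.Enum):
    T1GD = "T1Gd"
    FLAIR = "FLAIR"

    @classmethod
    def parse(cls, value: str) -> "Modality":
        v = str(value).strip().lower()
        if v == "t1gd":
            return cls.T1GD
        if v == "flair":
            return cls.FLAIR
        raise ValueError(f"unknown modality {value!r} (expected T1Gd or FLAIR)")


class Sex(str, enum.Enum):
    M = "M"
    F = "F"


class IneligibilityReason(str, enum.Enum):
    OK = "ok"
    MISSING_PRETREATMENT_SCAN = "missing_pretreatment_scan"
    MISSING_POSTTREATMENT_SCAN = "missing_posttreatment_scan"


class TreatmentGroupLabel(str, enum.Enum):
    BEV_ALONE = "BevAlone"
    BEV_CYTO = "BevCyto"


class CohortValidationError(ValueError):
    """Raised when a cohort table violates the format contract.

    ``problems`` lists one human-readable message per offending row or
    column so a caller can report every defect at once.
    """

    def __init__(self, message: str, problems: list[str] | None = None):
        self.problems = problems or []
        detail = "" if not self.problems else "\n  - " + "\n  - ".join(self.problems)
        super().__init__(message + detail)


class DegenerateIntervalError(ValueError):
    """Two scans with identical dates where a time interval is required."""


@dataclass(frozen=True, order=True)
class ImagingObservation:
    patient_id: str
    scan_date: dt.date
    modality: Modality
    volume_mm3: float

    def __post_init__(self):
        if self.volume_mm3 < 0:
            raise ValueError(
                f"negative volume {self.volume_mm3} for patient {self.patient_id}"
            )


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    treatment_start: dt.date
    age_at_start: float
    sex: Sex
    cytotoxic_dates: tuple[dt.date, ...]
    os_time_days: float
    os_event: bool
    pfs_time_days: float
    pfs_event: bool

    def __post_init__(self):
        if self.age_at_start <= 0:
            raise ValueError(f"age_at_start must be > 0 for {self.patient_id}")
        if self.os_time_days < 0 or self.pfs_time_days < 0:
            raise ValueError(f"negative survival time for {self.patient_id}")


@dataclass(frozen=True)
class EligibilityStatus:
    patient_id: str
    modality: Modality
    eligible: bool
    reason: IneligibilityReason

    def __post_init__(self):
        if self.eligible != (self.reason is IneligibilityReason.OK):
            raise ValueError("eligible must be True iff reason is 'ok'")


@dataclass(frozen=True)
class TreatmentGroup:
    patient_id: str
    group: TreatmentGroupLabel


def _parse_date(value, problems: list[str], where: str) -> dt.date | None:
    try:
        return dt.date.fromisoformat(str(value).strip())
    except (ValueError, TypeError):
        problems.append(f"{where}: unparseable date {value!r}")
        return None


def _read_table(path, delimiter: str | None) -> pd.DataFrame:
    if delimiter is not None:
        return pd.read_csv(path, sep=delimiter, dtype=str)
    # comma by default, tab accepted: sniff via the python engine
    return pd.read_csv(path, sep=None, engine="python", dtype=str)


def load_longitudinal(path, delimiter: str | None = None) -> list[ImagingObservation]:
    """Read the longitudinal imaging table.

    Rows failing validation (bad date, bad modality, negative volume) are
    collected and reported in a single :class:`CohortValidationError`,
    never silently dropped.  Duplicate (patient, date, modality) rows are
    a hard error.
    """
    df = _read_table(path, delimiter)
    missing = [c for c in LONGITUDINAL_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(
            f"longitudinal table {path} is missing required column(s): "
            + ", ".join(missing)
        )
    if df.empty:
        warnings.warn(f"longitudinal table {path} has a header but no rows")
        return []

    problems: list[str] = []
    observations: list[ImagingObservation] = []
    for idx, row in df.iterrows():
        where = f"row {idx + 2}"  # 1-based, counting the header line
        date = _parse_date(row["scan_date"], problems, where)
        try:
            modality = Modality.parse(row["modality"])
        except ValueError as exc:
            problems.append(f"{where}: {exc}")
            modality = None
        try:
            volume = float(row["volume_mm3"])
        except (TypeError, ValueError):
            problems.append(f"{where}: unparseable volume {row['volume_mm3']!r}")
            volume = None
        if volume is not None and volume < 0:
            problems.append(f"{where}: negative volume {volume}")
            volume = None
        if date is not None and modality is not None and volume is not None:
            observations.append(
                ImagingObservation(str(row["patient_id"]), date, modality, volume)
            )
    if problems:
        raise CohortValidationError(
            f"longitudinal table {path} failed validation", problems
        )

    seen: set[tuple[str, dt.date, Modality]] = set()
    dups = []
    for obs in observations:
        key = (obs.patient_id, obs.scan_date, obs.modality)
        if key in seen:
            dups.append(f"duplicate row for {key}")
        seen.add(key)
    if dups:
        raise CohortValidationError(
            f"longitudinal table {path} contains duplicate rows", dups
        )
    return observations


def _parse_cytotoxic_dates(value, problems, where) -> tuple[dt.date, ...] | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ()
    text = str(value).strip()
    if not text:
        return ()
    dates = []
    for part in text.split(";"):
        d = _parse_date(part, problems, where)
        if d is None:
            return None
        dates.append(d)
    return tuple(sorted(dates))


def load_patients(path, delimiter: str | None = None) -> list[PatientRecord]:
    """Read the patient table (one row per patient)."""
    df = _read_table(path, delimiter)
    missing = [c for c in PATIENT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(
            f"patient table {path} is missing required column(s): " + ", ".join(missing)
        )
    problems: list[str] = []
    patients: list[PatientRecord] = []
    seen_ids: set[str] = set()
    for idx, row in df.iterrows():
        where = f"row {idx + 2}"
        pid = str(row["patient_id"])
        if pid in seen_ids:
            problems.append(f"{where}: duplicate patient_id {pid}")
            continue
        seen_ids.add(pid)
        start = _parse_date(row["treatment_start"], problems, where)
        cyto = _parse_cytotoxic_dates(row["cytotoxic_dates"], problems, where)
        try:
            sex = Sex(str(row["sex"]).strip().upper())
        except ValueError:
            problems.append(f"{where}: unknown sex {row['sex']!r}")
            sex = None
        fields = {}
        for col, cast in [
            ("age_at_start", float),
            ("os_time_days", float),
            ("pfs_time_days", float),
            ("os_event", lambda v: bool(int(v))),
            ("pfs_event", lambda v: bool(int(v))),
        ]:
            try:
                fields[col] = cast(row[col])
            except (TypeError, ValueError):
                problems.append(f"{where}: unparseable {col} {row[col]!r}")
                fields[col] = None
        if start is None or cyto is None or sex is None or None in fields.values():
            continue
        try:
            patients.append(
                PatientRecord(
                    patient_id=pid,
                    treatment_start=start,
                    age_at_start=fields["age_at_start"],
                    sex=sex,
                    cytotoxic_dates=cyto,
                    os_time_days=fields["os_time_days"],
                    os_event=fields["os_event"],
                    pfs_time_days=fields["pfs_time_days"],
                    pfs_event=fields["pfs_event"],
                )
            )
        except ValueError as exc:
            problems.append(f"{where}: {exc}")
    if problems:
        raise CohortValidationError(f"patient table {path} failed validation", problems)
    return patients


def load_cohort(
    longitudinal_path, patient_path, delimiter: str | None = None
) -> tuple[list[ImagingObservation], list[PatientRecord]]:
    """Load and validate the two cohort tables together."""
    observations = load_longitudinal(longitudinal_path, delimiter)
    patients = load_patients(patient_path, delimiter)
    return observations, patients


def write_cohort(
    observations: list[ImagingObservation],
    patients: list[PatientRecord],
    longitudinal_path,
    patient_path,
) -> None:
    """Write cohort tables in the exact format :func:`load_cohort` reads."""
    obs_df = pd.DataFrame(
        [
            {
                "patient_id": o.patient_id,
                "scan_date": o.scan_date.isoformat(),
                "modality": o.modality.value,
                "volume_mm3": repr(o.volume_mm3),
            }
            for o in observations
        ],
        columns=LONGITUDINAL_COLUMNS,
    )
    obs_df.to_csv(longitudinal_path, index=False)
    pat_df = pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "treatment_start": p.treatment_start.isoformat(),
                "age_at_start": repr(p.age_at_start),
                "sex": p.sex.value,
                "cytotoxic_dates": ";".join(d.isoformat() for d in p.cytotoxic_dates),
                "os_time_days": repr(p.os_time_days),
                "os_event": int(p.os_event),
                "pfs_time_days": repr(p.pfs_time_days),
                "pfs_event": int(p.pfs_event),
            }
            for p in patients
        ],
        columns=PATIENT_COLUMNS,
    )
    pat_df.to_csv(patient_path, index=False)


def select_dg_scans(
    observations: list[ImagingObservation], treatment_start: dt.date
) -> tuple[ImagingObservation, ImagingObservation, ImagingObservation] | EligibilityStatus:
    """Pick the DG scan triple for one patient and modality.

    Pre-treatment scans are the two latest scans strictly before
    ``treatment_start``; the post-treatment scan is the earliest scan on
    or after it (a scan on the start date itself counts as post).
    Returns an :class:`EligibilityStatus` when the triple cannot be
    formed.  Invariant to the input ordering of ``observations``.
    """
    if not observations:
        raise ValueError("select_dg_scans requires at least one observation")
    pid = observations[0].patient_id
    modality = observations[0].modality
    if any(o.patient_id != pid or o.modality != modality for o in observations):
        raise ValueError("observations must share one patient and one modality")

    ordered = sorted(observations, key=lambda o: o.scan_date)
    pres = [o for o in ordered if o.scan_date < treatment_start]
    posts = [o for o in ordered if o.scan_date >= treatment_start]
    if len(pres) < 2:
        return EligibilityStatus(
            pid, modality, False, IneligibilityReason.MISSING_PRETREATMENT_SCAN
        )
    if not posts:
        return EligibilityStatus(
            pid, modality, False, IneligibilityReason.MISSING_POSTTREATMENT_SCAN
        )
    pre1, pre2 = pres[-2], pres[-1]
    if pre1.scan_date == pre2.scan_date:
        raise DegenerateIntervalError(
            f"patient {pid}: two pre-treatment scans on {pre1.scan_date}; "
            "growth velocity is undefined"
        )
    return pre1, pre2, posts[0]


def assign_treatment_group(
    patient: PatientRecord, pre2_date: dt.date, post1_date: dt.date
) -> TreatmentGroup:
    """BevCyto iff a cytotoxic dose falls in the half-open window
    (pre2_date, post1_date]; otherwise BevAlone."""
    if not pre2_date < post1_date:
        raise ValueError("pre2_date must precede post1_date")
    in_window = any(pre2_date < d <= post1_date for d in patient.cytotoxic_dates)
    label = TreatmentGroupLabel.BEV_CYTO if in_window else TreatmentGroupLabel.BEV_ALONE
    return TreatmentGroup(patient.patient_id, label)


def group_observations(
    observations: list[ImagingObservation], modality: Modality
) -> dict[str, list[ImagingObservation]]:
    """Index observations of one modality by patient id."""
    by_patient: dict[str, list[ImagingObservation]] = {}
    for obs in observations:
        if obs.modality is modality:
            by_patient.setdefault(obs.patient_id, []).append(obs)
    return by_patient
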