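"""Days Gained (DG) scoring from an untreated-virtual-control growth line.

The tumor abnormality is summarized by its spherically equivalent radius
r = (3V / 4*pi)^(1/3).  Two pre-treatment scans define a patient-specific
radial growth velocity v; extrapolating that line past the second
pre-treatment scan gives the untreated virtual control (UVC), the size
the tumor was expected to reach absent therapy.  DG compares the
observed post-treatment radius with the UVC and expresses the deficit in
days of growth:

    DG = (t_post - t_pre2) - (r_post - r_pre2) / v
       = (r_uvc(t_post) - r_post) / v

DG = 0 means the tumor grew exactly as predicted; DG equal to the full
inter-scan interval means no net radial growth; DG < 0 means the tumor
outgrew its own prediction.  DG requires v > 0 — cases with non-positive
pre-treatment velocity are excluded, not scored.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import pandas as pd

from .cohort import (
    DegenerateIntervalError,
    EligibilityStatus,
    ImagingObservation,
    IneligibilityReason,
    Modality,
    PatientRecord,
    group_observations,
    select_dg_scans,
)

#: velocities at or below this (mm/day) are treated as non-positive;
#: DG divides by v, so exact zeros must be excluded too
VELOCITY_TOLERANCE = 1e-12

RESULT_COLUMNS = [
    "patient_id",
    "modality",
    "status",
    "velocity_mm_per_day",
    "interval_days",
    "dg_days",
    "deep_response",
]


class NonPositiveVelocityError(ValueError):
    """Pre-treatment growth velocity <= 0: DG is undefined."""


class RadialMeasurement(NamedTuple):
    """A spherically-equivalent radius (mm) at a time offset (days)."""

    time: float
    radius: float


@dataclass(frozen=True)
class GrowthKinetics:
    """Linear pre-treatment growth: velocity plus the anchoring scan."""

    velocity: float  # mm/day, signed
    r_pre2: float  # mm
    t_pre2: float  # days

    def __post_init__(self):
        if not math.isfinite(self.velocity):
            raise ValueError("velocity must be finite")


class DGStatus(str, enum.Enum):
    SCORED = "scored"
    EXCLUDED_NONPOSITIVE_VELOCITY = "excluded_nonpositive_velocity"
    INELIGIBLE = "ineligible"


@dataclass(frozen=True)
class DGResult:
    patient_id: str
    modality: Modality
    status: DGStatus
    dg_days: float | None = None
    velocity_mm_per_day: float | None = None
    interval_days: float | None = None
    r_predicted_mm: float | None = None
    ineligibility_reason: IneligibilityReason | None = None
    #: post-treatment radius fell below the *first* pre-treatment radius;
    #: the uncapped linear formula is still applied, this only flags the
    #: extreme response in output
    deep_response: bool = False

    def __post_init__(self):
        if (self.dg_days is not None) != (self.status is DGStatus.SCORED):
            raise ValueError("dg_days present iff status is 'scored'")


def volume_to_radius(volume: float, units: str = "mm3") -> float:
    """Spherically equivalent radius (mm) of a tumor volume.

    Parameters
    ----------
    volume : segmented tumor-abnormality volume, necrosis included.
    units : ``"mm3"`` (default) or ``"cm3"`` (converted as 1 cm^3 = 1000 mm^3).
    """
    if units == "cm3":
        volume = volume * 1000.0
    elif units != "mm3":
        raise ValueError(f"unknown volume units {units!r}")
    if volume < 0:
        raise ValueError(f"volume must be non-negative, got {volume}")
    return (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)


def radius_to_volume(radius: float) -> float:
    """Inverse of :func:`volume_to_radius` (sphere volume, mm^3)."""
    if radius < 0:
        raise ValueError("radius must be non-negative")
    return 4.0 / 3.0 * math.pi * radius**3


def estimate_velocity(pre1: RadialMeasurement, pre2: RadialMeasurement) -> float:
    """Radial growth velocity (mm/day) from the two pre-treatment scans.

    May be negative or zero; the exclusion decision is made downstream.
    """
    if pre2.time == pre1.time:
        raise DegenerateIntervalError("pre-treatment scans share a time point")
    if pre2.time < pre1.time:
        raise ValueError("pre2 must be later than pre1")
    return (pre2.radius - pre1.radius) / (pre2.time - pre1.time)


def growth_kinetics(pre1: RadialMeasurement, pre2: RadialMeasurement) -> GrowthKinetics:
    return GrowthKinetics(estimate_velocity(pre1, pre2), pre2.radius, pre2.time)


def predict_uvc_radius(kinetics: GrowthKinetics, t: float) -> float:
    """Untreated-virtual-control radius at time ``t`` (days).

    Linear extrapolation anchored at the second pre-treatment scan; only
    defined forward in time from that anchor.
    """
    if t < kinetics.t_pre2:
        raise ValueError("UVC prediction is only defined at or after t_pre2")
    return kinetics.r_pre2 + kinetics.velocity * (t - kinetics.t_pre2)


def compute_days_gained(kinetics: GrowthKinetics, post: RadialMeasurement) -> float:
    """DG score (days, signed, uncapped) for one post-treatment scan."""
    if post.time <= kinetics.t_pre2:
        raise ValueError("post-treatment scan must follow the second pre-treatment scan")
    if kinetics.velocity <= VELOCITY_TOLERANCE:
        raise NonPositiveVelocityError(
            f"DG requires positive growth velocity, got {kinetics.velocity}"
        )
    interval = post.time - kinetics.t_pre2
    return interval - (post.radius - kinetics.r_pre2) / kinetics.velocity


def score_patient(
    observations: list[ImagingObservation],
    patient: PatientRecord,
    volume_units: str = "mm3",
) -> DGResult:
    """Score one patient on one modality (all observations share both)."""
    selected = select_dg_scans(observations, patient.treatment_start)
    modality = observations[0].modality
    if isinstance(selected, EligibilityStatus):
        return DGResult(
            patient_id=patient.patient_id,
            modality=modality,
            status=DGStatus.INELIGIBLE,
            ineligibility_reason=selected.reason,
        )
    pre1_obs, pre2_obs, post_obs = selected

    def as_radial(obs: ImagingObservation) -> RadialMeasurement:
        t = (obs.scan_date - patient.treatment_start).days
        return RadialMeasurement(float(t), volume_to_radius(obs.volume_mm3, volume_units))

    pre1, pre2, post = as_radial(pre1_obs), as_radial(pre2_obs), as_radial(post_obs)
    kinetics = growth_kinetics(pre1, pre2)
    interval = post.time - pre2.time
    if kinetics.velocity <= VELOCITY_TOLERANCE:
        return DGResult(
            patient_id=patient.patient_id,
            modality=modality,
            status=DGStatus.EXCLUDED_NONPOSITIVE_VELOCITY,
            velocity_mm_per_day=kinetics.velocity,
            interval_days=interval,
        )
    dg = compute_days_gained(kinetics, post)
    return DGResult(
        patient_id=patient.patient_id,
        modality=modality,
        status=DGStatus.SCORED,
        dg_days=dg,
        velocity_mm_per_day=kinetics.velocity,
        interval_days=interval,
        r_predicted_mm=predict_uvc_radius(kinetics, post.time),
        deep_response=post.radius < pre1.radius,
    )


def score_cohort(
    observations: list[ImagingObservation],
    patients: Iterable[PatientRecord],
    modality: Modality,
    volume_units: str = "mm3",
) -> list[DGResult]:
    """One DGResult per patient for the requested modality.

    Every patient in the table receives exactly one result: scored,
    excluded for non-positive velocity, or ineligible (insufficient
    scans — including patients with no scans of this modality at all).
    """
    by_patient = group_observations(observations, modality)
    results = []
    for patient in patients:
        obs = by_patient.get(patient.patient_id)
        if not obs:
            results.append(
                DGResult(
                    patient_id=patient.patient_id,
                    modality=modality,
                    status=DGStatus.INELIGIBLE,
                    ineligibility_reason=IneligibilityReason.MISSING_PRETREATMENT_SCAN,
                )
            )
            continue
        results.append(score_patient(obs, patient, volume_units))
    return results


def dg_results_to_frame(results: Iterable[DGResult]) -> pd.DataFrame:
    """Tabular view of DG results with a reproducible column order."""
    rows = [
        {
            "patient_id": r.patient_id,
            "modality": r.modality.value,
            "status": r.status.value,
            "velocity_mm_per_day": r.velocity_mm_per_day,
            "interval_days": r.interval_days,
            "dg_days": r.dg_days,
            "deep_response": r.deep_response,
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def summarize_dg(results: Iterable[DGResult]) -> dict:
    """Bookkeeping summary: counts per status plus median and range of DG."""
    results = list(results)
    scored = [r.dg_days for r in results if r.status is DGStatus.SCORED]
    summary = {
        "n_input": len(results),
        "n_scored": len(scored),
        "n_excluded_nonpositive_velocity": sum(
            r.status is DGStatus.EXCLUDED_NONPOSITIVE_VELOCITY for r in results
        ),
        "n_ineligible": sum(r.status is DGStatus.INELIGIBLE for r in results),
        "dg_median": None,
        "dg_min": None,
        "dg_max": None,
    }
    if scored:
        scored.sort()
        mid = len(scored) // 2
        median = (
            scored[mid]
            if len(scored) % 2
            else 0.5 * (scored[mid - 1] + scored[mid])
        )
        summary.update(dg_median=median, dg_min=scored[0], dg_max=scored[-1])
    return summary
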