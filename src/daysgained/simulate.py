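"""Synthetic cohort generator for the DG analysis pipeline.

Emulates the data structure the analysis assumes — no images, just the
volume-level quantities the pipeline consumes:

* per patient, one MRI session timeline shared by both sequences
  (two pre-treatment sessions, one post-treatment session);
* per modality, a latent linear radial growth velocity ``v`` (log-normal;
  a configurable fraction of FLAIR cases get a negated velocity, to
  exercise the exclusion path);
* a treatment *deflection* in days that sets the tumor back along its
  own growth line: ``r_post = r_pre2 + v * (dt_post - deflection)``
  (+ Gaussian radius noise).  In the noiseless limit the pipeline's DG
  equals the deflection, so every generated cohort carries a known true
  DG per case;
* OS and PFS drawn from an exponential proportional-hazards model whose
  log-hazard is linear in (true T1Gd DG)/25, with administrative plus
  uniform-dropout right censoring;
* a BevAlone / BevCyto split realized as an actual cytotoxic dosing date
  placed inside the evaluation window, so group assignment is exercised
  through the same rule the pipeline applies to real tables.

All randomness flows through one ``numpy.random.default_rng`` (PCG64)
seeded from the config: a fixed seed reproduces the cohort byte for
byte.  The ground-truth sidecar stores the latent quantities every
generated case was built from, for parameter-recovery tests.
"""

from __future__ import annotations

import datetime as dt
import math
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .cohort import (
    ImagingObservation,
    Modality,
    PatientRecord,
    Sex,
    write_cohort,
)
from .dg import radius_to_volume

#: radius floor (mm): a deflection large enough to drive the noiseless
#: post-treatment radius below this saturates there (a complete
#: response); the realized true DG is recomputed from the floored
#: trajectory so it stays exactly what the pipeline should recover
RADIUS_FLOOR_MM = 0.1

_MAX_RESAMPLE_ROUNDS = 100

GROUND_TRUTH_COLUMNS = [
    "patient_id",
    "modality",
    "group",
    "velocity_true_mm_per_day",
    "deflection_days",
    "dg_true_days",
    "log_hazard_os",
    "log_hazard_pfs",
]


class SyntheticConfig(BaseModel):
    """All generator knobs; the defaults are the reference study conditions."""

    n_patients: int = Field(62, ge=1)
    group_split_bevcyto: float = Field(38 / 62, ge=0.0, le=1.0)
    #: fraction of patients whose FLAIR velocity is negated
    frac_negative_velocity_flair: float = Field(9 / 62, ge=0.0, le=1.0)

    #: log-normal radial growth velocity, mm/day (median = exp(mu))
    velocity_log_mu: float = math.log(0.05)
    velocity_log_sigma: float = Field(0.6, ge=0.0)

    #: log-normal second pre-treatment radius, mm, per modality
    radius_log_mu_t1gd: float = math.log(15.0)
    radius_log_mu_flair: float = math.log(22.0)
    radius_log_sigma: float = Field(0.25, ge=0.0)

    #: inter-scan intervals, whole days, uniform inclusive
    pre_interval_days: tuple[int, int] = (30, 120)
    post_interval_days: tuple[int, int] = (30, 90)

    #: latent treatment effect (days of growth removed); Gaussian
    deflection_mean_days: float = 100.0
    deflection_sd_days: float = Field(120.0, ge=0.0)

    radius_noise_sd_mm: float = Field(0.2, ge=0.0)

    #: proportional-hazards truth: HR per +25 true T1Gd DG
    os_hr_per25: float = Field(0.875, gt=0.0)
    pfs_hr_per25: float = Field(0.877, gt=0.0)
    baseline_median_os_days: float = Field(270.0, gt=0.0)
    baseline_median_pfs_days: float = Field(120.0, gt=0.0)
    #: the DG at which the baseline hazard applies (centers the linear predictor)
    dg_reference_days: float = 100.0
    #: shared OS/PFS log-normal patient frailty (sd of the log); 0 = off
    frailty_sd: float = Field(0.0, ge=0.0)

    admin_horizon_days: float = Field(1095.0, gt=0.0)
    dropout_window_days: tuple[float, float] = (180.0, 1500.0)

    prob_male: float = Field(42 / 62, ge=0.0, le=1.0)
    age_mean: float = 57.0
    age_sd: float = Field(12.0, ge=0.0)

    calendar_base: dt.date = dt.date(2013, 1, 1)
    seed: int = 0

    @model_validator(mode="after")
    def _check_intervals(self):
        for name in ("pre_interval_days", "post_interval_days"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"{name} must satisfy 1 <= low <= high")
        lo, hi = self.dropout_window_days
        if lo <= 0 or hi < lo:
            raise ValueError("dropout_window_days must satisfy 0 < low <= high")
        return self


def _draw_positive_kinetics(rng, n, cfg, radius_log_mu, negate_mask, dt_pre):
    """Velocities and pre-treatment radii with r_pre1 > 0.

    ``dt_pre`` (the patient's pre-treatment inter-scan interval) is
    drawn once per patient and shared across modalities — one MRI
    session yields both sequences.  Entries whose back-extrapolated
    first radius would be non-positive are redrawn (bounded number of
    rounds), keeping the draw vectorized and deterministic.
    """
    v = rng.lognormal(cfg.velocity_log_mu, cfg.velocity_log_sigma, n)
    r_pre2 = rng.lognormal(radius_log_mu, cfg.radius_log_sigma, n)
    signed_v = np.where(negate_mask, -v, v)
    for _ in range(_MAX_RESAMPLE_ROUNDS):
        r_pre1 = r_pre2 - signed_v * dt_pre
        bad = r_pre1 <= RADIUS_FLOOR_MM
        if not bad.any():
            return signed_v, r_pre2
        k = int(bad.sum())
        v_new = rng.lognormal(cfg.velocity_log_mu, cfg.velocity_log_sigma, k)
        r_new = rng.lognormal(radius_log_mu, cfg.radius_log_sigma, k)
        signed_v = signed_v.copy()
        r_pre2 = r_pre2.copy()
        signed_v[bad] = np.where(negate_mask[bad], -v_new, v_new)
        r_pre2[bad] = r_new
    raise RuntimeError(
        "could not draw positive pre-treatment radii; "
        "velocity/radius configuration is inconsistent"
    )


def _post_radius(rng, cfg, r_pre2, v, dt_post, deflection):
    """Noiseless post radius (floored), realized true DG, and noisy radius."""
    r_post0 = r_pre2 + v * (dt_post - deflection)
    r_post0 = np.maximum(r_post0, RADIUS_FLOOR_MM)
    with np.errstate(divide="ignore", invalid="ignore"):
        dg_true = dt_post - (r_post0 - r_pre2) / v
    r_post = r_post0.copy()
    if cfg.radius_noise_sd_mm > 0:
        noise = rng.normal(0.0, cfg.radius_noise_sd_mm, r_post0.shape)
        r_post = r_post0 + noise
        for _ in range(_MAX_RESAMPLE_ROUNDS):
            bad = r_post <= 0
            if not bad.any():
                break
            r_post[bad] = r_post0[bad] + rng.normal(
                0.0, cfg.radius_noise_sd_mm, int(bad.sum())
            )
        else:
            raise RuntimeError("could not draw positive noisy post radii")
    return r_post0, dg_true, r_post


def _draw_survival(rng, cfg, dg_true, hr_per25, median_days, frailty):
    beta = math.log(hr_per25)
    lp = beta * (dg_true - cfg.dg_reference_days) / 25.0 + frailty
    hazard = math.log(2.0) / median_days * np.exp(lp)
    event_time = rng.exponential(1.0 / hazard)
    dropout = rng.uniform(*cfg.dropout_window_days, size=dg_true.shape)
    censor_time = np.minimum(cfg.admin_horizon_days, dropout)
    time = np.minimum(event_time, censor_time)
    event = event_time <= censor_time
    return np.maximum(np.round(time, 1), 1.0), event


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[list[ImagingObservation], list[PatientRecord], pd.DataFrame]:
    """Generate one synthetic cohort.

    Returns the observation and patient records (the same in-memory
    types :func:`daysgained.cohort.load_cohort` produces) plus the
    ground-truth sidecar table.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    ids = [f"P{i:04d}" for i in range(1, n + 1)]

    # timeline (shared by both MRI sequences within a session)
    start_offsets = rng.integers(0, 4 * 365 + 1, n)
    treatment_start = [
        cfg.calendar_base + dt.timedelta(days=int(o)) for o in start_offsets
    ]
    gap = rng.integers(1, 15, n)  # days from pre2 scan to treatment start
    dt_pre = rng.integers(cfg.pre_interval_days[0], cfg.pre_interval_days[1] + 1, n)
    dt_post = rng.integers(cfg.post_interval_days[0], cfg.post_interval_days[1] + 1, n)

    # treatment groups
    n_cyto = int(round(cfg.group_split_bevcyto * n))
    cyto_mask = np.zeros(n, dtype=bool)
    cyto_mask[rng.permutation(n)[:n_cyto]] = True

    # per-modality kinetics; FLAIR gets the planted negative velocities
    n_neg = int(round(cfg.frac_negative_velocity_flair * n))
    neg_flair = np.zeros(n, dtype=bool)
    neg_flair[rng.choice(n, size=n_neg, replace=False)] = True
    no_neg = np.zeros(n, dtype=bool)

    per_modality = {}
    for modality, radius_mu, neg_mask in [
        (Modality.T1GD, cfg.radius_log_mu_t1gd, no_neg),
        (Modality.FLAIR, cfg.radius_log_mu_flair, neg_flair),
    ]:
        v, r_pre2 = _draw_positive_kinetics(rng, n, cfg, radius_mu, neg_mask, dt_pre)
        deflection = rng.normal(cfg.deflection_mean_days, cfg.deflection_sd_days, n)
        r_post0, dg_true, r_post = _post_radius(rng, cfg, r_pre2, v, dt_post, deflection)
        r_pre1 = r_pre2 - v * dt_pre
        per_modality[modality] = dict(
            v=v, r_pre1=r_pre1, r_pre2=r_pre2, r_post=r_post,
            deflection=deflection, dg_true=dg_true,
        )

    # survival driven by the realized true T1Gd DG
    dg_driver = per_modality[Modality.T1GD]["dg_true"]
    frailty = (
        rng.normal(0.0, cfg.frailty_sd, n) if cfg.frailty_sd > 0 else np.zeros(n)
    )
    os_time, os_event = _draw_survival(
        rng, cfg, dg_driver, cfg.os_hr_per25, cfg.baseline_median_os_days, frailty
    )
    pfs_time, pfs_event = _draw_survival(
        rng, cfg, dg_driver, cfg.pfs_hr_per25, cfg.baseline_median_pfs_days, frailty
    )

    age = np.clip(rng.normal(cfg.age_mean, cfg.age_sd, n), 20.0, 85.0).round(1)
    male = rng.random(n) < cfg.prob_male

    observations: list[ImagingObservation] = []
    patients: list[PatientRecord] = []
    truth_rows = []
    for i, pid in enumerate(ids):
        start = treatment_start[i]
        pre2_day = -int(gap[i])
        post1_day = pre2_day + int(dt_post[i])
        scan_days = {}
        pre1_day = pre2_day - int(dt_pre[i])
        for modality in (Modality.T1GD, Modality.FLAIR):
            m = per_modality[modality]
            for day, radius in [
                (pre1_day, m["r_pre1"][i]),
                (pre2_day, m["r_pre2"][i]),
                (post1_day, m["r_post"][i]),
            ]:
                observations.append(
                    ImagingObservation(
                        patient_id=pid,
                        scan_date=start + dt.timedelta(days=day),
                        modality=modality,
                        volume_mm3=radius_to_volume(float(radius)),
                    )
                )
        if cyto_mask[i]:
            # one cytotoxic dose mid-window: strictly after the second
            # pre-treatment scan, on or before the post-treatment scan
            dose_day = pre2_day + max(1, int(dt_post[i]) // 2)
            cyto_dates = (start + dt.timedelta(days=dose_day),)
        else:
            cyto_dates = ()
        patients.append(
            PatientRecord(
                patient_id=pid,
                treatment_start=start,
                age_at_start=float(age[i]),
                sex=Sex.M if male[i] else Sex.F,
                cytotoxic_dates=cyto_dates,
                os_time_days=float(os_time[i]),
                os_event=bool(os_event[i]),
                pfs_time_days=float(pfs_time[i]),
                pfs_event=bool(pfs_event[i]),
            )
        )
        group = "BevCyto" if cyto_mask[i] else "BevAlone"
        for modality in (Modality.T1GD, Modality.FLAIR):
            m = per_modality[modality]
            v_i = float(m["v"][i])
            truth_rows.append(
                {
                    "patient_id": pid,
                    "modality": modality.value,
                    "group": group,
                    "velocity_true_mm_per_day": v_i,
                    "deflection_days": float(m["deflection"][i]),
                    "dg_true_days": float(m["dg_true"][i]) if v_i > 0 else np.nan,
                    "log_hazard_os": float(
                        math.log(cfg.os_hr_per25)
                        * (dg_driver[i] - cfg.dg_reference_days) / 25.0
                        + frailty[i]
                    ),
                    "log_hazard_pfs": float(
                        math.log(cfg.pfs_hr_per25)
                        * (dg_driver[i] - cfg.dg_reference_days) / 25.0
                        + frailty[i]
                    ),
                }
            )
    truth = pd.DataFrame(truth_rows, columns=GROUND_TRUTH_COLUMNS)
    return observations, patients, truth


def generate_null_cohort(
    config: SyntheticConfig,
) -> tuple[list[ImagingObservation], list[PatientRecord], pd.DataFrame]:
    """Same generator with survival independent of DG (both HRs = 1)."""
    null_cfg = config.model_copy(update={"os_hr_per25": 1.0, "pfs_hr_per25": 1.0})
    return generate_cohort(null_cfg)


def write_synthetic_cohort(
    config: SyntheticConfig, out_dir, null: bool = False
) -> dict[str, Path]:
    """Generate and write the cohort files plus the ground-truth sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gen = generate_null_cohort if null else generate_cohort
    observations, patients, truth = gen(config)
    paths = {
        "longitudinal": out / "longitudinal.csv",
        "patients": out / "patients.csv",
        "ground_truth": out / "ground_truth.csv",
        "config": out / "synthetic_config.json",
    }
    write_cohort(observations, patients, paths["longitudinal"], paths["patients"])
    truth.to_csv(paths["ground_truth"], index=False, float_format="%.10g")
    paths["config"].write_text(config.model_dump_json(indent=2) + "\n")
    return paths
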