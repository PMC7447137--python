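"""End-to-end orchestration: validate -> score DG -> survival -> tables/plots.

A run produces a deterministic directory layout::

    out/
      dg_scores.csv   one row per (patient, modality) with status and DG
      km_table.csv    log-rank results per modality x subgroup x endpoint x cutoff
      cox_table.csv   uni/multivariate Cox hazard ratios (DG per 25 days)
      sweep.csv       iterative threshold-sweep grid
      figures/        KM curves and sweep significance maps (optional)
      run.log         versions, config echo, exclusion bookkeeping

Stage failures raise :class:`PipelineStageError` carrying the stage
name; the CLI maps stages to distinct nonzero exit codes.
"""

from __future__ import annotations

import datetime as dt
import logging
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .cohort import (
    CohortValidationError,
    EligibilityStatus,
    Modality,
    assign_treatment_group,
    group_observations,
    load_cohort,
    select_dg_scans,
)
from .dg import DGStatus, dg_results_to_frame, score_cohort, summarize_dg
from .survival import (
    PRIOR_CUTOFF_OS,
    PRIOR_CUTOFF_PFS,
    DegenerateCovariateError,
    cox_fit,
    dichotomize,
    iterative_km_sweep,
    km_logrank,
)
from lifelines.exceptions import ConvergenceError

logger = logging.getLogger("daysgained")

_FLOAT_FORMAT = "%.10g"
ALL_GROUPS = "All"


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


class RunConfig(BaseModel):
    """Pipeline configuration; defaults reproduce the standard analysis
    shape (prior + median cutoffs, threshold sweep, uni/multivariate Cox)."""

    longitudinal: Path
    patients: Path
    out_dir: Path
    modality: Literal["t1gd", "flair", "both"] = "both"
    cutoff_os: float = PRIOR_CUTOFF_OS
    cutoff_pfs: float = PRIOR_CUTOFF_PFS
    median_cutoffs: bool = True
    sweep_step: float = Field(5.0, gt=0.0)
    min_group_size: int = Field(3, ge=1)
    volume_units: Literal["mm3", "cm3"] = "mm3"
    make_plots: bool = True
    run_sweep: bool = True
    run_cox: bool = True
    seed: int = 0
    log_level: str = "INFO"


def _requested_modalities(config: RunConfig) -> list[Modality]:
    return {
        "t1gd": [Modality.T1GD],
        "flair": [Modality.FLAIR],
        "both": [Modality.T1GD, Modality.FLAIR],
    }[config.modality]


def build_analysis_frame(results, observations, patients, modality) -> pd.DataFrame:
    """Scored patients with DG, outcomes, covariates and treatment group.

    One row per scored (patient, modality) case, merged with the patient
    record and the window-rule treatment group — the table every
    survival stage consumes.
    """
    by_patient = group_observations(observations, modality)
    patient_index = {p.patient_id: p for p in patients}
    rows = []
    for r in results:
        if r.status is not DGStatus.SCORED:
            continue
        patient = patient_index[r.patient_id]
        selected = select_dg_scans(by_patient[r.patient_id], patient.treatment_start)
        assert not isinstance(selected, EligibilityStatus)
        _, pre2, post1 = selected
        group = assign_treatment_group(patient, pre2.scan_date, post1.scan_date)
        rows.append(
            {
                "patient_id": r.patient_id,
                "modality": modality.value,
                "dg_days": r.dg_days,
                "group": group.group.value,
                "age": patient.age_at_start,
                "sex_M": 1.0 if patient.sex.value == "M" else 0.0,
                "os_time": patient.os_time_days,
                "os_event": int(patient.os_event),
                "pfs_time": patient.pfs_time_days,
                "pfs_event": int(patient.pfs_event),
            }
        )
    return pd.DataFrame(rows)


def _endpoint_columns(endpoint: str) -> tuple[str, str]:
    return ("os_time", "os_event") if endpoint == "OS" else ("pfs_time", "pfs_event")


def _km_rows(frame: pd.DataFrame, modality: Modality, config: RunConfig) -> list[dict]:
    rows = []
    for subset_name in (ALL_GROUPS, "BevAlone", "BevCyto"):
        sub = frame if subset_name == ALL_GROUPS else frame[frame["group"] == subset_name]
        if sub.empty:
            continue
        for endpoint in ("OS", "PFS"):
            tcol, ecol = _endpoint_columns(endpoint)
            prior = config.cutoff_os if endpoint == "OS" else config.cutoff_pfs
            cutoffs = [("prior", prior)]
            if config.median_cutoffs:
                cutoffs.append(("median", float(np.median(sub["dg_days"]))))
            for source, cutoff in cutoffs:
                labels = dichotomize(sub["dg_days"], cutoff)
                km = km_logrank(sub[tcol], sub[ecol], labels, min_group_size=1)
                rows.append(
                    {
                        "modality": modality.value,
                        "group": subset_name,
                        "endpoint": endpoint,
                        "cutoff_source": source,
                        "cutoff": cutoff,
                        "n_high": km.group_sizes.get("High", 0),
                        "n_low": km.group_sizes.get("Low", 0),
                        "chi_square": km.chi_square,
                        "p_value": km.p_value,
                        "evaluable": km.evaluable,
                    }
                )
    return rows


def _cox_rows(frame: pd.DataFrame, modality: Modality) -> list[dict]:
    rows = []
    for subset_name in (ALL_GROUPS, "BevAlone", "BevCyto"):
        sub = frame if subset_name == ALL_GROUPS else frame[frame["group"] == subset_name]
        if sub.empty:
            continue
        for endpoint in ("OS", "PFS"):
            tcol, ecol = _endpoint_columns(endpoint)
            for model_type in ("univariate", "multivariate"):
                base = {
                    "modality": modality.value,
                    "group": subset_name,
                    "endpoint": endpoint,
                    "model": model_type,
                }
                try:
                    result = cox_fit(
                        sub["dg_days"],
                        sub[tcol],
                        sub[ecol],
                        age=sub["age"] if model_type == "multivariate" else None,
                        sex_male=sub["sex_M"] if model_type == "multivariate" else None,
                        model_type=model_type,
                        endpoint=endpoint,
                    )
                except (ValueError, DegenerateCovariateError, ConvergenceError) as exc:
                    logger.warning(
                        "Cox fit skipped (%s %s %s %s): %s",
                        modality.value, subset_name, endpoint, model_type, exc,
                    )
                    rows.append({**base, "covariate": None, "hr": None,
                                 "ci_low": None, "ci_high": None, "p": None,
                                 "n": len(sub), "events": int(sub[ecol].sum()),
                                 "note": str(exc)})
                    continue
                for covariate, row in result.table.iterrows():
                    rows.append(
                        {
                            **base,
                            "covariate": covariate,
                            "hr": row["hr"],
                            "ci_low": row["ci_low"],
                            "ci_high": row["ci_high"],
                            "p": row["p"],
                            "n": result.n,
                            "events": result.n_events,
                            "note": "",
                        }
                    )
    return rows


def _sweep_rows(frame: pd.DataFrame, modality: Modality, config: RunConfig) -> list[dict]:
    rows = []
    for subset_name in (ALL_GROUPS, "BevAlone", "BevCyto"):
        sub = frame if subset_name == ALL_GROUPS else frame[frame["group"] == subset_name]
        if len(sub) < 2 * config.min_group_size:
            continue
        for endpoint in ("OS", "PFS"):
            tcol, ecol = _endpoint_columns(endpoint)
            sweep = iterative_km_sweep(
                sub["dg_days"],
                sub[tcol],
                sub[ecol],
                step=config.sweep_step,
                min_group_size=config.min_group_size,
            )
            for _, r in sweep.table.iterrows():
                rows.append(
                    {
                        "modality": modality.value,
                        "group": subset_name,
                        "endpoint": endpoint,
                        "cutoff": r["cutoff"],
                        "n_high": int(r["n_high"]),
                        "n_low": int(r["n_low"]),
                        "p_value": r["p_value"],
                        "evaluable": bool(r["evaluable"]),
                    }
                )
    return rows


def _plot_km(frame, modality, endpoint, cutoff, path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from lifelines import KaplanMeierFitter

    tcol, ecol = _endpoint_columns(endpoint)
    labels = dichotomize(frame["dg_days"], cutoff)
    fig, ax = plt.subplots(figsize=(5, 4))
    for lab in ("High", "Low"):
        mask = labels == lab
        if not mask.any():
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(frame[tcol][mask], frame[ecol][mask], label=f"{lab} DG (n={mask.sum()})")
        kmf.plot_survival_function(ax=ax)
    ax.set_xlabel(f"{endpoint} time (days)")
    ax.set_ylabel("Survival probability")
    ax.set_title(f"DG_{modality.value} cutoff {cutoff:g}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_sweep(sweep_df, modality, path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = sweep_df[sweep_df["modality"] == modality.value]
    panels = [(g, e) for g in ("BevAlone", "BevCyto") for e in ("OS", "PFS")]
    fig, axes = plt.subplots(2, 2, figsize=(9, 6), sharex=True)
    for ax, (grp, endpoint) in zip(axes.ravel(), panels):
        block = sub[(sub["group"] == grp) & (sub["endpoint"] == endpoint)]
        evaluable = block[block["evaluable"]]
        if not evaluable.empty:
            sig = evaluable["p_value"] <= 0.05
            ax.scatter(evaluable["cutoff"][~sig], evaluable["p_value"][~sig],
                       c="grey", s=12, label="p > .05")
            ax.scatter(evaluable["cutoff"][sig], evaluable["p_value"][sig],
                       c="tab:red", s=12, label="p <= .05")
            ax.axhline(0.05, ls="--", lw=0.8, c="k")
            ax.set_yscale("log")
        ax.set_title(f"{grp} {endpoint}")
    for ax in axes[-1]:
        ax.set_xlabel(f"DG_{modality.value} cutoff (days)")
    for ax in axes[:, 0]:
        ax.set_ylabel("log-rank p")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [
        f"daysgained {__version__} | numpy {np.__version__} | pandas {pd.__version__}",
        f"started {dt.datetime.now().isoformat(timespec='seconds')}",
        "config: " + config.model_dump_json(),
        "boundary rule: DG >= cutoff -> High",
    ]

    try:
        observations, patients = load_cohort(config.longitudinal, config.patients)
    except (CohortValidationError, FileNotFoundError) as exc:
        raise PipelineStageError("validate", str(exc)) from exc

    dg_frames, km_rows, cox_rows, sweep_rows = [], [], [], []
    analysis_frames = {}
    for modality in _requested_modalities(config):
        if not any(o.modality is modality for o in observations):
            raise PipelineStageError(
                "score",
                f"no {modality.value} observations in the longitudinal table",
            )
        try:
            results = score_cohort(observations, patients, modality, config.volume_units)
        except Exception as exc:  # noqa: BLE001 - stage boundary
            raise PipelineStageError("score", str(exc)) from exc
        summary = summarize_dg(results)
        log_lines.append(
            f"{modality.value}: N_input={summary['n_input']} "
            f"scored={summary['n_scored']} "
            f"excluded_nonpositive_velocity={summary['n_excluded_nonpositive_velocity']} "
            f"ineligible={summary['n_ineligible']} "
            f"median_dg={summary['dg_median']}"
        )
        dg_frames.append(dg_results_to_frame(results))
        frame = build_analysis_frame(results, observations, patients, modality)
        analysis_frames[modality] = frame
        if frame.empty:
            continue
        try:
            km_rows.extend(_km_rows(frame, modality, config))
            if config.run_cox:
                cox_rows.extend(_cox_rows(frame, modality))
        except Exception as exc:  # noqa: BLE001 - stage boundary
            raise PipelineStageError("survival", str(exc)) from exc
        if config.run_sweep:
            try:
                sweep_rows.extend(_sweep_rows(frame, modality, config))
            except Exception as exc:  # noqa: BLE001 - stage boundary
                raise PipelineStageError("sweep", str(exc)) from exc

    try:
        pd.concat(dg_frames, ignore_index=True).to_csv(
            out / "dg_scores.csv", index=False, float_format=_FLOAT_FORMAT
        )
        pd.DataFrame(km_rows).to_csv(
            out / "km_table.csv", index=False, float_format=_FLOAT_FORMAT
        )
        if config.run_cox:
            pd.DataFrame(cox_rows).to_csv(
                out / "cox_table.csv", index=False, float_format=_FLOAT_FORMAT
            )
        if config.run_sweep:
            sweep_df = pd.DataFrame(sweep_rows)
            sweep_df.to_csv(out / "sweep.csv", index=False, float_format=_FLOAT_FORMAT)
        if config.make_plots:
            figures = out / "figures"
            figures.mkdir(exist_ok=True)
            for modality, frame in analysis_frames.items():
                if frame.empty:
                    continue
                for endpoint, cutoff in [("OS", config.cutoff_os), ("PFS", config.cutoff_pfs)]:
                    _plot_km(
                        frame, modality, endpoint, cutoff,
                        figures / f"km_{modality.value}_{endpoint}.png",
                    )
                if config.run_sweep and sweep_rows:
                    _plot_sweep(sweep_df, modality, figures / f"sweep_{modality.value}.png")
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
    except PipelineStageError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineStageError("output", str(exc)) from exc
    return out
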