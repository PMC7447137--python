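"""Survival analysis of Days Gained scores.

Three stages, mirroring a standard response-metric evaluation:

* dichotomize DG at a cutoff into High/Low responders and compare the
  groups with a Kaplan–Meier product-limit estimate and an (unweighted)
  two-sample log-rank test;
* sweep a grid of cutoffs and record log-rank significance at each, to
  map the range of thresholds that discriminate outcome;
* fit Cox proportional-hazards models with DG entered per 25 days
  (hazard ratios are then "per 25 DG"), univariate or adjusted for age
  and sex (M = 1).

Kaplan–Meier product-limit curves and the Cox partial likelihood
(Efron handling of tied event times) are delegated to ``lifelines``.
The two-sample log-rank statistic is computed in-package in vectorized
form — the threshold sweep evaluates it once per grid cutoff — and is
verified against both a brute-force risk-set enumeration and lifelines
in the test suite.  This module owns the cutoff semantics, the sweep,
and reporting.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

HIGH, LOW = "High", "Low"

#: prior optimal T1Gd DG cutoffs identified in the newly diagnosed,
#: first-line-therapy setting (linear UVC model)
PRIOR_CUTOFF_OS = 78.0
PRIOR_CUTOFF_PFS = 93.0


class CutoffSource(str, enum.Enum):
    PRIOR_OS_78 = "prior_os_78"
    PRIOR_PFS_93 = "prior_pfs_93"
    COHORT_MEDIAN = "cohort_median"
    USER = "user"


class Endpoint(str, enum.Enum):
    OS = "OS"
    PFS = "PFS"


@dataclass(frozen=True)
class CutoffSpec:
    value: float
    source: CutoffSource
    endpoint: Endpoint

    def __post_init__(self):
        if self.source is CutoffSource.PRIOR_OS_78 and self.value != PRIOR_CUTOFF_OS:
            raise ValueError("prior_os_78 cutoff must have value 78")
        if self.source is CutoffSource.PRIOR_PFS_93 and self.value != PRIOR_CUTOFF_PFS:
            raise ValueError("prior_pfs_93 cutoff must have value 93")


class DegenerateCovariateError(ValueError):
    """A Cox covariate is constant; its hazard ratio is undefined."""


@dataclass
class KMResult:
    """Two-group Kaplan–Meier comparison."""

    curves: dict  # label -> DataFrame(time, at_risk, events, survival)
    group_sizes: dict
    chi_square: float | None
    p_value: float | None
    evaluable: bool
    note: str = ""


@dataclass
class SweepResult:
    """Per-cutoff log-rank significance over a grid of DG thresholds."""

    table: pd.DataFrame  # columns cutoff, n_high, n_low, p_value, evaluable
    min_group_size: int


@dataclass
class CoxResult:
    model_type: str  # "univariate" | "multivariate"
    endpoint: str
    table: pd.DataFrame  # index covariate; columns hr, ci_low, ci_high, p
    n: int
    n_events: int


def dichotomize(dg_scores, cutoff_value: float) -> np.ndarray:
    """High/Low labels; a score exactly at the cutoff is High."""
    scores = np.asarray(dg_scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("DG scores must be finite for dichotomization")
    return np.where(scores >= cutoff_value, HIGH, LOW)


def median_cutoff(dg_scores, endpoint: Endpoint) -> CutoffSpec:
    scores = np.asarray(dg_scores, dtype=float)
    return CutoffSpec(float(np.median(scores)), CutoffSource.COHORT_MEDIAN, endpoint)


def _logrank_statistic(times, events, group_mask) -> tuple[float, float]:
    """Unweighted two-sample log-rank chi-square and p-value.

    Standard hypergeometric form over the pooled risk set at each
    distinct event time; vectorized because the threshold sweep calls
    this once per grid cutoff.  Returns (0, 1) when the risk sets carry
    no discriminating information (zero variance, e.g. no events).
    """
    order = np.argsort(times, kind="stable")
    t = times[order]
    e = events[order].astype(np.int64)
    g = group_mask[order].astype(np.int64)
    n = len(t)
    uniq_idx = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    at_risk = n - uniq_idx
    at_risk1 = int(g.sum()) - np.r_[0, np.cumsum(g)][uniq_idx]
    d = np.add.reduceat(e, uniq_idx)
    d1 = np.add.reduceat(e * g, uniq_idx)
    keep = d > 0
    nj, n1j, dj, d1j = at_risk[keep], at_risk1[keep], d[keep], d1[keep]
    observed_minus_expected = float(np.sum(d1j - dj * n1j / nj))
    multi = nj > 1
    variance = float(
        np.sum(
            dj[multi]
            * (n1j[multi] / nj[multi])
            * (1 - n1j[multi] / nj[multi])
            * (nj[multi] - dj[multi])
            / (nj[multi] - 1)
        )
    )
    if variance <= 0.0:
        return 0.0, 1.0
    statistic = observed_minus_expected**2 / variance
    return statistic, float(stats.chi2.sf(statistic, df=1))


def _km_curve(times, events, label) -> pd.DataFrame:
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events, label=label)
    table = kmf.event_table
    surv = kmf.survival_function_[label]
    return pd.DataFrame(
        {
            "time": table.index.to_numpy(dtype=float),
            "at_risk": table["at_risk"].to_numpy(dtype=float),
            "events": table["observed"].to_numpy(dtype=float),
            "survival": surv.reindex(table.index).to_numpy(dtype=float),
        }
    )


def km_logrank(
    times, events, labels, min_group_size: int = 1, compute_curves: bool = True
) -> KMResult:
    """Kaplan–Meier curves per label plus the two-sample log-rank test.

    If either group is smaller than ``min_group_size`` (in particular
    empty), the comparison is flagged not-evaluable; curves for the
    non-empty groups are still returned.  ``compute_curves=False`` skips
    the product-limit estimates (the test is unchanged) — used by the
    threshold sweep, which only needs p-values.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    labels = np.asarray(labels)
    if np.any(times < 0):
        raise ValueError("survival times must be non-negative")
    uniq = sorted(set(labels.tolist()))
    curves, sizes = {}, {}
    for lab in uniq:
        mask = labels == lab
        sizes[lab] = int(mask.sum())
        if compute_curves:
            curves[lab] = _km_curve(times[mask], events[mask], lab)
    for lab in (HIGH, LOW):
        sizes.setdefault(lab, 0)
    if len(uniq) != 2 or min(sizes[lab] for lab in uniq) < min_group_size:
        return KMResult(
            curves=curves,
            group_sizes=sizes,
            chi_square=None,
            p_value=None,
            evaluable=False,
            note=f"not evaluable: group sizes {sizes} (minimum {min_group_size})",
        )
    a, _ = uniq
    statistic, p_value = _logrank_statistic(times, events, labels == a)
    return KMResult(
        curves=curves,
        group_sizes=sizes,
        chi_square=statistic,
        p_value=p_value,
        evaluable=True,
    )


def default_sweep_grid(dg_scores, step: float = 5.0) -> np.ndarray:
    """Cutoff grid from the 5th to the 95th percentile of observed DG."""
    scores = np.asarray(dg_scores, dtype=float)
    lo, hi = np.percentile(scores, [5.0, 95.0])
    if hi <= lo:
        return np.asarray([lo], dtype=float)
    return np.arange(lo, hi + 1e-9, step, dtype=float)


def iterative_km_sweep(
    dg_scores,
    times,
    events,
    grid=None,
    step: float = 5.0,
    min_group_size: int = 3,
) -> SweepResult:
    """Log-rank p-value at every cutoff of a DG threshold grid.

    Cutoffs leaving fewer than ``min_group_size`` subjects in either arm
    are flagged not-evaluable.  P-values are raw (no multiple-testing
    correction): the sweep maps where discrimination holds, it is not a
    selection procedure.
    """
    scores = np.asarray(dg_scores, dtype=float)
    if grid is None:
        grid = default_sweep_grid(scores, step)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("sweep grid is empty")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("sweep grid must be strictly increasing")
    rows = []
    for cutoff in grid:
        labels = dichotomize(scores, cutoff)
        result = km_logrank(
            times, events, labels, min_group_size=min_group_size, compute_curves=False
        )
        rows.append(
            {
                "cutoff": cutoff,
                "n_high": result.group_sizes.get(HIGH, 0),
                "n_low": result.group_sizes.get(LOW, 0),
                "p_value": result.p_value if result.evaluable else np.nan,
                "evaluable": result.evaluable,
            }
        )
    return SweepResult(table=pd.DataFrame(rows), min_group_size=min_group_size)


def cox_fit(
    dg_scores,
    times,
    events,
    age=None,
    sex_male=None,
    model_type: str = "univariate",
    endpoint: str = "OS",
) -> CoxResult:
    """Cox proportional-hazards fit with DG per 25 days.

    ``model_type='univariate'`` uses dg/25 alone; ``'multivariate'``
    adds age (years) and sex (male = 1).  Hazard ratios, Wald 95%
    confidence intervals and Wald p-values are reported per covariate.
    """
    scores = np.asarray(dg_scores, dtype=float)
    data = {"dg_per25": scores / 25.0}
    if model_type == "multivariate":
        if age is None or sex_male is None:
            raise ValueError("multivariate model requires age and sex")
        data["age"] = np.asarray(age, dtype=float)
        data["sex_M"] = np.asarray(sex_male, dtype=float)
    elif model_type != "univariate":
        raise ValueError(f"unknown model_type {model_type!r}")
    df = pd.DataFrame(data)
    if not np.all(np.isfinite(df.to_numpy())):
        raise ValueError("covariates must be finite")
    df["time"] = np.asarray(times, dtype=float)
    df["event"] = np.asarray(events, dtype=int)
    if int(df["event"].sum()) < 2:
        raise ValueError("Cox fit requires at least 2 observed events")
    for col in data:
        if np.ptp(df[col].to_numpy()) == 0:
            raise DegenerateCovariateError(
                f"covariate {col!r} is constant; hazard ratio undefined"
            )
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as exc:
        raise ConvergenceError(
            f"Cox model did not converge ({model_type}, {endpoint}): {exc}"
        ) from exc
    summary = cph.summary
    table = pd.DataFrame(
        {
            "hr": summary["exp(coef)"],
            "ci_low": summary["exp(coef) lower 95%"],
            "ci_high": summary["exp(coef) upper 95%"],
            "p": summary["p"],
        }
    )
    table.index.name = "covariate"
    return CoxResult(
        model_type=model_type,
        endpoint=endpoint,
        table=table,
        n=len(df),
        n_events=int(df["event"].sum()),
    )


def hazard_reduction_percent(hr: float) -> float:
    """Convert a hazard ratio to a percent hazard reduction.

    ``(1 - hr) * 100`` rounded to one decimal; negative when hr > 1
    (i.e., an increase in hazard).
    """
    if hr <= 0:
        raise ValueError(f"hazard ratio must be positive, got {hr}")
    return round((1.0 - hr) * 100.0, 1)
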