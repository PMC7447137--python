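# daysgained

**Days Gained (DG) treatment-response scoring and survival analysis for
longitudinal volumetric tumor measurements.**

Imaging response criteria that threshold a single diameter or area
(RECIST, Macdonald, RANO) ignore how fast each patient's tumor was
growing before therapy started. In aggressive gliomas — and especially
under anti-angiogenic agents such as bevacizumab, where contrast
"pseudo-response" can mimic real cytoreduction — that pre-treatment
growth rate carries most of the patient-specific signal. The Days
Gained metric addresses this by scoring the *deflection* a therapy
produced relative to the patient's own projected untreated growth, in
units of days.

This package is aimed at quantitative imaging / neuro-oncology
researchers who already have volumetric tumor segmentations (it does
not touch DICOM or perform segmentation) and want to:

1. score DG per patient and MRI sequence (T1Gd, FLAIR),
2. relate DG to overall and progression-free survival, and
3. validate the whole pipeline on synthetic cohorts with known truth.

## The metric

Each segmented tumor-abnormality volume `V` (necrosis included) is
reduced to a spherically equivalent radius

    r = (3 V / 4π)^{1/3}.

Two pre-treatment scans define a linear radial growth velocity
`v = (r₂ − r₁)/(t₂ − t₁)`; extrapolating that line past the second
pre-treatment scan gives the *untreated virtual control* (UVC), the
radius the tumor was expected to reach without therapy. Comparing the
first post-treatment radius `r₃` at time `t₃` against the UVC yields

    DG = (t₃ − t₂) − (r₃ − r₂)/v,

the number of days of growth the therapy removed. `DG = 0` means the
tumor tracked its own prediction; `DG` equal to the whole inter-scan
interval means no net radial growth; negative `DG` means growth faster
than predicted. DG requires `v > 0`; cases with non-positive
pre-treatment velocity are excluded (reported, never silently dropped).

The survival layer dichotomizes DG into High/Low response groups at
fixed cutoffs (78 DG for OS, 93 DG for PFS — thresholds carried over
from the newly diagnosed, first-line setting — plus cohort medians),
compares the groups with Kaplan–Meier/log-rank analyses, sweeps a grid
of cutoffs to map the discriminating range, and fits Cox
proportional-hazards models with DG entered per 25 days (so hazard
ratios read "per 25 DG"), univariate or adjusted for age and sex.

## Worked example

The package ships a synthetic cohort generator that emulates the data
structure the analysis assumes — per-patient scan timelines, log-normal
growth velocities, a latent treatment deflection that *is* the true DG,
measurement noise, a bevacizumab-monotherapy (BevAlone) vs
bevacizumab-plus-cytotoxic (BevCyto) split realized through actual
dosing dates, and OS/PFS drawn from a proportional-hazards model whose
log-hazard is linear in true DG/25. One command simulates a cohort and
runs the full pipeline:

```bash
daysgained demo --n 62 --seed 7 --out demo_run
```

The run log shows the exclusion bookkeeping (the generator plants
negative-velocity FLAIR cases, which DG cannot score):

```
T1Gd:  N_input=62 scored=62 excluded_nonpositive_velocity=0 ineligible=0 median_dg=95.7
FLAIR: N_input=62 scored=53 excluded_nonpositive_velocity=9 ineligible=0 median_dg=103.4
```

`km_table.csv` holds the High/Low log-rank comparisons, e.g. for T1Gd
DG in the full simulated cohort (a score exactly at the cutoff counts
as High):

```
group endpoint cutoff_source  cutoff  n_high  n_low  p_value
  All       OS         prior    78.0      37     25 0.000297
  All       OS        median    95.7      31     31 0.000132
  All      PFS         prior    93.0      34     28 0.002391
```

`cox_table.csv` holds the hazard ratios; the multivariate per-25-DG row
for the full cohort's OS reads HR 0.858 [0.787, 0.936], p = .001 —
`hazard_reduction_percent(0.858)` converts this to a 14.2% reduction in
the hazard of death per 25 DG gained. The generator's truth for this
cohort was HR 0.875 per 25 DG, i.e. a 12.5% reduction, so the pipeline
recovers the planted effect within its confidence interval.

The same stages are available individually (`validate`, `score`,
`survival`, `sweep`, `simulate`) and as library functions
(`score_cohort`, `km_logrank`, `iterative_km_sweep`, `cox_fit`,
`generate_cohort`, ...).

## Limitations

Simulation is at the volume level (no images, no segmentation masks,
no scanner effects), the UVC is the two-point linear model only, and DG
uncertainty propagation is out of scope. See `docs/methods.md` for the
model assumptions, generator defaults, and numerical choices.
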