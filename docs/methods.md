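# Methods

## The Days Gained model

DG treats the tumor abnormality as a sphere of equivalent volume and
assumes its radius grows linearly in time over the pre-treatment
window. The model is deliberately minimal: two pre-treatment scans
fully determine the patient-specific untreated virtual control (UVC)

    r_uvc(t) = r₂ + v·(t − t₂),    v = (r₂ − r₁)/(t₂ − t₁),

and the score for the first post-treatment scan (t₃, r₃) is

    DG = (t₃ − t₂) − (r₃ − r₂)/v = (r_uvc(t₃) − r₃)/v.

Assumptions worth keeping in mind:

* **Linear radial growth.** Gliomas at the sizes analyzed here grow
  approximately linearly in equivalent radius; the package implements
  only this two-point linear UVC, not regression over more scans and
  not the anatomic/spherical 4-D variants. Extra pre-treatment scans
  are ignored by design — only the two most recent before treatment
  start enter the fit.
* **Positive growth required.** DG divides by `v`; cases with
  `v ≤ 1e−12 mm/day` are excluded with status
  `excluded_nonpositive_velocity` rather than scored (an exact zero is
  excluded too, since the score is undefined, and a measurement-noise
  zero is indistinguishable from it).
* **Uncapped scores.** DG is passed through unbounded in both
  directions; deep responses (post radius below the *first*
  pre-treatment radius) are flagged `deep_response` in output but not
  treated specially.
* **Whole-day timestamps.** Scan dates are ISO-8601 calendar dates in
  files and integer day offsets from treatment start internally; the
  metric's unit is days, and sub-day imaging times are not meaningful
  at MRI follow-up cadence.

Boundary conventions (the underlying clinical definitions do not
resolve these, so fixed rules are required for reproducibility):

* a scan on the treatment-start date counts as **post**-treatment;
  pre-treatment means strictly before;
* the concurrent-cytotoxic (BevCyto) window is half-open,
  `(pre2 scan date, post1 scan date]`: a dose on the post-scan day
  still influenced the interval;
* eligibility is per modality — a patient without usable FLAIR scans
  can still be scored on T1Gd, and vice versa;
* two pre-treatment scans on the same date are a degenerate-interval
  error, not a silent skip.

## Survival layer

* **Dichotomization.** `DG ≥ cutoff → High` (ties go High; "above and
  below" alone does not fix tie handling). Default cutoffs are the
  prior thresholds 78 DG (OS) and 93 DG (PFS) from the newly diagnosed
  first-line setting, plus the cohort median computed per analysis
  subgroup after exclusions.
* **Log-rank.** Unweighted two-sample test, hypergeometric
  variance over the pooled risk set at each distinct event time,
  chi-square(1) reference. Implemented in vectorized numpy (the sweep
  evaluates it once per grid cutoff; the lifelines implementation
  costs ~30 ms per call building event tables) and verified in the test
  suite against both a brute-force risk-set enumeration (1e−9) and
  lifelines itself (1e−10). Zero variance (no informative risk sets)
  returns statistic 0, p = 1.
* **Kaplan–Meier curves** come from lifelines' product-limit fitter and
  are checked against event-time-by-event-time brute force.
* **Threshold sweep.** Grid from the 5th to the 95th percentile of
  observed DG in steps of 5 DG; cutoffs leaving fewer than 3 subjects
  in either arm are flagged not-evaluable. P-values are raw — the sweep
  maps where discrimination holds and is not a selection procedure, so
  no multiple-testing correction is applied (this is stated in output).
  The grid and minimum-arm rule are configurable.
* **Cox models.** lifelines `CoxPHFitter` (Efron tie handling, the
  default of the R survival ecosystem). DG enters as `dg/25` so hazard
  ratios read per 25 DG; sex is coded M = 1. Wald 95% CIs and p-values
  on the log-hazard scale. Constant covariates raise a
  degenerate-covariate error; fewer than 2 events is rejected;
  non-convergence propagates as an explicit error. In the pipeline's
  subgroup tables a failed fit becomes a row with a `note` rather than
  aborting the run — small subgroups legitimately fail.
* `hazard_reduction_percent(hr) = (1 − hr)·100`, rounded to one decimal
  for reporting.

## Synthetic cohort generator

The generator produces the statistical structure the analysis assumes,
so every stage is testable without patient data and parameter recovery
is verifiable against stored ground truth.

Per patient: one scan timeline shared by both MRI sequences (an MRI
session yields both T1Gd and FLAIR), with the second pre-treatment scan
1–14 days before treatment start, pre1→pre2 interval uniform on 30–120
days and pre2→post1 uniform on 30–90 days (inter-scan interval
distributions are not clinically standardized; these are configurable
placeholders at realistic follow-up cadence). Per modality: velocity
`v` log-normal with median 0.05 mm/day (log-sd 0.6, spanning the
indolent-to-aggressive range of recurrent disease), second
pre-treatment radius log-normal (median 15 mm T1Gd, 22 mm FLAIR —
FLAIR abnormality envelopes the enhancing core), and a latent
*deflection* `d ~ N(100, 120)` days. The post radius is constructed as

    r₃ = r₂ + v·(Δt − d) + ε,    ε ~ N(0, 0.2 mm),

so in the noiseless limit the pipeline's DG equals `d` exactly — the
construction identity every release is tested against. When a large
deflection would drive the noiseless radius below 0.1 mm it is floored
there (a complete response), and the stored true DG is recomputed from
the floored trajectory so the identity survives saturation. A 9/62
fraction of patients get a negated FLAIR velocity, exercising the
exclusion path at the rate seen in practice; 38/62 of patients receive
a cytotoxic dosing date placed mid-window, so BevCyto assignment is
exercised through the same window rule applied to real tables.

OS and PFS are exponential proportional-hazards draws with log-hazard
`ln(HR_per25)·(DG_true − 100)/25` (defaults HR 0.875 for OS, 0.877 for
PFS; baseline medians 270 and 120 days at the reference DG of 100),
censored by an administrative horizon of 1095 days and uniform dropout
on 180–1500 days. An optional shared log-normal frailty couples the two
endpoints (default off, keeping recovery tests clean). The null
generator sets both HRs to 1. Defaults target a cohort of 62 patients
whose DG medians land near 100 days.

All randomness flows through one `numpy.random.default_rng` (PCG64)
seeded from the config; a fixed seed reproduces every output file byte
for byte, and numpy's PCG64 stream is stable across platforms.

**What the generator does not emulate:** images and segmentation (and
hence segmentation error structure — radius noise is i.i.d. Gaussian on
the post scan only), scanner/institution effects, correlated
velocities between modalities, non-linear growth, informative
censoring, and any dependence of survival on covariates other than DG
(age and sex are drawn independently of outcome). Passing tests
therefore demonstrate internal consistency and statistical correctness
of the machinery under the stated model, not clinical performance on
real cohorts.

## Validation problem sizes

The test suite and `scripts/acceptance.py` use: 1,000 randomized cases
for the closed-form-vs-bisection DG check (tolerance 1e−6 days); a
200-patient noiseless cohort for the construction identity; cohorts of
at most 20 subjects for brute-force KM/log-rank equivalence (1e−9); 50
replicates of 400 patients for Cox recovery at truth HR 0.875 per 25 DG
(95% CI coverage ≥ 90%, mean estimate within ±0.03); 20 null seeds at
the default cohort size for sweep false-positive calibration and 50
null replicates of 200 patients for CI coverage of HR = 1. Across 750
independent recovery replicates the Wald CI covers the truth ~94% of
the time with an unbiased mean estimate; the mild shortfall from the
nominal 95% traces to measurement error in the DG covariate (radius
noise propagated through 1/v) and is inherent to the noisy-measurement
condition, not to the fitting code (a direct PH simulation through the
same Cox routine covers at 96%).

## Known limitations

* The two-point UVC ignores additional pre-treatment scans even when
  they would stabilize the velocity estimate.
* No propagation of segmentation or timing uncertainty into DG
  confidence intervals; DG is a point score here.
* The sweep reports raw p-values; using it to *select* a cutoff and
  then quoting that cutoff's p-value would be circular.
* Median cutoffs are computed per subgroup after exclusions; cohorts
  assembled differently may want to override them via the CLI flags.
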