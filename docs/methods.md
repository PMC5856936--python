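# Methods

## The process being modeled

A hospital cancer registry moves each newly diagnosed reportable tumor
through case finding, a waiting queue, abstraction, and batch submission
to the state registry. `registrysim` simulates that pipeline in continuous
time (fractional days; a uniform 365-day year, months of 365/12 ≈ 30.42
days, no weekends or calendar effects — the step-duration estimates the
model is built on are working-process figures, and a calendar layer would
add parameters nothing in those estimates could calibrate).

Two queue-release policies are compared on identical simulated case
streams:

* **Existing.** Pathology-identified cases surface at the next daily
  pathology scan; ICD disease-index cases at the next monthly index scan.
  Each identified case waits a facility-wide constant suspense time
  `W_h ∈ [90, 180]` days, is abstracted (uniform 45–90 minutes), and ships
  at the next caseload-tiered batch boundary.
* **Redesigned.** Pathology cases surface at the next daily ePath review;
  index cases are unchanged. A case is released at its
  treatment-completion notification, `max(t_identified, t_treat)`, or at
  the 180-day fallback after diagnosis if no treatment is recorded in
  time; abstraction and batch submission are unchanged.

## Stochastic inputs

| Quantity | Distribution | Default | Basis |
| --- | --- | --- | --- |
| Case arrivals | homogeneous Poisson | rate = caseload/365 per day | simplest stationary process consistent with an "average annual caseload" |
| Cancer type | categorical | calibrated weights 0.10 / 0.80 / 0.10 (breast / colorectal / lung); neutral preset = equal thirds | registry mix is unpublished → calibration dial |
| Treatment wait | triangular per type | (24; 14–40), (37; 20–63), (26; 13–46) days | published national diagnosis-to-treatment summaries (Bilimoria et al. 2011) |
| Identification source | Bernoulli | P(pathology) = 0.925 | reported 90–95%, midpoint |
| External records needed | Bernoulli | 0.25 | reported 10–40%, midpoint |
| Suspense wait | per-facility constant ~ U(105, 135) d | mean 120 d | see calibration note below |
| Abstraction | U(45, 90) minutes | — | registrar estimate |
| External-record delay | constant 0 | — | unquantified; see below |

**Triangular from a three-point summary.** Sources give (mean; min–max)
only. A triangular distribution on [min, max] with
`mode = 3·mean − min − max` is the unique member of the family whose
analytic mean equals the stated mean; the derived modes (18, 28, 19 days)
all fall inside their ranges, so the construction is well defined for all
three types. Summaries whose derived mode would leave the range are
rejected with an error rather than silently clamped.

**Suspense-wait spread.** Registrars report "3–6 months, varies among
hospitals" — a *between*-facility statement; within a facility one wait is
applied to all cases. The per-case spread of the published latency table
(SD ≈ 10.8 d) is incompatible with facility waits spread over the full
90–180 band (that alone yields SD ≈ 26 d), so the shipped policy draws
facility waits from the narrower U(105, 135) band (mean 120 d = 4 months);
a `U(90, 180)` full-band policy is available in config. Waits are re-drawn
per replicate; facilities can also pin an explicit wait.

## Calibration

The published comparison depends on two inputs its sources do not print:
the registry's cancer-type mix and the hospital panel. Both are therefore
explicit calibration parameters, fixed once from the analytic
decomposition of the mean reporting time (identification + release policy
+ abstraction + expected batch residence of interval/2 per tier), not
fitted by search:

* **Panel**: eight 350-case (monthly-tier) facilities plus one 150-case
  (every-other-month) and one 60-case (quarterly) facility — ~3,010
  expected cases/year, case-weighted mean batch residence ≈ 16.6 days.
* **Mixture weights** 0.10 / 0.80 / 0.10 give a mean treatment wait of
  ≈ 34.6 days, which with that residence reproduces the published
  redesigned-arm mean; the same panel with the 120-day mean suspense wait
  reproduces the existing-arm mean. The weights are a calibration preset,
  not an epidemiological claim — the equal-thirds preset is the neutral
  default for non-calibrated studies.

## Simulation engine

A bespoke event calendar (binary heap keyed by event time with a
monotone scheduling sequence as tie-break) drives both workflow models.
Simultaneous events fire in scheduling order (stable FIFO); diagnoses are
scheduled before scan boundaries so a diagnosis falling exactly on a
boundary is picked up by that scan, and an abstract completed exactly on a
batch boundary ships on it. Scheduling into the past aborts the run.
Randomness is realized *outside* the event loop: each replicate derives
named substreams (arrivals, types, sources, treatment, suspense,
abstraction, external) from the top-level seed, and both workflow arms
consume the same realized case stream and duration draws, so their
contrast is purely the release policy and replicate results are
reproducible bit-for-bit (checkable via the event-trace hash).

Capacity is unlimited by default: abstraction is a sampled service time
with no queueing for registrar attention, consistent with a latency table
that decomposes additively and reports no backlog dynamics. A
`single_registrar` sensitivity mode serializes abstraction per facility,
stretching service times by 24/8 to mimic an 8-hour workday; it is not
calibrated against any published figure.

Batch boundaries are global multiples of the tier interval from t = 0.
Phase offsets are unidentifiable from the sources and the stationary mean
residence interval/2 is phase-invariant, so none are applied by default.

## Horizon handling

Summaries include only cases *submitted* within the horizon; later cases
are reported as in-flight (conservation: every generated case is exactly
one of the two). This matches the published 1-year vs 2-year framing and
slightly depresses the 1-year means (long-latency cases diagnosed late in
the year are excluded), by well under a day for the redesigned arm and
about half a day for the existing arm at the default settings.

## Design choices on genuinely open points

* **Suspense clock origin (existing).** Whether the fixed wait runs from
  diagnosis or identification is not stated; the workflow ordering implies
  identification, which is what is implemented.
* **Fallback clock (redesigned).** The six-month timeout runs from
  *diagnosis* ("no new treatment within 6 months of the date of
  diagnosis"). A `fallback_from: identification` option exists because it
  makes the redesigned model with notifications disabled degenerate
  exactly to the existing model (a useful structural check; with the
  diagnosis anchor the two differ by the identification delay).
* **External-record delay.** Reported as a barrier but never quantified;
  the default is zero (in the existing arm only — the redesigned HIE path
  is modeled as removing it), so the arm contrast is driven entirely by
  the release policy rather than an invented constant.
* **Daily vs weekly pathology scans.** Daily is the default (the modal
  report); the scan period is per-facility configurable.
* **Non-reportable ICD-flagged cases** (only 2.5–11% of flagged cases are
  reportable) consume review effort but not pipeline time under unlimited
  capacity, so they are not generated.
* **Statistical comparison.** Welch's unequal-variance t-test on
  per-replicate mean reporting times — replicates, not cases, are the
  independent units of a simulation experiment. Quantiles interpolate
  linearly between order statistics; SDs are per-case, pooled across
  replicates, n−1 denominator (recorded in the output metadata).

## What the generator does and does not emulate

The synthetic stream reproduces arrival volume, type mix, source mix,
external-records mix and treatment-wait distributions — everything the
latency model consumes. It carries no stage, histology, demographics,
inter-case correlation, seasonality, or data-quality rework loops, so
passing tests say nothing about those aspects of real registry operations;
they validate the queueing arithmetic and the policy contrast under the
stated assumptions.

## Problem sizes and numerics

Default experiment: 20 replicates × 2 arms × ~3,010 cases over 365 days
(about 9,500 events per run), a few seconds on one CPU. Tests compare the
event engine against a brute-force 0.01-day fixed-step reference on ≤50
case scenarios, and check sampler means/quantiles at n = 100,000 with
3-sigma or Kolmogorov–Smirnov (α = 0.001) bounds. Boundary arithmetic
("next multiple of the interval") uses a 1e-9 relative guard so that
values lying exactly on a boundary, up to float error, ship on it.

## Known limitations

* The simulated existing-arm extremes are wider than the published table
  (max ≈ 229 vs 177.8 d; SD ≈ 15 vs 10.8) because the quarterly-tier
  facility contributes up-to-91-day batch residences; the published run's
  unpublished panel evidently concentrated caseload in higher tiers.
  Means, which the calibration targets, are unaffected.
* Single-state submission rules (the four caseload tiers) are hard-coded
  as the policy surface; other registries' tiers would need a code-level
  extension.
* No inhomogeneous arrivals (seasonality) and no capacity interaction
  between case finding and abstraction.
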