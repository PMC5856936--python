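"""The two hospital reporting-process models.

Existing workflow
    Case finding at periodic scans (daily for pathology reports, monthly
    for the ICD disease index), a fixed facility-wide suspense-file wait so
    that treatment data can accumulate, abstraction, then batch submission
    to the state registry at caseload-tiered intervals.

Redesigned workflow
    ePath identification of pathology cases at a daily review, release from
    the suspense file as soon as the EHR records treatment completion for
    the case (notification), with a fallback release six months after
    diagnosis if no treatment arrives, then abstraction and the same tiered
    batch submission.

Both are expressed as event handlers over the shared kernel in
:mod:`registrysim.engine`; per-case stochastic inputs (arrival stream,
treatment waits, abstraction durations) are realized up front so that the
two variants can be compared on identical case streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .casegen import (
    Case,
    ConfigurationError,
    HospitalProfile,
    PATHOLOGY,
)
from .durations import (
    ABSTRACTION_DEFAULT,
    MONTH_DAYS,
    DistributionSpec,
    ZERO_DELAY,
    sample,
)
from .engine import Simulation
from .rng import named_streams

__all__ = [
    "EXISTING",
    "REDESIGNED",
    "WorkflowConfig",
    "CaseOutcome",
    "WorkflowResult",
    "submission_interval",
    "next_submission_time",
    "identification_time",
    "release_time_existing",
    "release_time_redesigned",
    "simulate_workflow",
]

EXISTING = "existing"
REDESIGNED = "redesigned"

_BOUNDARY_TOL = 1e-9


@dataclass(frozen=True)
class WorkflowConfig:
    """Which process variant to simulate, plus its tunable parameters.

    ``fallback_days`` is the redesigned workflow's no-treatment timeout
    (six months by default).  ``fallback_from`` selects the clock the
    timeout runs against: ``"diagnosis"`` (the default, matching the
    six-months-from-diagnosis rule) or ``"identification"``, under which
    the redesigned model with notifications disabled degenerates exactly
    to the existing fixed-wait model.  ``external_delay`` is the extra
    abstraction delay for cases whose records sit at an outside facility;
    it applies to the existing workflow only, the redesigned workflow's
    HIE/messaging path being modeled as removing it.
    """

    variant: str
    horizon: float
    seed: int = 0
    fallback_days: float = 180.0
    notification_enabled: bool = True
    fallback_from: str = "diagnosis"
    capacity_model: str = "unlimited"
    abstraction: DistributionSpec = ABSTRACTION_DEFAULT
    external_delay: DistributionSpec = ZERO_DELAY
    epath_review_period: float = 1.0
    workday_hours: float = 8.0  # single_registrar mode only

    def __post_init__(self) -> None:
        if self.variant not in (EXISTING, REDESIGNED):
            raise ConfigurationError(f"unknown variant {self.variant!r}")
        if self.horizon <= 0:
            raise ConfigurationError("horizon must be > 0")
        if self.fallback_days <= 0:
            raise ConfigurationError("fallback_days must be > 0")
        if self.fallback_from not in ("diagnosis", "identification"):
            raise ConfigurationError(
                f"unknown fallback_from {self.fallback_from!r}"
            )
        if self.capacity_model not in ("unlimited", "single_registrar"):
            raise ConfigurationError(
                f"unknown capacity_model {self.capacity_model!r}"
            )
        if self.epath_review_period <= 0:
            raise ConfigurationError("epath_review_period must be > 0")


@dataclass(frozen=True)
class CaseOutcome:
    """Completed per-case timeline, fractional days from simulation start."""

    case_id: str
    hospital_id: str
    cancer_type: str
    t_diagnosis: float
    t_identified: float
    t_released: float
    t_abstract_done: float
    t_submitted: float

    @property
    def reporting_time(self) -> float:
        """Days from diagnosis to submission — the primary outcome."""
        return self.t_submitted - self.t_diagnosis

    def __post_init__(self) -> None:
        t = (
            self.t_diagnosis,
            self.t_identified,
            self.t_released,
            self.t_abstract_done,
            self.t_submitted,
        )
        if any(b < a - _BOUNDARY_TOL for a, b in zip(t, t[1:])):
            raise ConfigurationError(f"non-monotone timeline for {self.case_id}: {t}")


@dataclass
class WorkflowResult:
    """Outcomes of one simulated run.

    ``outcomes`` holds cases submitted within the horizon; ``in_flight``
    holds the ids of generated cases still somewhere in the pipeline when
    the horizon ended.  Together they account for every generated case.
    """

    variant: str
    horizon: float
    outcomes: list[CaseOutcome]
    in_flight: list[str]
    trace_hash: str | None = None

    @property
    def reporting_times(self) -> np.ndarray:
        return np.array([o.reporting_time for o in self.outcomes])


def submission_interval(annual_caseload: float) -> float:
    """Caseload-tiered batch-submission period, in days.

    State-registry rules: 1-59 cases/year report annually, 60-149
    quarterly, 150-299 every other month, 300 or more monthly.  A zero
    caseload degenerates to the annual tier.
    """
    if annual_caseload < 0:
        raise ConfigurationError("annual_caseload must be >= 0")
    if annual_caseload < 60:
        return 365.0
    if annual_caseload < 150:
        return 365.0 / 4.0
    if annual_caseload < 300:
        return 365.0 / 6.0
    return MONTH_DAYS


def _next_boundary(period: float, t: float) -> float:
    """Smallest multiple of ``period`` that is >= ``t`` (boundary-inclusive)."""
    if period <= 0:
        raise ConfigurationError("period must be > 0")
    if t <= 0:
        return 0.0
    k = math.ceil(t / period - _BOUNDARY_TOL)
    return k * period


def next_submission_time(interval: float, t: float) -> float:
    """First batch boundary at or after ``t``.

    Batches ship at global multiples of the tier interval counted from the
    simulation start; an abstract completed exactly on a boundary ships on
    that boundary.
    """
    if t < 0:
        raise ConfigurationError("t must be >= 0")
    return _next_boundary(interval, t)


def identification_time(
    case: Case, hospital: HospitalProfile, variant: str, *,
    epath_review_period: float = 1.0,
) -> float:
    """When case finding detects the case.

    Pathology cases surface at the next pathology-scan boundary (existing)
    or the next daily ePath review boundary (redesigned); disease-index
    cases surface at the next monthly index scan in both variants.  A
    diagnosis falling exactly on a boundary is picked up at that boundary.
    """
    if case.source == PATHOLOGY:
        period = (
            hospital.pathology_scan_period
            if variant == EXISTING
            else epath_review_period
        )
    else:
        period = hospital.index_scan_period
    return _next_boundary(period, case.t_diagnosis)


def release_time_existing(t_identified: float, hospital: HospitalProfile) -> float:
    """Fixed-wait release: identification plus the facility suspense wait."""
    return t_identified + hospital.suspense_wait


def release_time_redesigned(
    t_identified: float, case: Case, config: WorkflowConfig
) -> float:
    """Notification release with fallback timeout.

    The case leaves the suspense file at its treatment-completion
    notification (never before identification); if no treatment is
    recorded within ``fallback_days`` of the anchor clock, it is released
    at the timeout instead.  The release never exceeds the timeout.
    """
    anchor = case.t_diagnosis if config.fallback_from == "diagnosis" else t_identified
    t_fallback = anchor + config.fallback_days
    t_treat = case.t_treatment_complete
    if (
        config.notification_enabled
        and t_treat is not None
        and t_treat <= t_fallback
    ):
        return max(t_identified, t_treat)
    return max(t_identified, t_fallback)


def simulate_workflow(
    config: WorkflowConfig,
    hospitals: Sequence[HospitalProfile],
    cases: Sequence[Case],
    *,
    abstraction_by_case: Mapping[str, float] | None = None,
    external_by_case: Mapping[str, float] | None = None,
    collect_trace: bool = False,
) -> WorkflowResult:
    """Run one workflow variant over a realized case stream.

    Per-case abstraction durations (and external-record delays, existing
    variant only) may be supplied explicitly; otherwise they are drawn from
    substreams of ``config.seed`` in case order, so that both variants run
    with identical realizations when given the same seed and cases.
    """
    hosp = {h.hospital_id: h for h in hospitals}
    for case in cases:
        if case.hospital_id not in hosp:
            raise ConfigurationError(f"case {case.case_id}: unknown hospital")

    if abstraction_by_case is None or external_by_case is None:
        streams = named_streams(config.seed)
        if abstraction_by_case is None:
            rng = streams["abstraction"]
            abstraction_by_case = {
                c.case_id: float(sample(config.abstraction, rng)) for c in cases
            }
        if external_by_case is None:
            rng = streams["external"]
            external_by_case = {
                c.case_id: float(sample(config.external_delay, rng))
                for c in cases
            }

    sim = Simulation(collect_trace=collect_trace)
    pending: dict[str, dict[str, list[Case]]] = {
        hid: {"pathology": [], "disease_index": []} for hid in hosp
    }
    submit_queue: dict[str, list[CaseOutcome]] = {hid: [] for hid in hosp}
    partial: dict[str, dict[str, float]] = {}
    outcomes: list[CaseOutcome] = []
    submitted: set[str] = set()
    registrar_free: dict[str, float] = {hid: 0.0 for hid in hosp}
    slowdown = 24.0 / config.workday_hours  # wall-clock stretch, serial mode

    def _submit(case: Case, now: float) -> None:
        p = partial[case.case_id]
        outcomes.append(
            CaseOutcome(
                case_id=case.case_id,
                hospital_id=case.hospital_id,
                cancer_type=case.cancer_type,
                t_diagnosis=case.t_diagnosis,
                t_identified=p["identified"],
                t_released=p["released"],
                t_abstract_done=p["done"],
                t_submitted=now,
            )
        )
        submitted.add(case.case_id)

    def on_diagnosis(sim: Simulation, ev) -> None:
        case: Case = ev.payload
        partial[case.case_id] = {}
        pending[case.hospital_id][case.source].append(case)

    def _identify(sim: Simulation, case: Case, now: float) -> None:
        partial[case.case_id]["identified"] = now
        h = hosp[case.hospital_id]
        if config.variant == EXISTING:
            sim.schedule(
                release_time_existing(now, h), "suspense_release", case
            )
        else:
            t_rel = release_time_redesigned(now, case, config)
            notified = (
                config.notification_enabled
                and case.t_treatment_complete is not None
                and case.t_treatment_complete
                <= (
                    case.t_diagnosis
                    if config.fallback_from == "diagnosis"
                    else now
                )
                + config.fallback_days
            )
            kind = "treatment_notification" if notified else "fallback_timeout"
            sim.schedule(t_rel, kind, case)

    def on_scan(source: str):
        def handler(sim: Simulation, ev) -> None:
            hid = ev.payload
            buffered = pending[hid][source]
            if buffered:
                pending[hid][source] = []
                for case in buffered:
                    _identify(sim, case, sim.clock)
        return handler

    def on_release(sim: Simulation, ev) -> None:
        case: Case = ev.payload
        now = sim.clock
        partial[case.case_id]["released"] = now
        service = abstraction_by_case[case.case_id]
        if config.variant == EXISTING and case.needs_external:
            service += external_by_case[case.case_id]
        if config.capacity_model == "single_registrar":
            start = max(now, registrar_free[case.hospital_id])
            finish = start + service * slowdown
            registrar_free[case.hospital_id] = finish
        else:
            finish = now + service
        sim.schedule(finish, "abstraction_complete", case)

    def on_abstract_done(sim: Simulation, ev) -> None:
        case: Case = ev.payload
        now = sim.clock
        partial[case.case_id]["done"] = now
        h = hosp[case.hospital_id]
        boundary = next_submission_time(h.submission_interval, now)
        if boundary == now:
            _submit(case, now)
        else:
            submit_queue[case.hospital_id].append(case)

    def on_submission_batch(sim: Simulation, ev) -> None:
        hid = ev.payload
        queued = submit_queue[hid]
        if queued:
            submit_queue[hid] = []
            for case in queued:
                _submit(case, sim.clock)

    sim.on("diagnosis", on_diagnosis)
    sim.on("pathology_scan", on_scan("pathology"))
    sim.on("index_scan", on_scan("disease_index"))
    sim.on("suspense_release", on_release)
    sim.on("treatment_notification", on_release)
    sim.on("fallback_timeout", on_release)
    sim.on("abstraction_complete", on_abstract_done)
    sim.on("submission_batch", on_submission_batch)

    # Diagnoses first so that a diagnosis coinciding with a scan boundary is
    # picked up by that very scan (stable FIFO tie-break).
    for case in sorted(cases, key=lambda c: (c.t_diagnosis, c.case_id)):
        sim.schedule(case.t_diagnosis, "diagnosis", case)
    for h in hospitals:
        period = (
            h.pathology_scan_period
            if config.variant == EXISTING
            else config.epath_review_period
        )
        for k in range(1, int(config.horizon / period + _BOUNDARY_TOL) + 1):
            sim.schedule(k * period, "pathology_scan", h.hospital_id)
        for k in range(1, int(config.horizon / h.index_scan_period + _BOUNDARY_TOL) + 1):
            sim.schedule(k * h.index_scan_period, "index_scan", h.hospital_id)
        n_batches = int(config.horizon / h.submission_interval + _BOUNDARY_TOL)
        for k in range(1, n_batches + 1):
            sim.schedule(k * h.submission_interval, "submission_batch", h.hospital_id)

    sim.run_until(config.horizon)

    in_flight = [c.case_id for c in cases if c.case_id not in submitted]
    return WorkflowResult(
        variant=config.variant,
        horizon=config.horizon,
        outcomes=outcomes,
        in_flight=in_flight,
        trace_hash=sim.trace_hash() if collect_trace else None,
    )
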