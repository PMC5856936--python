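"""Replicate-level experiment orchestration.

One experiment = the same generated case streams pushed through one or
both workflow variants, replicated ``config.replicates`` times with
independent seeds spawned from the top-level seed.  Within a replicate the
two variants share the case stream and all per-case duration draws, so the
contrast between them is purely the queue-release policy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .casegen import Case, HospitalProfile, generate_cases
from .config import RunConfig
from .durations import draw_suspense_wait, sample
from .metrics import ComparisonResult, ReportingSummary, compare, summarize
from .rng import named_streams
from .workflows import (
    EXISTING,
    REDESIGNED,
    WorkflowConfig,
    WorkflowResult,
    simulate_workflow,
)

__all__ = ["ArmResult", "ExperimentResult", "run_experiment", "build_panel"]


@dataclass
class ArmResult:
    variant: str
    replicates: list[WorkflowResult]
    summary: ReportingSummary

    @property
    def outcomes_by_replicate(self) -> list[list]:
        return [r.outcomes for r in self.replicates]

    @property
    def pooled_outcomes(self) -> list:
        return [o for r in self.replicates for o in r.outcomes]


@dataclass
class ExperimentResult:
    config: RunConfig
    arms: dict[str, ArmResult]
    comparison: ComparisonResult | None = None

    def summaries(self) -> list[ReportingSummary]:
        return [arm.summary for arm in self.arms.values()]


def build_panel(
    config: RunConfig, suspense_rng
) -> list[HospitalProfile]:
    """Materialize the hospital panel for one replicate.

    Facilities without a pinned suspense wait draw their constant wait from
    the panel-wide policy; waits are re-drawn each replicate so that the
    between-facility variation is itself resampled.
    """
    panel = []
    for spec in config.hospitals:
        wait = spec.suspense_wait
        if wait is None:
            wait = draw_suspense_wait(
                config.suspense_policy,
                suspense_rng,
                enforce_band=not config.allow_out_of_band_suspense,
            )
        panel.append(config.build_profile(spec, wait))
    return panel


def _workflow_config(config: RunConfig, variant: str, seed: int) -> WorkflowConfig:
    return WorkflowConfig(
        variant=variant,
        horizon=config.horizon_days,
        seed=seed,
        fallback_days=config.fallback_days,
        notification_enabled=config.notification_enabled,
        fallback_from=config.fallback_from,
        capacity_model=config.capacity_model,
        abstraction=config.abstraction,
        external_delay=config.external_delay,
        epath_review_period=config.epath_review_period,
    )


def run_experiment(
    config: RunConfig,
    variants: Sequence[str] = (EXISTING, REDESIGNED),
    *,
    collect_trace: bool = False,
) -> ExperimentResult:
    """Run the configured experiment for the requested variants."""
    for v in variants:
        if v not in (EXISTING, REDESIGNED):
            raise ValueError(f"unknown variant {v!r}")
    runs: dict[str, list[WorkflowResult]] = {v: [] for v in variants}

    for rep in range(config.replicates):
        streams = named_streams(config.seed, rep)
        panel = build_panel(config, streams["suspense"])
        cases: list[Case] = []
        for hospital in panel:
            cases.extend(
                generate_cases(
                    hospital,
                    config.horizon_days,
                    config.mixture,
                    p_pathology=config.p_pathology,
                    p_external=config.p_external,
                    p_no_treatment=config.p_no_treatment,
                    streams=streams,
                )
            )
        abstraction_by_case = {
            c.case_id: float(sample(config.abstraction, streams["abstraction"]))
            for c in cases
        }
        external_by_case = {
            c.case_id: float(sample(config.external_delay, streams["external"]))
            for c in cases
        }
        for variant in variants:
            wf = _workflow_config(config, variant, config.seed)
            runs[variant].append(
                simulate_workflow(
                    wf,
                    panel,
                    cases,
                    abstraction_by_case=abstraction_by_case,
                    external_by_case=external_by_case,
                    collect_trace=collect_trace,
                )
            )

    arms = {
        v: ArmResult(
            variant=v,
            replicates=runs[v],
            summary=summarize(
                [o for r in runs[v] for o in r.outcomes],
                variant=v,
                horizon=config.horizon_days,
            ),
        )
        for v in variants
    }
    comparison = None
    if EXISTING in arms and REDESIGNED in arms:
        comparison = compare(
            arms[EXISTING].outcomes_by_replicate,
            arms[REDESIGNED].outcomes_by_replicate,
        )
    return ExperimentResult(config=config, arms=arms, comparison=comparison)
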