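"""Brute-force fixed-step reference simulator.

An independent oracle for the event-driven engine: each case is marched
through the workflow with a fixed clock step (default 0.01 day).  Scan
boundaries, release conditions and batch boundaries are detected by
stepping and linear search over multiples rather than by an event calendar
or ceiling arithmetic, and the exact transition times crossed during a
step are recorded.  Only the unlimited-capacity model (cases independent)
is supported, which is the calibrated default the engine is checked
against.
"""

from __future__ import annotations


def _boundary_at_or_after(period: float, t: float) -> float:
    """Linear search: smallest multiple of ``period`` >= ``t``.

    The multiple is counted and multiplied out rather than accumulated, so
    repeated float addition cannot drift off the exact boundary value.
    """
    k = 0
    while k * period < t - 1e-12:
        k += 1
    return k * period


def fixed_step_timelines(
    variant: str,
    hospitals,
    cases,
    abstraction_by_case,
    external_by_case,
    config,
    dt: float = 0.01,
):
    """Per-case timelines computed by time-stepping; dict keyed by case_id."""
    hosp = {h.hospital_id: h for h in hospitals}
    horizon = config.horizon
    out = {}
    for case in cases:
        h = hosp[case.hospital_id]
        if case.source == "pathology":
            period = (
                h.pathology_scan_period
                if variant == "existing"
                else config.epath_review_period
            )
        else:
            period = h.index_scan_period

        identified = released = done = submitted = None
        n_steps = int(round(horizon / dt))
        step = 0
        while step <= n_steps:
            t = step * dt  # indexed, not accumulated: no drift at the horizon
            if identified is None:
                b = _boundary_at_or_after(period, case.t_diagnosis)
                if b <= t and b <= horizon:
                    identified = b
            if identified is not None and released is None:
                if variant == "existing":
                    r = identified + h.suspense_wait
                else:
                    anchor = (
                        case.t_diagnosis
                        if config.fallback_from == "diagnosis"
                        else identified
                    )
                    timeout = anchor + config.fallback_days
                    treat = case.t_treatment_complete
                    if (
                        config.notification_enabled
                        and treat is not None
                        and treat <= timeout
                    ):
                        r = max(identified, treat)
                    else:
                        r = max(identified, timeout)
                if r <= t:
                    released = r
            if released is not None and done is None:
                service = abstraction_by_case[case.case_id]
                if variant == "existing" and case.needs_external:
                    service += external_by_case[case.case_id]
                d = released + service
                if d <= t:
                    done = d
            if done is not None and submitted is None:
                b = _boundary_at_or_after(h.submission_interval, done)
                if b <= t and b <= horizon:
                    submitted = b
                    break
            step += 1
        out[case.case_id] = {
            "t_identified": identified,
            "t_released": released,
            "t_abstract_done": done,
            "t_submitted": submitted,
        }
    return out
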