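import dataclasses

import numpy as np
import pytest

from registrysim import (
    MONTH_DAYS,
    WorkflowConfig,
    identification_time,
    next_submission_time,
    release_time_existing,
    release_time_redesigned,
    simulate_workflow,
    submission_interval,
)
from registrysim.casegen import Case, ConfigurationError, generate_cases
from registrysim.rng import named_streams
from registrysim.workflows import EXISTING, REDESIGNED

from fixedstep import fixed_step_timelines


def _case(t, source="pathology", treat=None, hid="H01", cid="H01-00000",
          cancer="breast", external=False):
    return Case(
        case_id=cid, hospital_id=hid, cancer_type=cancer, t_diagnosis=t,
        source=source, needs_external=external, t_treatment_complete=treat,
    )


def _wf(variant, horizon=365.0, **kw):
    return WorkflowConfig(variant=variant, horizon=horizon, seed=3, **kw)


# --- submission policy -----------------------------------------------------

@pytest.mark.parametrize(
    "caseload, interval",
    [
        (0, 365.0),
        (1, 365.0),
        (59, 365.0),
        (60, 365.0 / 4),
        (149, 365.0 / 4),
        (150, 365.0 / 6),
        (299, 365.0 / 6),
        (300, MONTH_DAYS),
        (350, MONTH_DAYS),
        (5000, MONTH_DAYS),
    ],
)
def test_submission_interval_tiers(caseload, interval):
    assert submission_interval(caseload) == pytest.approx(interval)


def test_negative_caseload_rejected():
    with pytest.raises(ConfigurationError):
        submission_interval(-1)


def test_next_submission_time_boundaries():
    assert next_submission_time(MONTH_DAYS, 37.0) == pytest.approx(2 * MONTH_DAYS)
    assert next_submission_time(MONTH_DAYS, 0.0) == 0.0
    boundary = 3 * MONTH_DAYS
    assert next_submission_time(MONTH_DAYS, boundary) == pytest.approx(boundary)


def test_monthly_tier_mean_residence_is_half_an_interval(rng):
    """Uniform completions wait interval/2 ~ 15 days on the monthly tier."""
    done = rng.uniform(0.0, MONTH_DAYS, 200_000)
    residence = np.array([next_submission_time(MONTH_DAYS, t) - t for t in done])
    assert residence.mean() == pytest.approx(MONTH_DAYS / 2, abs=0.1)


# --- identification --------------------------------------------------------

def test_identification_boundaries(hospital):
    path = _case(3.2)
    assert identification_time(path, hospital, EXISTING) == pytest.approx(4.0)
    assert identification_time(path, hospital, REDESIGNED) == pytest.approx(4.0)
    index = _case(3.2, source="disease_index")
    assert identification_time(index, hospital, EXISTING) == pytest.approx(MONTH_DAYS)
    on_boundary = _case(7.0)
    assert identification_time(on_boundary, hospital, EXISTING) == pytest.approx(7.0)


def test_weekly_pathology_scans_supported(hospital):
    weekly = dataclasses.replace(hospital, pathology_scan_period=7.0)
    assert identification_time(_case(3.2), weekly, EXISTING) == pytest.approx(7.0)


# --- release rules ---------------------------------------------------------

def test_release_existing_is_fixed_offset(hospital):
    assert release_time_existing(10.0, hospital) == pytest.approx(130.0)
    low = dataclasses.replace(hospital, suspense_wait=90.0)
    assert release_time_existing(8.0, low) == pytest.approx(98.0)
    # fixed offset preserves FIFO order
    assert release_time_existing(5.0, hospital) < release_time_existing(8.0, hospital)


def test_release_redesigned_notification_and_fallback():
    cfg = _wf(REDESIGNED)
    assert release_time_redesigned(5.0, _case(0.0, treat=40.0), cfg) == 40.0
    # no treatment: released at diagnosis + fallback
    assert release_time_redesigned(5.0, _case(0.0), cfg) == 180.0
    # treatment after the fallback window: fallback dominates
    late = _case(0.0, treat=300.0)
    assert release_time_redesigned(5.0, late, cfg) == 180.0
    # treatment before identification: released at identification
    early = _case(0.0, treat=2.0)
    assert release_time_redesigned(5.0, early, cfg) == 5.0
    # release never exceeds diagnosis + fallback
    for treat in (None, 20.0, 100.0, 400.0):
        c = _case(0.0, treat=treat)
        assert release_time_redesigned(5.0, c, cfg) <= 180.0


# --- end-to-end ------------------------------------------------------------

def test_hand_traced_existing_case(hospital):
    cfg = _wf(EXISTING)
    case = _case(3.2)
    res = simulate_workflow(
        cfg, [hospital], [case],
        abstraction_by_case={case.case_id: 0.05},
        external_by_case={case.case_id: 0.0},
    )
    (o,) = res.outcomes
    assert o.t_identified == pytest.approx(4.0)
    assert o.t_released == pytest.approx(124.0)
    assert o.t_abstract_done == pytest.approx(124.05)
    # first monthly batch boundary at or after 124.05 is 5 * 365/12
    assert o.t_submitted == pytest.approx(5 * MONTH_DAYS)
    assert o.reporting_time == pytest.approx(5 * MONTH_DAYS - 3.2)


def test_abstract_completed_on_boundary_ships_on_that_boundary(hospital):
    cfg = _wf(EXISTING)
    # identified day 1, suspense 120, duration chosen to land exactly on
    # the fifth monthly boundary
    done = 5 * MONTH_DAYS
    case = _case(1.0)
    res = simulate_workflow(
        cfg, [hospital], [case],
        abstraction_by_case={case.case_id: done - 121.0},
        external_by_case={case.case_id: 0.0},
    )
    assert res.outcomes[0].t_submitted == pytest.approx(done)


def test_redesigned_worst_case_bound(mixture, hospital):
    """With treatment waits <= 63 d every reporting time is bounded by
    63 + identification + abstraction + one batch interval."""
    cases = generate_cases(hospital, 365.0, mixture, streams=named_streams(9, 0))
    res = simulate_workflow(_wf(REDESIGNED), [hospital], cases)
    bound = 63.0 + MONTH_DAYS + MONTH_DAYS + 1.0
    assert res.reporting_times.max() < bound


def test_tiny_horizon_yields_no_outcomes(mixture, hospital):
    cases = generate_cases(hospital, 365.0, mixture, streams=named_streams(9, 0))
    res = simulate_workflow(_wf(EXISTING, horizon=0.5), [hospital], cases[:3])
    assert res.outcomes == []
    assert len(res.in_flight) == 3


def test_monotone_timelines_and_conservation(mixture, hospital, small_hospital):
    panel = [hospital, small_hospital]
    cases = []
    for h in panel:
        cases.extend(
            generate_cases(h, 365.0, mixture, streams=named_streams(17, 0))
        )
    for variant in (EXISTING, REDESIGNED):
        res = simulate_workflow(_wf(variant), panel, cases)
        ids = {o.case_id for o in res.outcomes}
        assert ids.isdisjoint(res.in_flight)
        assert len(ids) + len(res.in_flight) == len(cases)
        for o in res.outcomes:
            assert (
                o.t_diagnosis <= o.t_identified <= o.t_released
                <= o.t_abstract_done <= o.t_submitted
            )
            assert o.reporting_time >= 0
        # submissions on exact tier boundaries
        by_hospital = {h.hospital_id: h for h in panel}
        for o in res.outcomes:
            interval = by_hospital[o.hospital_id].submission_interval
            assert o.t_submitted / interval == pytest.approx(
                round(o.t_submitted / interval), abs=1e-9
            )


def test_redesigned_release_never_later_than_existing(mixture, hospital):
    """Dominance whenever treatment completes within the fixed wait."""
    cases = generate_cases(hospital, 365.0, mixture, streams=named_streams(23, 0))
    ex = simulate_workflow(_wf(EXISTING), [hospital], cases)
    re = simulate_workflow(_wf(REDESIGNED), [hospital], cases)
    ex_rel = {o.case_id: o.t_released for o in ex.outcomes}
    re_rel = {o.case_id: o.t_released for o in re.outcomes}
    by_id = {c.case_id: c for c in cases}
    checked = 0
    for cid in set(ex_rel) & set(re_rel):
        c = by_id[cid]
        ex_id = [o for o in ex.outcomes if o.case_id == cid][0].t_identified
        if (
            c.t_treatment_complete is not None
            and c.t_treatment_complete <= ex_id + hospital.suspense_wait
        ):
            assert re_rel[cid] <= ex_rel[cid] + 1e-9
            checked += 1
    assert checked > 100
    assert re.reporting_times.mean() < ex.reporting_times.mean()


def test_disabled_notification_reduces_to_existing(mixture, hospital):
    """With the notification off and the fallback clock anchored at
    identification with the facility's suspense wait, the redesigned model
    releases exactly like the existing one."""
    cases = generate_cases(hospital, 365.0, mixture, streams=named_streams(31, 0))
    ex = simulate_workflow(_wf(EXISTING), [hospital], cases)
    red = simulate_workflow(
        _wf(
            REDESIGNED,
            notification_enabled=False,
            fallback_days=hospital.suspense_wait,
            fallback_from="identification",
        ),
        [hospital],
        cases,
    )
    ex_rel = {o.case_id: o.t_released for o in ex.outcomes}
    re_rel = {o.case_id: o.t_released for o in red.outcomes}
    assert ex_rel.keys() == re_rel.keys()
    for cid, t in ex_rel.items():
        assert re_rel[cid] == pytest.approx(t, abs=1e-9)


def test_trace_hash_determinism(mixture, hospital):
    cases = generate_cases(hospital, 365.0, mixture, streams=named_streams(37, 0))
    kw = dict(
        abstraction_by_case={c.case_id: 0.05 for c in cases},
        external_by_case={c.case_id: 0.0 for c in cases},
        collect_trace=True,
    )
    a = simulate_workflow(_wf(EXISTING), [hospital], cases, **kw)
    b = simulate_workflow(_wf(EXISTING), [hospital], cases, **kw)
    c = simulate_workflow(_wf(REDESIGNED), [hospital], cases, **kw)
    assert a.trace_hash == b.trace_hash
    assert a.trace_hash != c.trace_hash


@pytest.mark.parametrize("variant", [EXISTING, REDESIGNED])
def test_engine_agrees_with_fixed_step_oracle(mixture, hospital, small_hospital,
                                              variant):
    """<=50-case scenario: per-case timelines match a brute-force
    0.01-day time-stepping simulator."""
    panel = [hospital, small_hospital]
    rng = np.random.default_rng(41)
    cases = []
    streams = named_streams(41, 0)
    for h in panel:
        small = dataclasses.replace(h, annual_caseload=25)
        cases.extend(generate_cases(small, 300.0, mixture, streams=streams))
    assert 0 < len(cases) <= 50
    abstraction = {c.case_id: float(rng.uniform(0.03, 0.07)) for c in cases}
    external = {c.case_id: float(rng.uniform(0.0, 2.0)) for c in cases}
    cfg = _wf(variant)
    res = simulate_workflow(
        cfg, panel, cases,
        abstraction_by_case=abstraction, external_by_case=external,
    )
    oracle = fixed_step_timelines(
        variant, panel, cases, abstraction, external, cfg, dt=0.01
    )
    submitted_engine = {o.case_id for o in res.outcomes}
    submitted_oracle = {
        cid for cid, t in oracle.items() if t["t_submitted"] is not None
    }
    assert submitted_engine == submitted_oracle
    for o in res.outcomes:
        ref = oracle[o.case_id]
        for key in ("t_identified", "t_released", "t_abstract_done", "t_submitted"):
            assert getattr(o, key) == pytest.approx(ref[key], abs=0.01)


def test_single_registrar_mode_serializes_abstraction(mixture, hospital):
    cases = generate_cases(hospital, 120.0, mixture, streams=named_streams(43, 0))
    dur = {c.case_id: 0.05 for c in cases}
    res = simulate_workflow(
        _wf(EXISTING, capacity_model="single_registrar"), [hospital], cases,
        abstraction_by_case=dur,
        external_by_case={c.case_id: 0.0 for c in cases},
    )
    assert res.outcomes
    # service stretched to wall clock by 24/8; windows must not overlap
    windows = sorted(
        (o.t_abstract_done - 0.05 * 3.0, o.t_abstract_done) for o in res.outcomes
    )
    for (s1, e1), (s2, e2) in zip(windows, windows[1:]):
        assert s2 >= e1 - 1e-9
        assert s1 <= e1


def test_invalid_workflow_config_rejected():
    with pytest.raises(ConfigurationError):
        WorkflowConfig(variant="hybrid", horizon=365.0)
    with pytest.raises(ConfigurationError):
        WorkflowConfig(variant=EXISTING, horizon=-1.0)
    with pytest.raises(ConfigurationError):
        WorkflowConfig(variant=REDESIGNED, horizon=365.0, fallback_days=0.0)
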