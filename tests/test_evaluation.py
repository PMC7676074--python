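"""Independent feasibility checking and schedule metrics."""

import pytest

from linacbook import (
    Instance,
    Linac,
    PlannerParams,
    Schedule,
    Session,
    check_feasibility,
    compute_metrics,
)

from conftest import make_patient

PARAMS = PlannerParams(horizon_days=5, slots_per_day=120, slot_minutes=5)


def _instance(patients, n_linacs=1):
    linacs = tuple(Linac(f"L{j + 1}") for j in range(n_linacs))
    return Instance(patients=tuple(patients), linacs=linacs, params=PARAMS)


def _codes(violations):
    return {v.code for v in violations}


def test_clean_daily_course_passes():
    p = make_patient(remaining_sessions=3, duration_slots=3)
    sched = Schedule(tuple(Session("p1", "L1", d, 1) for d in (1, 2, 3)))
    assert check_feasibility(sched, _instance([p])) == []


def test_overlapping_footprints_are_flagged():
    pats = [
        make_patient("a", duration_slots=2),
        make_patient("b", duration_slots=2),
    ]
    sched = Schedule((Session("a", "L1", 1, 3), Session("b", "L1", 1, 4)))
    assert "overlap" in _codes(check_feasibility(sched, _instance(pats)))


def test_sessions_on_different_linacs_are_flagged():
    p = make_patient(remaining_sessions=2, feasible_linacs=("L1", "L2"))
    sched = Schedule((Session("p1", "L1", 1, 1), Session("p1", "L2", 2, 1)))
    assert "same-linac" in _codes(check_feasibility(sched, _instance([p], n_linacs=2)))


def test_missed_due_date_and_missing_continuation_are_flagged():
    p = make_patient(remaining_sessions=2, due_day=1)
    late = Schedule((Session("p1", "L1", 2, 1), Session("p1", "L1", 3, 1)))
    assert "due-date" in _codes(check_feasibility(late, _instance([p])))
    gap = Schedule((Session("p1", "L1", 1, 1),))
    assert "continuity" in _codes(check_feasibility(gap, _instance([p])))


def test_spacing_rhythm_violation_is_flagged():
    p = make_patient(remaining_sessions=2, spacing_days=2)
    sched = Schedule((Session("p1", "L1", 1, 1), Session("p1", "L1", 2, 1),
                      Session("p1", "L1", 3, 1)))
    assert "spacing" in _codes(check_feasibility(sched, _instance([p])))


def test_new_start_cap_counts_first_days():
    params = PlannerParams(horizon_days=5, slots_per_day=120, slot_minutes=5,
                           max_new_starts=1)
    pats = [make_patient("a"), make_patient("b")]
    inst = Instance(patients=tuple(pats), linacs=(Linac("L1"),), params=params)
    sched = Schedule((Session("a", "L1", 1, 1), Session("b", "L1", 1, 2)))
    assert "new-start-cap" in _codes(check_feasibility(sched, inst))


def test_blocked_start_slot_is_flagged():
    p = make_patient()
    inst = Instance(
        patients=(p,),
        linacs=(Linac("L1", unavailable=frozenset({(1, 1)})),),
        params=PARAMS,
    )
    sched = Schedule((Session("p1", "L1", 1, 1),))
    assert "availability" in _codes(check_feasibility(sched, inst))


def test_restricted_frame_start_is_flagged():
    p = make_patient(restricted_frame=True)
    params = PlannerParams(horizon_days=5, slots_per_day=120, slot_minutes=5,
                           frame_lo=60, frame_hi=570)
    inst = Instance(patients=(p,), linacs=(Linac("L1"),), params=params)
    sched = Schedule((Session("p1", "L1", 1, 1),))  # slot 1 < frame slot 13
    assert "frame" in _codes(check_feasibility(sched, inst))


def test_metrics_utilization_and_deviation():
    """A 2055-min workload on a 3000-min linac runs at 68.5% utilization."""
    # 137 sessions of 15 min each on one linac: 5 slots per day is too few,
    # so spread patients over days; use duration 3 slots (15 min).
    pats = [
        make_patient(f"p{i}", remaining_sessions=5, duration_slots=3,
                     window_lo=0, window_hi=595)
        for i in range(1, 28)  # 27 patients x 5 days = 135 sessions
    ] + [
        make_patient("p28", remaining_sessions=2, duration_slots=3,
                     window_lo=0, window_hi=595)
    ]
    inst = _instance(pats)
    sessions = []
    for i in range(27):
        for d in range(1, 6):
            sessions.append(Session(f"p{i + 1}", "L1", d, 1 + 3 * i))
    sessions += [Session("p28", "L1", d, 1 + 3 * 27) for d in (1, 2)]
    sched = Schedule(tuple(sessions))
    m = compute_metrics(sched, inst)
    assert m.sessions_scheduled == 137
    assert m.per_linac_workload_min["L1"] == 2055
    assert m.per_linac_utilization["L1"] == pytest.approx(0.685)
    assert m.cumulative_deviation_min == 0.0
    assert m.sessions_outside_window == 0
    assert m.avg_deviation_outside_min == 0.0
    assert m.per_linac_patients["L1"] == 28


def test_boundary_starts_count_as_inside_the_window():
    p = make_patient(window_lo=90, window_hi=510)
    inst = _instance([p])
    on_bound = Schedule((Session("p1", "L1", 1, 19),))  # start minute 90
    m = compute_metrics(on_bound, inst)
    assert m.sessions_outside_window == 0


def test_empty_schedule_reports_not_applicable_fractions():
    m = compute_metrics(Schedule(()), _instance([make_patient()]))
    assert m.sessions_scheduled == 0
    assert m.fraction_outside_window is None
    assert m.avg_deviation_outside_min is None
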