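"""Model construction, deviation linking, and small exact solves."""

import numpy as np
import pytest
from dataclasses import replace

from linacbook import (
    Instance,
    Linac,
    PlannerParams,
    build_milp,
    brute_force_optimal,
    check_feasibility,
    compute_metrics,
    extract_schedule,
    min_deviation,
    solve_milp,
)
from linacbook.errors import BuildRefusedError

from conftest import make_patient, random_tiny_instance


@pytest.mark.parametrize(
    "s, l, window, expected",
    [
        (1, 5, (0, 90), (0, 0)),
        (25, 5, (0, 90), (0, 30)),
        (10, 5, (90, 510), (45, 0)),
        (19, 5, (90, 510), (0, 0)),  # start exactly at the lower bound
        (103, 5, (90, 510), (0, 0)),  # start exactly at the upper bound
    ],
)
def test_min_deviation(s, l, window, expected):
    assert min_deviation(s, l, window) == expected


def _one_patient_instance(**patient_kw):
    params = PlannerParams(horizon_days=5, slots_per_day=4, slot_minutes=5,
                           frame_lo=0, frame_hi=20)
    return Instance(
        patients=(make_patient(window_hi=15, **patient_kw),),
        linacs=(Linac("L1"),),
        params=params,
    )


def test_variable_grid_spans_patients_linacs_slots_days():
    model = build_milp(_one_patient_instance())
    assert model.n_x == 1 * 1 * 4 * 5


def test_multi_slot_sessions_cannot_start_at_day_end():
    model = build_milp(_one_patient_instance(duration_slots=2))
    for t in range(1, 6):
        assert model.is_fixed_zero(model.x_index(0, 0, 4, t))
        assert not model.is_fixed_zero(model.x_index(0, 0, 3, t))


def test_restricted_frame_fixes_starts_outside_frame():
    params = PlannerParams(horizon_days=5, slots_per_day=120, slot_minutes=5,
                           frame_lo=60, frame_hi=570)
    inst = Instance(
        patients=(make_patient(restricted_frame=True),),
        linacs=(Linac("L1"),),
        params=params,
    )
    model = build_milp(inst)  # frame slots are (13, 115)
    for s in (1, 12, 116, 120):
        assert model.is_fixed_zero(model.x_index(0, 0, s, 1))
    for s in (13, 115):
        assert not model.is_fixed_zero(model.x_index(0, 0, s, 1))


def test_build_refuses_invalid_instance():
    inst = _one_patient_instance(due_day=9)
    with pytest.raises(BuildRefusedError):
        build_milp(inst)


def test_every_family_present_on_a_full_featured_instance():
    inst = Instance(
        patients=(
            make_patient(remaining_sessions=3, duration_slots=2,
                         feasible_linacs=("L1", "L2"), window_lo=0, window_hi=10),
            make_patient("p2", is_new=False, current_linac="L1", spacing_days=2,
                         remaining_sessions=2, restricted_frame=True,
                         window_lo=10, window_hi=30),
        ),
        linacs=(Linac("L1", unavailable=frozenset({(1, 1)})), Linac("L2")),
        params=PlannerParams(horizon_days=5, slots_per_day=8, slot_minutes=5,
                             frame_lo=5, frame_hi=30),
    )
    counts = build_milp(inst).family_counts()
    for fam in ("eq2", "eq3", "eq4", "eq5", "eq6", "eq7", "eq8", "eq8_fixed", "eq9",
                "eq10", "eq11", "eq12", "eq13", "eq14", "eq15", "eq16", "delta_cap"):
        assert counts.get(fam, 0) > 0, fam


def test_single_patient_with_wide_window_solves_to_zero():
    inst = _one_patient_instance()
    model = build_milp(inst)
    report, values = solve_milp(model, time_limit_s=30)
    assert report.status == "optimal"
    assert report.objective == pytest.approx(0.0, abs=1e-9)
    schedule = extract_schedule(model, values)
    assert len(schedule.sessions) == 1
    assert check_feasibility(schedule, inst) == []


def test_capacity_shortfall_is_infeasible():
    params = PlannerParams(horizon_days=1, slots_per_day=1, slot_minutes=5,
                           frame_lo=0, frame_hi=5)
    inst = Instance(
        patients=(
            make_patient(window_hi=0),
            make_patient("p2", window_hi=0),
        ),
        linacs=(Linac("L1"),),
        params=params,
    )
    report, _ = solve_milp(build_milp(inst), time_limit_s=30)
    assert report.status == "infeasible"


def test_objective_equals_recomputed_session_deviations():
    """At any optimum the objective is the sum of per-session minimal deviations."""
    for seed in (3, 11, 27):
        inst = random_tiny_instance(seed)
        model = build_milp(inst)
        report, values = solve_milp(model, time_limit_s=30)
        if report.status != "optimal":
            continue
        schedule = extract_schedule(model, values)
        recomputed = compute_metrics(schedule, inst).cumulative_deviation_min
        assert recomputed == pytest.approx(report.objective, abs=1e-6)


def test_widening_a_window_never_increases_the_optimum():
    checked = 0
    for seed in range(20):
        inst = random_tiny_instance(seed)
        base = brute_force_optimal(inst)
        if base is None:
            continue
        p0 = inst.patients[0]
        widened = replace(
            p0,
            window_lo=max(0, p0.window_lo - 10),
            window_hi=min(inst.params.day_span_minutes, p0.window_hi + 10),
        )
        wider = inst.replace_patients((widened,) + inst.patients[1:])
        report, _ = solve_milp(build_milp(wider), time_limit_s=30)
        assert report.status == "optimal"
        assert report.objective <= base + 1e-9
        checked += 1
    assert checked >= 5


def test_full_day_windows_make_any_feasible_instance_costless():
    for seed in range(12):
        inst = random_tiny_instance(seed)
        span = inst.params.slot_minutes * (inst.params.slots_per_day - 1)
        relaxed = inst.replace_patients(
            replace(p, window_lo=0, window_hi=span) for p in inst.patients
        )
        report, _ = solve_milp(build_milp(relaxed), time_limit_s=30)
        if report.status == "optimal":
            assert report.objective == pytest.approx(0.0, abs=1e-9)
        else:
            assert report.status == "infeasible"


def test_lp_export_lists_objective_and_families(tmp_path):
    model = build_milp(_one_patient_instance())
    path = tmp_path / "model.lp"
    model.to_lp(str(path))
    text = path.read_text()
    assert text.startswith("Minimize")
    assert "eq7" in text and "Binaries" in text
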