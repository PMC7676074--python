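"""Greedy balancing heuristic, workload bookkeeping and linac clustering."""

import pytest

from linacbook import (
    ClusterSpec,
    Instance,
    Linac,
    PlannerParams,
    default_nki_config,
    generate_instance,
    initial_workloads,
    partition_clusters,
    patient_volume,
    preassign,
    single_linac_clusters,
)
from linacbook.errors import ClusterSpecError, PreassignmentInfeasibleError

from conftest import make_patient

PARAMS = PlannerParams()  # 5 days x 120 slots x 5 min


@pytest.mark.parametrize(
    "sessions, spacing, duration_slots, expected",
    [
        (5, 1, 3, 75),   # 5 daily 15-min sessions
        (10, 2, 3, 45),  # every other day: days 1,3,5
        (2, 1, 2, 20),   # truncation at the session count
        (35, 1, 3, 75),  # horizon truncation at 5 days
    ],
)
def test_patient_volume(sessions, spacing, duration_slots, expected):
    p = make_patient(remaining_sessions=sessions, spacing_days=spacing,
                     duration_slots=duration_slots)
    assert patient_volume(p, PARAMS) == expected


def _instance(patients, n_linacs=2, satellite=()):
    linacs = tuple(
        Linac(f"L{j + 1}", location="satellite" if f"L{j + 1}" in satellite else "main")
        for j in range(n_linacs)
    )
    return Instance(patients=tuple(patients), linacs=linacs, params=PARAMS)


def all_linacs(n):
    return tuple(f"L{j + 1}" for j in range(n))


def test_initial_workloads_sum_ongoing_volumes():
    pats = [
        make_patient("a", is_new=False, current_linac="L2",
                     feasible_linacs=all_linacs(2), remaining_sessions=5, duration_slots=3),
        make_patient("b", is_new=False, current_linac="L2",
                     feasible_linacs=all_linacs(2), remaining_sessions=2, duration_slots=2),
        make_patient("c", feasible_linacs=all_linacs(2)),
    ]
    assert initial_workloads(_instance(pats)) == {"L1": 0.0, "L2": 95.0}
    assert initial_workloads(_instance([make_patient("c", feasible_linacs=all_linacs(2))])) == {
        "L1": 0.0, "L2": 0.0,
    }


def test_identical_patients_spread_over_empty_identical_linacs():
    pats = [
        make_patient("a", feasible_linacs=all_linacs(2), remaining_sessions=5, duration_slots=3),
        make_patient("b", feasible_linacs=all_linacs(2), remaining_sessions=5, duration_slots=3),
    ]
    pa = preassign(_instance(pats))
    assert sorted(pa.assignment.values()) == ["L1", "L2"]
    assert pa.workloads == {"L1": 75.0, "L2": 75.0}


def test_new_patient_goes_to_least_loaded_linac():
    pats = [
        make_patient("busy", is_new=False, current_linac="L1",
                     feasible_linacs=all_linacs(2), remaining_sessions=5, duration_slots=4),
        make_patient("next", feasible_linacs=all_linacs(2), remaining_sessions=5,
                     duration_slots=2),
    ]
    pa = preassign(_instance(pats))
    assert pa.assignment["next"] == "L2"


def test_scan_skips_least_loaded_linac_without_residual_capacity():
    linacs = (Linac("L1", capacity_min=60), Linac("L2", capacity_min=3000))
    pats = [
        make_patient("big", feasible_linacs=all_linacs(2), remaining_sessions=5,
                     duration_slots=3),  # vol 75 > 60 on L1
    ]
    inst = Instance(patients=tuple(pats), linacs=linacs, params=PARAMS)
    pa = preassign(inst)
    assert pa.assignment["big"] == "L2"


def test_preassign_error_names_the_unplaceable_patient():
    linacs = (Linac("L1", capacity_min=10),)
    pats = [make_patient("stuck", remaining_sessions=5, duration_slots=3)]
    inst = Instance(patients=tuple(pats), linacs=linacs, params=PARAMS)
    with pytest.raises(PreassignmentInfeasibleError) as err:
        preassign(inst)
    assert "stuck" in str(err.value)


def test_preassign_is_deterministic():
    cfg = default_nki_config(n_patients=100, n_linacs=4, n_satellite=0, seed=5)
    inst = generate_instance(cfg)
    assert preassign(inst) == preassign(inst)


def test_greedy_balance_bound_with_equal_initial_loads():
    """From empty linacs, max-min workload never exceeds the largest volume."""
    cfg = default_nki_config(n_patients=120, n_linacs=4, n_satellite=0, seed=9,
                             new_patient_fraction=1.0)
    inst = generate_instance(cfg)
    pa = preassign(inst)
    volumes = [patient_volume(p, inst.params) for p in inst.patients]
    wl = list(pa.workloads.values())
    assert max(wl) - min(wl) <= max(volumes)


class TestPartition:
    def _nki_like(self, n_patients=40):
        cfg = default_nki_config(n_patients=n_patients, n_linacs=8, seed=2)
        return generate_instance(cfg)

    def test_eight_singleton_clusters(self):
        inst = self._nki_like()
        pa = preassign(inst)
        subs = partition_clusters(inst, pa, single_linac_clusters(inst))
        assert len(subs) == 8
        assert all(len(s.linacs) == 1 for s in subs)

    def test_four_pair_clusters_partition_the_patients(self):
        inst = self._nki_like()
        pa = preassign(inst)
        spec = ClusterSpec((("L1", "L3"), ("L2", "L6"), ("L4", "L5"), ("L7", "L8")))
        subs = partition_clusters(inst, pa, spec)
        assert [len(s.linacs) for s in subs] == [2, 2, 2, 2]
        ids = [p.id for s in subs for p in s.patients]
        assert sorted(ids) == sorted(p.id for p in inst.patients)
        for sub in subs:
            members = {k.id for k in sub.linacs}
            for p in sub.patients:
                assert set(p.feasible_linacs) <= members
                if not p.is_new:
                    assert p.feasible_linacs == (p.current_linac,)

    def test_mixing_satellite_and_main_is_rejected(self):
        inst = self._nki_like()
        pa = preassign(inst)
        spec = ClusterSpec((("L1", "L7"), ("L2", "L3", "L4", "L5", "L6"), ("L8",)))
        with pytest.raises(ClusterSpecError):
            partition_clusters(inst, pa, spec)

    def test_incomplete_partition_is_rejected(self):
        inst = self._nki_like()
        pa = preassign(inst)
        with pytest.raises(ClusterSpecError):
            partition_clusters(inst, pa, ClusterSpec((("L1",),)))
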