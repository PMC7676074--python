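"""Greedy workload-balancing pre-assignment and linac clustering.

The heuristic walks the new patients in input order and, for each, scans that
patient's feasible linacs in increasing order of current workload WL(k)
(ties broken by linac id), assigning the patient to the first linac whose
residual weekly capacity fits the patient's expected weekly volume vol(i).
Ongoing patients keep the linac they are treated on and seed the initial
workloads. Clustering then partitions the linacs into groups solved as
independent subproblems; within a cluster a new patient may still move to any
cluster linac that is feasible for them, while main and satellite locations
are never mixed (satellite placement is decided at referral).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .core import (
    Instance,
    Patient,
    PlannerParams,
    linac_weekly_capacity,
    required_session_days,
)
from .errors import ClusterSpecError, PreassignmentInfeasibleError

__all__ = [
    "PreAssignment",
    "ClusterSpec",
    "patient_volume",
    "initial_workloads",
    "preassign",
    "partition_clusters",
    "single_linac_clusters",
]


@dataclass(frozen=True)
class PreAssignment:
    """A patient-to-linac map with the resulting per-linac workloads (min)."""

    assignment: dict[str, str]
    workloads: dict[str, float]


@dataclass(frozen=True)
class ClusterSpec:
    """A partition of the linacs into independently solvable groups."""

    clusters: tuple[tuple[str, ...], ...]

    def validate(self, instance: Instance) -> None:
        ids = [k.id for k in instance.linacs]
        seen: set[str] = set()
        for group in self.clusters:
            locations = set()
            for kid in group:
                if kid not in ids:
                    raise ClusterSpecError(f"unknown linac {kid!r} in cluster spec")
                if kid in seen:
                    raise ClusterSpecError(f"linac {kid!r} appears in two clusters")
                seen.add(kid)
                locations.add(instance.linac_by_id(kid).location)
            if len(locations) > 1:
                raise ClusterSpecError(
                    f"cluster {group} mixes main and satellite locations"
                )
        missing = set(ids) - seen
        if missing:
            raise ClusterSpecError(f"linacs not covered by any cluster: {sorted(missing)}")


def single_linac_clusters(instance: Instance) -> ClusterSpec:
    """One cluster per linac (the fully decomposed regime)."""
    return ClusterSpec(tuple((k.id,) for k in instance.linacs))


def patient_volume(patient: Patient, params: PlannerParams) -> int:
    """Expected weekly session minutes vol(i): reachable sessions x duration.

    Counts the sessions a treatment started on day 1 can fit in the horizon
    given the spacing, times the session length in minutes.
    """
    days = required_session_days(
        1, patient.spacing_days, patient.remaining_sessions, params.horizon_days
    )
    return len(days) * patient.duration_slots * params.slot_minutes


def initial_workloads(instance: Instance) -> dict[str, float]:
    """WL(k) seeded by the volume of patients already treated on each linac."""
    wl = {k.id: 0.0 for k in instance.linacs}
    for p in instance.patients:
        if not p.is_new and p.current_linac is not None:
            wl[p.current_linac] += patient_volume(p, instance.params)
    return wl


def preassign(instance: Instance) -> PreAssignment:
    """Run the greedy balancing pass over the new patients in input order."""
    wl = initial_workloads(instance)
    capacity = {k.id: float(linac_weekly_capacity(k, instance.params)) for k in instance.linacs}
    assignment: dict[str, str] = {
        p.id: p.current_linac
        for p in instance.patients
        if not p.is_new and p.current_linac is not None
    }
    for p in instance.patients:
        if not p.is_new:
            continue
        vol = patient_volume(p, instance.params)
        chosen = None
        for kid in sorted(p.feasible_linacs, key=lambda kid: (wl[kid], kid)):
            if wl[kid] + vol <= capacity[kid]:
                chosen = kid
                break
        if chosen is None:
            raise PreassignmentInfeasibleError(p.id)
        assignment[p.id] = chosen
        wl[chosen] += vol
    return PreAssignment(assignment=assignment, workloads=wl)


def partition_clusters(
    instance: Instance, preassignment: PreAssignment, spec: ClusterSpec
) -> list[Instance]:
    """Split an instance into one subinstance per cluster.

    Each subinstance keeps the cluster's linacs and the patients pre-assigned
    to them. New patients may use any feasible linac of the cluster; ongoing
    patients stay pinned to their current linac.
    """
    spec.validate(instance)
    for pid, kid in preassignment.assignment.items():
        instance.patient_by_id(pid)  # raises KeyError on stale assignment
        instance.linac_by_id(kid)
    unassigned = [p.id for p in instance.patients if p.id not in preassignment.assignment]
    if unassigned:
        raise ClusterSpecError(f"patients without a pre-assigned linac: {unassigned[:5]}")

    subinstances: list[Instance] = []
    for group in spec.clusters:
        members = set(group)
        linacs = tuple(k for k in instance.linacs if k.id in members)
        patients = []
        for p in instance.patients:
            if preassignment.assignment[p.id] not in members:
                continue
            if p.is_new:
                allowed = tuple(kid for kid in p.feasible_linacs if kid in members)
            else:
                allowed = (p.current_linac,)
            patients.append(replace(p, feasible_linacs=allowed))
        subinstances.append(Instance(patients=tuple(patients), linacs=linacs, params=instance.params))
    return subinstances
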