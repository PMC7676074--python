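"""End-to-end solving: pre-assignment, clustering, sequential MILP, merging.

``solve_sequential`` is the method's main entry point. With ``cluster_spec``
left ``None`` it builds and solves one MILP over the whole instance (the pure
exact regime that stays tractable up to roughly two linacs). With a cluster
spec it first runs the greedy pre-assignment, partitions the instance into
per-cluster subinstances, solves each cluster's MILP in sequence under a
shared time budget, and merges the schedules. Clusters that hit the time
limit or come back infeasible are reported without aborting the rest.

``brute_force_optimal`` is an exhaustive enumeration over tiny instances,
independent of the MILP code path, used as a testing oracle.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .core import Instance, Schedule, frame_to_slot_range, required_session_days
from .errors import OracleTooLargeError
from .evaluation import Metrics, compute_metrics
from .milp import SolveReport, build_milp, extract_schedule, min_deviation, solve_milp
from .preassign import ClusterSpec, PreAssignment, partition_clusters, preassign

__all__ = ["RunResult", "solve_sequential", "brute_force_optimal"]


@dataclass
class RunResult:
    """Merged outcome of a (possibly clustered) sequential run."""

    status: str  # "optimal" | "feasible" | "infeasible" | "time_limit"
    schedule: Schedule
    reports: list[SolveReport]
    objective: float | None
    metrics: Metrics | None
    preassignment: PreAssignment | None
    log: list[str] = field(default_factory=list)


def _merge_status(statuses: list[str]) -> str:
    if all(s == "optimal" for s in statuses):
        return "optimal"
    if all(s == "infeasible" for s in statuses):
        return "infeasible"
    if any(s in ("optimal", "feasible") for s in statuses):
        return "feasible"
    return "time_limit"


def solve_sequential(
    instance: Instance,
    cluster_spec: ClusterSpec | None = None,
    total_time_limit_s: float = 28800.0,
    gap_tol: float = 1e-4,
) -> RunResult:
    """Solve an instance, optionally decomposed into linac clusters.

    The total time budget is split evenly across clusters. The aggregate
    objective is the sum of cluster objectives (clusters share no patients or
    linacs, so the merge is exact for the restricted problem).
    """
    log: list[str] = []
    if cluster_spec is None:
        subinstances = [instance]
        pa = None
    else:
        pa = preassign(instance)
        subinstances = partition_clusters(instance, pa, cluster_spec)
        log.append(f"preassign: {len(pa.assignment)} patients over {len(pa.workloads)} linacs")

    per_cluster = total_time_limit_s / max(1, len(subinstances))
    reports: list[SolveReport] = []
    sessions: list = []
    deviations: dict = {}
    objective = 0.0
    have_objective = True
    for idx, sub in enumerate(subinstances):
        label = ",".join(k.id for k in sub.linacs)
        if not sub.patients:
            reports.append(SolveReport("optimal", 0.0, 0.0, 0.0))
            log.append(f"cluster {idx} [{label}]: empty, skipped")
            continue
        model = build_milp(sub)
        report, values = solve_milp(model, time_limit_s=per_cluster, gap_tol=gap_tol)
        reports.append(report)
        log.append(
            f"cluster {idx} [{label}]: status={report.status} "
            f"objective={report.objective} gap={report.gap} seconds={report.wall_time_s:.1f}"
        )
        if report.status in ("optimal", "feasible") and values is not None:
            part = extract_schedule(model, values)
            sessions.extend(part.sessions)
            deviations.update(part.deviations)
            objective += report.objective or 0.0
        else:
            have_objective = False

    status = _merge_status([r.status for r in reports]) if reports else "infeasible"
    schedule = Schedule(sessions=tuple(sessions), deviations=deviations)
    metrics = compute_metrics(schedule, instance) if sessions else None
    return RunResult(
        status=status,
        schedule=schedule,
        reports=reports,
        objective=objective if (have_objective and status != "infeasible") else None,
        metrics=metrics,
        preassignment=pa,
        log=log,
    )


def brute_force_optimal(instance: Instance, guard: int = 10_000_000) -> float | None:
    """Exhaustive minimal total deviation over all feasible schedules.

    Enumerates, per patient, every (linac, first day, per-day slot) choice
    that satisfies the assignment, spacing, due-date, frame, availability and
    day-end rules, then searches all combinations for the minimal objective
    with slot-footprint and new-start-cap checks. Returns the optimum in
    minutes or ``None`` if no feasible schedule exists. Raises
    :class:`OracleTooLargeError` above ``guard`` candidate combinations.
    Extra sessions beyond the required pattern never reduce the objective, so
    only minimal patterns are enumerated.
    """
    params = instance.params
    nT, nS, l = params.horizon_days, params.slots_per_day, params.slot_minutes
    lin_ids = [k.id for k in instance.linacs]

    frame_range = None
    if any(p.restricted_frame for p in instance.patients):
        frame_range = frame_to_slot_range(params.frame_lo, params.frame_hi, l, nS)

    def _placements(p):
        """Yield (linac idx, first day, days, per-day slot lists) for a patient."""
        allowed_linacs = (
            [p.current_linac] if (not p.is_new and p.current_linac) else list(p.feasible_linacs)
        )
        for kid in allowed_linacs:
            k = lin_ids.index(kid)
            lin = instance.linacs[k]
            for t0 in range(1, min(p.due_day, nT) + 1):
                days = required_session_days(t0, p.spacing_days, p.remaining_sessions, nT)
                slots_per_day = []
                ok = True
                for day in days:
                    slots = []
                    for s in range(1, nS - p.duration_slots + 2):
                        if not lin.is_available(s, day):
                            continue
                        if p.restricted_frame and not (
                            frame_range[0] <= s <= frame_range[1]
                        ):
                            continue
                        slots.append(s)
                    if not slots:
                        ok = False
                        break
                    slots_per_day.append(slots)
                if ok:
                    yield k, t0, days, slots_per_day

    # guard first, without materializing any slot combination
    space = 1
    for p in instance.patients:
        count = 0
        for _k, _t0, _days, slot_lists in _placements(p):
            n_combo = 1
            for slots in slot_lists:
                n_combo *= len(slots)
            count += n_combo
            if count > guard:
                raise OracleTooLargeError(f"search space exceeds {guard} candidates")
        space *= max(count, 1)
        if space > guard:
            raise OracleTooLargeError(f"search space exceeds {guard} candidates")

    # option = (linac index, start day, days, slots, footprint, deviation)
    per_patient: list[list[tuple]] = []
    for p in instance.patients:
        options = []
        for k, t0, days, slot_lists in _placements(p):
            for combo in itertools.product(*slot_lists):
                footprint = frozenset(
                    (k, day, slot)
                    for day, s in zip(days, combo)
                    for slot in range(s, s + p.duration_slots)
                )
                dev = sum(
                    sum(min_deviation(s, l, (p.window_lo, p.window_hi))) for s in combo
                )
                options.append((k, t0, days, combo, footprint, dev))
        if not options:
            return None
        options.sort(key=lambda o: o[-1])
        per_patient.append(options)

    cap = params.max_new_starts
    new_flags = [p.is_new for p in instance.patients]
    best: float | None = None

    def search(idx: int, used: set, starts: dict, acc: float) -> None:
        nonlocal best
        if best is not None and acc >= best:
            return
        if idx == len(per_patient):
            best = acc
            return
        for (k, t0, _days, _combo, footprint, dev) in per_patient[idx]:
            if best is not None and acc + dev >= best:
                break  # options sorted by deviation
            if used & footprint:
                continue
            key = (k, t0)
            if new_flags[idx] and starts.get(key, 0) + 1 > cap:
                continue
            if new_flags[idx]:
                starts[key] = starts.get(key, 0) + 1
            search(idx + 1, used | footprint, starts, acc + dev)
            if new_flags[idx]:
                starts[key] -= 1

    search(0, set(), {}, 0.0)
    return best
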