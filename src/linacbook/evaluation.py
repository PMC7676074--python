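"""Solver-independent feasibility checking and schedule quality metrics.

``check_feasibility`` re-implements the model's constraint families
declaratively so that any schedule extracted from a solve can be audited
without trusting the solver, and mirrors the model exactly: a schedule passes
here if and only if it corresponds to a feasible point of the built MILP.

``compute_metrics`` reports the quantities a planner reads off a weekly
schedule: sessions booked, sessions outside the preferred window (a start
exactly on a window bound counts as inside), cumulative and average deviation
minutes, and per-linac workload/utilization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import (
    Instance,
    Schedule,
    Violation,
    frame_to_slot_range,
    linac_weekly_capacity,
    required_session_days,
)
from .milp import min_deviation

__all__ = ["Metrics", "check_feasibility", "compute_metrics"]


@dataclass(frozen=True)
class Metrics:
    """Aggregate schedule quality figures."""

    sessions_scheduled: int
    sessions_outside_window: int
    fraction_outside_window: float | None  # None for an empty schedule
    cumulative_deviation_min: float
    avg_deviation_outside_min: float | None
    per_linac_workload_min: dict[str, float] = field(default_factory=dict)
    per_linac_utilization: dict[str, float] = field(default_factory=dict)
    per_linac_patients: dict[str, int] = field(default_factory=dict)

    @property
    def fraction_in_window(self) -> float | None:
        if self.fraction_outside_window is None:
            return None
        return 1.0 - self.fraction_outside_window


def check_feasibility(schedule: Schedule, instance: Instance) -> list[Violation]:
    """Audit a schedule against every constraint family; violations are data."""
    out: list[Violation] = []
    params = instance.params
    nT, nS = params.horizon_days, params.slots_per_day
    by_patient: dict[str, list] = {}
    occupancy: dict[tuple[str, int], dict[int, str]] = {}

    known_p = {p.id for p in instance.patients}
    known_k = {k.id for k in instance.linacs}
    for sess in schedule.sessions:
        if sess.patient not in known_p:
            out.append(Violation("unknown-patient", sess.patient, "session for unknown patient"))
            continue
        if sess.linac not in known_k:
            out.append(Violation("unknown-linac", sess.linac, "session on unknown linac"))
            continue
        by_patient.setdefault(sess.patient, []).append(sess)
    if out:
        return out

    frame_range = None
    if any(p.restricted_frame for p in instance.patients):
        frame_range = frame_to_slot_range(params.frame_lo, params.frame_hi, params.slot_minutes, nS)

    for p in instance.patients:
        sessions = sorted(by_patient.get(p.id, []), key=lambda s: s.day)
        days = [s.day for s in sessions]
        if len(set(days)) != len(days):
            out.append(Violation("one-per-day", p.id, "two sessions on the same day"))
            continue
        if not sessions:
            out.append(Violation("due-date", p.id, "no session booked (first due by "
                                 f"day {p.due_day})"))
            continue
        linacs_used = {s.linac for s in sessions}
        if len(linacs_used) > 1:
            out.append(Violation("same-linac", p.id, f"sessions on several linacs {sorted(linacs_used)}"))
        kid = sessions[0].linac
        if kid not in p.feasible_linacs or (not p.is_new and kid != p.current_linac):
            out.append(Violation("feasible-linac", p.id, f"booked on infeasible linac {kid!r}"))
        first = days[0]
        if first > min(p.due_day, nT):
            out.append(Violation("due-date", p.id, f"first session on day {first}, due {p.due_day}"))
        if len(days) > p.remaining_sessions:
            out.append(Violation("session-count", p.id, "more sessions than remaining"))
        # continuity: every day of the required pattern from the first session
        required = set(
            required_session_days(first, p.spacing_days, p.remaining_sessions, nT)
        )
        missing = required - set(days)
        if missing:
            out.append(Violation("continuity", p.id, f"missing sessions on days {sorted(missing)}"))
        # rest days for spaced schemes (the model constrains pairs with
        # t <= horizon - spacing; mirror that literally)
        if p.spacing_days >= 2:
            day_set = set(days)
            for t in range(1, nT - p.spacing_days + 1):
                if t in day_set:
                    for n in range(t + 1, t + p.spacing_days):
                        if n in day_set:
                            out.append(
                                Violation("spacing", p.id, f"sessions on days {t} and {n} "
                                          f"violate the {p.spacing_days}-day rhythm")
                            )
        for sess in sessions:
            if sess.start_slot < 1 or sess.start_slot + p.duration_slots - 1 > nS:
                out.append(Violation("day-end", p.id, f"session at slot {sess.start_slot} "
                                     "runs past the end of the day"))
                continue
            lin = instance.linac_by_id(sess.linac)
            if not lin.is_available(sess.start_slot, sess.day):
                out.append(Violation("availability", p.id,
                                     f"start slot {sess.start_slot} blocked on day {sess.day}"))
            if p.restricted_frame and frame_range is not None:
                lo, hi = frame_range
                if not lo <= sess.start_slot <= hi:
                    out.append(Violation("frame", p.id,
                                         f"start slot {sess.start_slot} outside frame slots [{lo}, {hi}]"))
            occ = occupancy.setdefault((sess.linac, sess.day), {})
            for slot in range(sess.start_slot, sess.start_slot + p.duration_slots):
                if slot in occ:
                    out.append(Violation("overlap", p.id,
                                         f"slot {slot} of {sess.linac} day {sess.day} already "
                                         f"used by {occ[slot]}"))
                else:
                    occ[slot] = p.id

    # new-start cap, counting starts the way the model's y variables do
    starts: dict[tuple[str, int], int] = {}
    for p in instance.patients:
        if not p.is_new:
            continue
        sessions = by_patient.get(p.id, [])
        if not sessions:
            continue
        day_set = {s.day for s in sessions}
        kid = sessions[0].linac
        for t in sorted(day_set):
            prev = max(1, t - p.spacing_days)
            if t == 1 or prev not in day_set:
                starts[(kid, t)] = starts.get((kid, t), 0) + 1
    for (kid, t), n in starts.items():
        if n > params.max_new_starts:
            out.append(Violation("new-start-cap", kid,
                                 f"{n} new patients start on day {t} (cap {params.max_new_starts})"))
    return out


def compute_metrics(schedule: Schedule, instance: Instance) -> Metrics:
    """Deviation and workload statistics of a schedule."""
    params = instance.params
    l = params.slot_minutes
    n = len(schedule.sessions)
    outside = 0
    total_dev = 0.0
    workload: dict[str, float] = {k.id: 0.0 for k in instance.linacs}
    patients_on: dict[str, set[str]] = {k.id: set() for k in instance.linacs}
    for sess in schedule.sessions:
        p = instance.patient_by_id(sess.patient)
        dm, dp = min_deviation(sess.start_slot, l, (p.window_lo, p.window_hi))
        dev = dm + dp
        total_dev += dev
        if dev > 0:
            outside += 1
        workload[sess.linac] += p.duration_slots * l
        patients_on[sess.linac].add(sess.patient)
    utilization = {
        kid: workload[kid] / linac_weekly_capacity(instance.linac_by_id(kid), params)
        for kid in workload
    }
    return Metrics(
        sessions_scheduled=n,
        sessions_outside_window=outside,
        fraction_outside_window=(outside / n) if n else None,
        cumulative_deviation_min=total_dev,
        avg_deviation_outside_min=(total_dev / outside) if outside else (0.0 if n else None),
        per_linac_workload_min=workload,
        per_linac_utilization=utilization,
        per_linac_patients={kid: len(v) for kid, v in patients_on.items()},
    )
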