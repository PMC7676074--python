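"""Domain model for weekly radiotherapy session scheduling.

A scheduling instance consists of patients (each with a number of remaining
irradiation sessions, a session duration, a daily/spaced rhythm, a waiting-time
due day and a preferred starting-time window), linacs (machines with a slot
grid of availability), and planner parameters (horizon, slot size, restricted
time frame, new-start cap). Days and slots are 1-based throughout; a slot ``s``
of length ``l`` minutes starts ``l*(s-1)`` minutes after the day opens.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

from .errors import InfeasibleFrameError, InvalidSlotError

__all__ = [
    "PlannerParams",
    "Linac",
    "Patient",
    "Instance",
    "Session",
    "Schedule",
    "Violation",
    "slot_start_minutes",
    "frame_to_slot_range",
    "required_session_days",
    "validate_instance",
    "linac_weekly_capacity",
]


@dataclass(frozen=True)
class PlannerParams:
    """Department-level planning parameters.

    ``frame_lo``/``frame_hi`` are the restricted time frame (minutes from day
    opening) imposed on patients that need specialist presence; they apply to
    every day of the horizon. ``max_new_starts`` caps the number of patients
    starting treatment on the same linac and day.
    """

    horizon_days: int = 5
    slots_per_day: int = 120
    slot_minutes: int = 5
    max_new_starts: int = 6
    frame_lo: int = 60
    frame_hi: int = 570

    @property
    def day_span_minutes(self) -> int:
        """Daily opening span in minutes (slots_per_day * slot_minutes)."""
        return self.slots_per_day * self.slot_minutes


@dataclass(frozen=True)
class Linac:
    """A linear accelerator with a per-(day, slot) availability grid.

    ``unavailable`` holds blocked (day, slot) pairs; everything else is open.
    ``capacity_min`` overrides the derived weekly capacity when given.
    """

    id: str
    location: str = "main"  # "main" or "satellite"
    capacity_min: int | None = None
    unavailable: frozenset[tuple[int, int]] = frozenset()

    def is_available(self, slot: int, day: int) -> bool:
        """Availability a_kst of a starting slot on a day (1-based)."""
        return (day, slot) not in self.unavailable


def linac_weekly_capacity(linac: Linac, params: PlannerParams) -> int:
    """Weekly capacity C_k in minutes: slot length times open slots."""
    if linac.capacity_min is not None:
        return linac.capacity_min
    blocked = sum(
        1
        for (day, slot) in linac.unavailable
        if 1 <= day <= params.horizon_days and 1 <= slot <= params.slots_per_day
    )
    return params.slot_minutes * (params.slots_per_day * params.horizon_days - blocked)


@dataclass(frozen=True)
class Patient:
    """A patient with remaining sessions to book this week.

    ``remaining_sessions`` (I_i) counts sessions still to deliver;
    ``due_day`` (d_i) is the latest first-session day; ``duration_slots``
    (p_i) is the per-session length in slots; ``spacing_days`` (b_i) is the
    gap between consecutive sessions (1 = daily). ``window_lo``/``window_hi``
    bound the preferred starting time in minutes from day opening.
    Ongoing patients (``is_new`` False) carry the linac they are treated on.
    """

    id: str
    care_plan: str
    is_new: bool
    remaining_sessions: int
    due_day: int
    duration_slots: int
    feasible_linacs: tuple[str, ...]
    spacing_days: int = 1
    window_lo: int = 0
    window_hi: int = 595
    current_linac: str | None = None
    must_start_monday: bool = False
    restricted_frame: bool = False
    urgent: bool = False


@dataclass(frozen=True)
class Instance:
    """A full scheduling instance: patients, linacs and planner parameters."""

    patients: tuple[Patient, ...]
    linacs: tuple[Linac, ...]
    params: PlannerParams = field(default_factory=PlannerParams)

    def linac_by_id(self, linac_id: str) -> Linac:
        for k in self.linacs:
            if k.id == linac_id:
                return k
        raise KeyError(linac_id)

    def patient_by_id(self, patient_id: str) -> Patient:
        for p in self.patients:
            if p.id == patient_id:
                return p
        raise KeyError(patient_id)

    def replace_patients(self, patients: Iterable[Patient]) -> "Instance":
        return replace(self, patients=tuple(patients))


@dataclass(frozen=True)
class Session:
    """One booked irradiation session (x_{iks}^t = 1)."""

    patient: str
    linac: str
    day: int
    start_slot: int


@dataclass(frozen=True)
class Schedule:
    """A set of booked sessions plus per-patient-day window deviations.

    ``deviations`` maps (patient id, day) to (under, over) minutes relative to
    the patient's preferred window; days without a session carry no entry
    (equivalently zero deviation).
    """

    sessions: tuple[Session, ...]
    deviations: dict[tuple[str, int], tuple[float, float]] = field(default_factory=dict)

    @property
    def total_deviation(self) -> float:
        return float(sum(lo + hi for lo, hi in self.deviations.values()))


@dataclass(frozen=True)
class Violation:
    """A single validation or feasibility violation (data, not an exception)."""

    code: str
    subject: str
    message: str


def slot_start_minutes(s: int, l: int) -> int:
    """Minutes from day opening at which 1-based slot ``s`` starts: l*(s-1)."""
    if s < 1:
        raise InvalidSlotError(f"slot index must be >= 1, got {s}")
    return l * (s - 1)


def frame_to_slot_range(frame_lo: int, frame_hi: int, l: int, n_slots: int) -> tuple[int, int]:
    """Slot range whose starts fall inside a minute frame [frame_lo, frame_hi].

    Returns (first, last): the smallest slot with start >= frame_lo and the
    largest slot with start <= frame_hi, capped at ``n_slots``. Raises
    :class:`InfeasibleFrameError` when no slot start lies in the frame.
    """
    if not (0 <= frame_lo <= frame_hi <= n_slots * l):
        raise InfeasibleFrameError(
            f"frame [{frame_lo}, {frame_hi}] outside day span [0, {n_slots * l}]"
        )
    first = -(-frame_lo // l) + 1  # ceil(frame_lo / l) + 1
    last = min(frame_hi // l + 1, n_slots)
    if first > last:
        raise InfeasibleFrameError(
            f"no slot start of a {l}-min grid lies within [{frame_lo}, {frame_hi}]"
        )
    return first, last


def required_session_days(
    start_day: int, spacing_days: int, n_sessions: int, horizon_days: int
) -> tuple[int, ...]:
    """Days a treatment started on ``start_day`` must occupy within the week.

    Sessions repeat every ``spacing_days`` from the start day until either the
    horizon or the patient's session count is exhausted:
    {t, t+b, t+2b, ...} truncated at min(horizon, t + b*(n_sessions-1)).
    """
    if not 1 <= start_day <= horizon_days:
        raise InvalidSlotError(f"start day {start_day} outside horizon 1..{horizon_days}")
    bound = min(horizon_days, start_day + spacing_days * (n_sessions - 1))
    return tuple(range(start_day, bound + 1, spacing_days))


def validate_instance(instance: Instance) -> list[Violation]:
    """Check every structural invariant of an instance; violations are data."""
    out: list[Violation] = []
    pr = instance.params
    if pr.horizon_days < 1 or pr.slots_per_day < 1 or pr.slot_minutes < 1:
        out.append(Violation("params", "params", "horizon, slots and slot length must be positive"))
        return out
    if pr.frame_lo > pr.frame_hi:
        out.append(Violation("params", "params", "frame_lo exceeds frame_hi"))
    if not 0 <= pr.frame_lo <= pr.day_span_minutes or pr.frame_hi > pr.day_span_minutes:
        out.append(Violation("params", "params", "restricted frame outside the day span"))

    linac_ids = [k.id for k in instance.linacs]
    if len(set(linac_ids)) != len(linac_ids):
        out.append(Violation("linacs", "linacs", "duplicate linac ids"))
    known = set(linac_ids)
    for k in instance.linacs:
        if k.location not in ("main", "satellite"):
            out.append(Violation("linac-location", k.id, f"unknown location {k.location!r}"))

    seen: set[str] = set()
    for p in instance.patients:
        if p.id in seen:
            out.append(Violation("patient-id", p.id, "duplicate patient id"))
        seen.add(p.id)
        if p.remaining_sessions < 1:
            out.append(Violation("sessions", p.id, "remaining sessions must be >= 1"))
        if p.duration_slots < 1:
            out.append(Violation("duration", p.id, "session duration must be >= 1 slot"))
        elif p.duration_slots > pr.slots_per_day:
            out.append(Violation("duration", p.id, "session longer than the day"))
        if p.spacing_days < 1:
            out.append(Violation("spacing", p.id, "spacing must be >= 1 day"))
        if p.due_day < 1:
            out.append(Violation("due-date", p.id, "due day must be >= 1"))
        elif p.due_day > pr.horizon_days:
            out.append(Violation("due-date", p.id, "due date beyond horizon"))
        if not (0 <= p.window_lo <= p.window_hi <= pr.day_span_minutes):
            out.append(Violation("window", p.id, "preference window outside the day span"))
        if not p.feasible_linacs:
            out.append(Violation("feasible-linacs", p.id, "empty feasible linac set"))
        for kid in p.feasible_linacs:
            if kid not in known:
                out.append(Violation("feasible-linacs", p.id, f"unknown linac {kid!r}"))
        if p.is_new:
            if p.current_linac is not None:
                out.append(Violation("current-linac", p.id, "new patient with a current linac"))
        else:
            if p.current_linac is None:
                out.append(Violation("current-linac", p.id, "ongoing patient without a current linac"))
            elif p.current_linac not in p.feasible_linacs:
                out.append(
                    Violation("current-linac", p.id, "current linac not in the feasible set")
                )
            if p.due_day != 1:
                out.append(Violation("due-date", p.id, "ongoing patient must have due day 1"))
        if p.must_start_monday and p.due_day != 1:
            out.append(Violation("due-date", p.id, "Monday starter must have due day 1"))
        if p.restricted_frame:
            try:
                frame_to_slot_range(pr.frame_lo, pr.frame_hi, pr.slot_minutes, pr.slots_per_day)
            except InfeasibleFrameError:
                out.append(Violation("frame", p.id, "restricted frame admits no slot start"))
    return out
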