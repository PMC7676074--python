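"""Readers and writers for instance, pre-assignment, schedule and report files.

Canonical on-disk formats are JSON; schedules additionally export to CSV (one
row per session, with start minutes precomputed so downstream tools need no
slot arithmetic), and a patients-only CSV mirror of the instance format is
accepted for tabular workflows. Days and slots are 1-based in every file.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Any

import yaml

from .core import Instance, Linac, Patient, PlannerParams, Schedule, Session
from .errors import ParseError
from .evaluation import Metrics
from .milp import min_deviation
from .preassign import ClusterSpec, PreAssignment

__all__ = [
    "instance_to_dict",
    "instance_from_dict",
    "read_instance",
    "write_instance",
    "read_patients_csv",
    "write_patients_csv",
    "read_preassignment",
    "write_preassignment",
    "read_schedule",
    "write_schedule",
    "write_schedule_csv",
    "write_report",
    "read_cluster_spec",
]


def _need(mapping: dict, key: str, where: str) -> Any:
    if key not in mapping:
        raise ParseError(f"missing field {key!r} in {where}")
    return mapping[key]


def instance_to_dict(instance: Instance) -> dict:
    p = instance.params
    return {
        "params": {
            "horizon_days": p.horizon_days,
            "slots_per_day": p.slots_per_day,
            "slot_minutes": p.slot_minutes,
            "max_new_starts": p.max_new_starts,
            "frame": [p.frame_lo, p.frame_hi],
        },
        "linacs": [
            {
                "id": k.id,
                "location": k.location,
                "capacity_min": k.capacity_min,
                "unavailable": sorted([d, s] for d, s in k.unavailable),
            }
            for k in instance.linacs
        ],
        "patients": [
            {
                "id": pt.id,
                "care_plan": pt.care_plan,
                "new": pt.is_new,
                "monday_start": pt.must_start_monday,
                "restricted_frame": pt.restricted_frame,
                "urgent": pt.urgent,
                "sessions": pt.remaining_sessions,
                "due_day": pt.due_day,
                "duration_slots": pt.duration_slots,
                "spacing_days": pt.spacing_days,
                "window": [pt.window_lo, pt.window_hi],
                "feasible_linacs": list(pt.feasible_linacs),
                "current_linac": pt.current_linac,
            }
            for pt in instance.patients
        ],
    }


def instance_from_dict(data: dict) -> Instance:
    try:
        pd = _need(data, "params", "instance")
        frame = _need(pd, "frame", "params")
        params = PlannerParams(
            horizon_days=int(_need(pd, "horizon_days", "params")),
            slots_per_day=int(_need(pd, "slots_per_day", "params")),
            slot_minutes=int(_need(pd, "slot_minutes", "params")),
            max_new_starts=int(_need(pd, "max_new_starts", "params")),
            frame_lo=int(frame[0]),
            frame_hi=int(frame[1]),
        )
        linacs = tuple(
            Linac(
                id=str(_need(kd, "id", "linac")),
                location=kd.get("location", "main"),
                capacity_min=kd.get("capacity_min"),
                unavailable=frozenset((int(d), int(s)) for d, s in kd.get("unavailable", [])),
            )
            for kd in _need(data, "linacs", "instance")
        )
        patients = tuple(
            Patient(
                id=str(_need(pt, "id", "patient")),
                care_plan=pt.get("care_plan", "unknown"),
                is_new=bool(_need(pt, "new", f"patient {pt.get('id')}")),
                must_start_monday=bool(pt.get("monday_start", False)),
                restricted_frame=bool(pt.get("restricted_frame", False)),
                urgent=bool(pt.get("urgent", False)),
                remaining_sessions=int(_need(pt, "sessions", f"patient {pt.get('id')}")),
                due_day=int(_need(pt, "due_day", f"patient {pt.get('id')}")),
                duration_slots=int(_need(pt, "duration_slots", f"patient {pt.get('id')}")),
                spacing_days=int(pt.get("spacing_days", 1)),
                window_lo=int(_need(pt, "window", f"patient {pt.get('id')}")[0]),
                window_hi=int(pt["window"][1]),
                feasible_linacs=tuple(_need(pt, "feasible_linacs", f"patient {pt.get('id')}")),
                current_linac=pt.get("current_linac"),
            )
            for pt in _need(data, "patients", "instance")
        )
    except (TypeError, ValueError, IndexError) as exc:
        raise ParseError(f"malformed instance data: {exc}") from exc
    return Instance(patients=patients, linacs=linacs, params=params)


def read_instance(path: str | Path) -> Instance:
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}") from exc
    return instance_from_dict(data)


def write_instance(instance: Instance, path: str | Path) -> None:
    Path(path).write_text(json.dumps(instance_to_dict(instance), indent=1, sort_keys=True) + "\n")


_PATIENT_CSV_FIELDS = [
    "id", "care_plan", "new", "monday_start", "restricted_frame", "urgent", "sessions",
    "due_day", "duration_slots", "spacing_days", "window_lo", "window_hi",
    "feasible_linacs", "current_linac",
]


def write_patients_csv(instance: Instance, path: str | Path) -> None:
    """Patients-only CSV mirror of the instance format (one patient per row)."""
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=_PATIENT_CSV_FIELDS)
        w.writeheader()
        for p in instance.patients:
            w.writerow(
                {
                    "id": p.id, "care_plan": p.care_plan, "new": int(p.is_new),
                    "monday_start": int(p.must_start_monday),
                    "restricted_frame": int(p.restricted_frame), "urgent": int(p.urgent),
                    "sessions": p.remaining_sessions, "due_day": p.due_day,
                    "duration_slots": p.duration_slots, "spacing_days": p.spacing_days,
                    "window_lo": p.window_lo, "window_hi": p.window_hi,
                    "feasible_linacs": ";".join(p.feasible_linacs),
                    "current_linac": p.current_linac or "",
                }
            )


def read_patients_csv(path: str | Path, linacs: tuple[Linac, ...], params: PlannerParams) -> Instance:
    """Assemble an instance from a patients CSV plus linacs and parameters."""
    patients = []
    with open(path, newline="") as fh:
        for row_no, row in enumerate(csv.DictReader(fh), start=2):
            try:
                patients.append(
                    Patient(
                        id=row["id"], care_plan=row.get("care_plan", "unknown"),
                        is_new=bool(int(row["new"])),
                        must_start_monday=bool(int(row.get("monday_start", 0) or 0)),
                        restricted_frame=bool(int(row.get("restricted_frame", 0) or 0)),
                        urgent=bool(int(row.get("urgent", 0) or 0)),
                        remaining_sessions=int(row["sessions"]),
                        due_day=int(row["due_day"]),
                        duration_slots=int(row["duration_slots"]),
                        spacing_days=int(row.get("spacing_days", 1) or 1),
                        window_lo=int(row["window_lo"]), window_hi=int(row["window_hi"]),
                        feasible_linacs=tuple(x for x in row["feasible_linacs"].split(";") if x),
                        current_linac=row.get("current_linac") or None,
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ParseError(f"{path}: line {row_no}: {exc}") from exc
    return Instance(patients=tuple(patients), linacs=linacs, params=params)


def write_preassignment(pa: PreAssignment, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({"assignment": pa.assignment, "workloads": pa.workloads},
                   indent=1, sort_keys=True) + "\n"
    )


def read_preassignment(path: str | Path) -> PreAssignment:
    try:
        data = json.loads(Path(path).read_text())
        return PreAssignment(
            assignment=dict(_need(data, "assignment", "preassignment")),
            workloads={k: float(v) for k, v in _need(data, "workloads", "preassignment").items()},
        )
    except (json.JSONDecodeError, TypeError, ValueError) as exc:
        raise ParseError(f"{path}: malformed preassignment: {exc}") from exc


def _session_rows(schedule: Schedule, instance: Instance) -> list[dict]:
    l = instance.params.slot_minutes
    rows = []
    for s in schedule.sessions:
        p = instance.patient_by_id(s.patient)
        dm, dp = min_deviation(s.start_slot, l, (p.window_lo, p.window_hi))
        rows.append(
            {
                "patient": s.patient, "linac": s.linac, "day": s.day,
                "start_slot": s.start_slot, "start_minutes": l * (s.start_slot - 1),
                "duration_min": p.duration_slots * l, "in_window": int(dm + dp == 0),
            }
        )
    return rows


def write_schedule(schedule: Schedule, instance: Instance, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({"sessions": _session_rows(schedule, instance)}, indent=1) + "\n"
    )


def write_schedule_csv(schedule: Schedule, instance: Instance, path: str | Path) -> None:
    rows = _session_rows(schedule, instance)
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=list(rows[0].keys()) if rows else
                           ["patient", "linac", "day", "start_slot", "start_minutes",
                            "duration_min", "in_window"])
        w.writeheader()
        w.writerows(rows)


def read_schedule(path: str | Path, instance: Instance) -> Schedule:
    """Read a schedule (JSON or CSV by extension), validating references."""
    path = Path(path)
    if path.suffix == ".csv":
        with open(path, newline="") as fh:
            raw = list(csv.DictReader(fh))
    else:
        try:
            raw = json.loads(path.read_text())["sessions"]
        except (json.JSONDecodeError, KeyError) as exc:
            raise ParseError(f"{path}: malformed schedule: {exc}") from exc
    known_k = {k.id for k in instance.linacs}
    known_p = {p.id for p in instance.patients}
    sessions = []
    deviations = {}
    l = instance.params.slot_minutes
    for n, row in enumerate(raw, start=1):
        try:
            sess = Session(
                patient=row["patient"], linac=row["linac"],
                day=int(row["day"]), start_slot=int(row["start_slot"]),
            )
        except (KeyError, ValueError) as exc:
            raise ParseError(f"{path}: session {n}: {exc}") from exc
        if sess.linac not in known_k:
            raise ParseError(f"{path}: session {n}: unknown linac {sess.linac!r}")
        if sess.patient not in known_p:
            raise ParseError(f"{path}: session {n}: unknown patient {sess.patient!r}")
        p = instance.patient_by_id(sess.patient)
        deviations[(sess.patient, sess.day)] = tuple(
            float(v) for v in min_deviation(sess.start_slot, l, (p.window_lo, p.window_hi))
        )
        sessions.append(sess)
    return Schedule(sessions=tuple(sessions), deviations=deviations)


def write_report(metrics: Metrics, path: str | Path) -> None:
    """Schedule quality report with aggregate and per-linac sections."""
    data = {
        "aggregate": {
            "sessions_scheduled": metrics.sessions_scheduled,
            "sessions_outside_window": metrics.sessions_outside_window,
            "fraction_outside_window": metrics.fraction_outside_window,
            "cumulative_deviation_min": metrics.cumulative_deviation_min,
            "avg_deviation_outside_min": metrics.avg_deviation_outside_min,
        },
        "per_linac": {
            kid: {
                "workload_min": metrics.per_linac_workload_min[kid],
                "utilization": metrics.per_linac_utilization[kid],
                "patients": metrics.per_linac_patients[kid],
            }
            for kid in metrics.per_linac_workload_min
        },
    }
    Path(path).write_text(json.dumps(data, indent=1, sort_keys=True) + "\n")


def read_cluster_spec(path: str | Path) -> ClusterSpec:
    """Cluster spec YAML: a list of lists of linac ids."""
    try:
        data = yaml.safe_load(Path(path).read_text())
        return ClusterSpec(tuple(tuple(str(k) for k in group) for group in data))
    except (yaml.YAMLError, TypeError) as exc:
        raise ParseError(f"{path}: malformed cluster spec: {exc}") from exc
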