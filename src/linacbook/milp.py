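"""Exact MILP for the weekly session scheduling and sequencing problem.

Decision variables: binaries x[i,k,s,t] (patient i gets a session starting at
slot s of linac k on day t) and y[i,k,t] (new patient i starts treatment on
linac k, day t); continuous deviations dm[i,t], dp[i,t] >= 0 measuring, in
minutes, how far the booked start falls below/above the patient's preferred
window. The objective minimizes the total deviation.

Constraint families (tags used throughout):

* ``eq2``/``eq3``  - continuity: once a first session is placed, sessions
  must follow every b_i days until the horizon or session count runs out
  (the history sum in eq2 makes the row binding only at the first session).
* ``eq4``          - no sessions on the rest days between spaced sessions.
* ``eq5``          - at most one session per patient per day.
* ``eq6``          - at most I_i sessions in the week.
* ``eq7``          - a first session no later than the due day.
* ``eq8``          - at most one session starts per open slot; blocked slots
  are fixed to zero (``eq8_fixed``).
* ``eq9``          - infeasible linacs: fixed to zero at the variable bounds.
* ``eq10``/``eq11``- start detection linking x to y.
* ``eq12``         - at most C new starts per linac per day.
* ``eq13``         - a session's remaining slots cannot host other starts.
* ``eq14``         - multi-slot sessions cannot start in the last slots of
  the day (variable fixing).
* ``eq15``         - restricted-frame patients start within the frame
  (variable fixing).
* ``eq16``         - deviation lower links: dm >= (t_min - start)*x,
  dp >= (start - t_max)*x, emitted only where the coefficient is positive
  (the remaining rows are implied by dm, dp >= 0).
* ``delta_cap``    - deviation upper links dm <= sum_k,s max(0, t_min-start)*x
  (and symmetrically dp), valid because eq5 books at most one session per
  patient-day; they pin the deviations to zero on sessionless days and to the
  exact minimal deviation otherwise, so the objective is well determined at
  every feasible point.

Solved through scipy's HiGHS-backed ``milp``.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .core import (
    Instance,
    Schedule,
    Session,
    frame_to_slot_range,
    slot_start_minutes,
    validate_instance,
)
from .errors import (
    BuildRefusedError,
    ExtractionError,
    SolverUnavailableError,
)

__all__ = ["MILPModel", "SolveReport", "build_milp", "solve_milp", "extract_schedule", "min_deviation"]


def min_deviation(s: int, l: int, window: tuple[int, int]) -> tuple[int, int]:
    """Smallest nonnegative (under, over) deviation of a start at slot ``s``.

    For a session starting at minute l*(s-1) and a preferred window
    [t_min, t_max]: under = max(0, t_min - start), over = max(0, start - t_max).
    """
    start = slot_start_minutes(s, l)
    lo, hi = window
    return max(0, lo - start), max(0, start - hi)


@dataclass
class SolveReport:
    """Outcome of a MILP solve."""

    status: str  # "optimal" | "feasible" | "infeasible" | "time_limit"
    objective: float | None
    gap: float | None
    wall_time_s: float


@dataclass
class MILPModel:
    """A built model: sparse rows tagged by constraint family, plus metadata."""

    instance: Instance
    n_vars: int
    c: np.ndarray
    integrality: np.ndarray
    var_lb: np.ndarray
    var_ub: np.ndarray
    row_matrix: sparse.csr_matrix
    row_lb: np.ndarray
    row_ub: np.ndarray
    row_family: list[str]
    fixed_counts: dict[str, int]
    # index geometry
    n_patients: int
    n_linacs: int
    n_slots: int
    n_days: int
    x_count: int
    dm_base: int
    dp_base: int
    y_base: int
    new_patient_rows: dict[int, int]  # patient index -> y block index
    effective_linacs: list[tuple[int, ...]] = field(default_factory=list)

    def x_index(self, i: int, k: int, s: int, t: int) -> int:
        """Column of x for patient i, linac k (0-based), slot s, day t (1-based)."""
        return ((i * self.n_linacs + k) * self.n_days + (t - 1)) * self.n_slots + (s - 1)

    def dm_index(self, i: int, t: int) -> int:
        return self.dm_base + i * self.n_days + (t - 1)

    def dp_index(self, i: int, t: int) -> int:
        return self.dp_base + i * self.n_days + (t - 1)

    def y_index(self, i: int, k: int, t: int) -> int:
        ni = self.new_patient_rows[i]
        return self.y_base + (ni * self.n_linacs + k) * self.n_days + (t - 1)

    @property
    def n_x(self) -> int:
        return self.x_count

    def family_counts(self) -> dict[str, int]:
        """Row counts per constraint family plus variable-fixing counts."""
        counts: dict[str, int] = {}
        for fam in self.row_family:
            counts[fam] = counts.get(fam, 0) + 1
        for fam, n in self.fixed_counts.items():
            counts[fam] = counts.get(fam, 0) + n
        return counts

    def is_fixed_zero(self, col: int) -> bool:
        return self.var_ub[col] == 0.0

    def to_lp(self, path: str) -> None:
        """Write an LP-format text dump of the model for auditing."""
        names = self._var_names()
        lines = ["Minimize", " obj: " + " + ".join(
            f"{self.c[j]:g} {names[j]}" for j in np.nonzero(self.c)[0]
        ), "Subject To"]
        m = self.row_matrix.tocsr()
        for r in range(m.shape[0]):
            cols = m.indices[m.indptr[r]:m.indptr[r + 1]]
            vals = m.data[m.indptr[r]:m.indptr[r + 1]]
            expr = " + ".join(f"{v:g} {names[j]}" for v, j in zip(vals, cols)).replace("+ -", "- ")
            lo, hi = self.row_lb[r], self.row_ub[r]
            tag = f"{self.row_family[r]}_{r}"
            if np.isfinite(hi):
                lines.append(f" {tag}: {expr} <= {hi:g}")
            if np.isfinite(lo):
                lines.append(f" {tag}_lo: {expr} >= {lo:g}")
        lines.append("Bounds")
        for j in range(self.n_vars):
            lines.append(f" {self.var_lb[j]:g} <= {names[j]} <= {self.var_ub[j]:g}")
        lines.append("Binaries")
        lines.append(" " + " ".join(names[j] for j in np.nonzero(self.integrality)[0]))
        lines.append("End")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    def _var_names(self) -> list[str]:
        inst = self.instance
        names = [""] * self.n_vars
        for i, p in enumerate(inst.patients):
            for k, lin in enumerate(inst.linacs):
                for t in range(1, self.n_days + 1):
                    for s in range(1, self.n_slots + 1):
                        names[self.x_index(i, k, s, t)] = f"x_{p.id}_{lin.id}_s{s}_t{t}"
            for t in range(1, self.n_days + 1):
                names[self.dm_index(i, t)] = f"dm_{p.id}_t{t}"
                names[self.dp_index(i, t)] = f"dp_{p.id}_t{t}"
        for i, ni in self.new_patient_rows.items():
            p = inst.patients[i]
            for k, lin in enumerate(inst.linacs):
                for t in range(1, self.n_days + 1):
                    names[self.y_index(i, k, t)] = f"y_{p.id}_{lin.id}_t{t}"
        return names


class _RowAccumulator:
    """Collects sparse rows (as triplets) with per-row bounds and family tags."""

    def __init__(self) -> None:
        self.rows: list[np.ndarray] = []
        self.cols: list[np.ndarray] = []
        self.vals: list[np.ndarray] = []
        self.lb: list[float] = []
        self.ub: list[float] = []
        self.family: list[str] = []
        self.n = 0

    def add_row(self, cols, vals, lb: float, ub: float, family: str) -> None:
        cols = np.asarray(cols, dtype=np.int64)
        self.rows.append(np.full(cols.size, self.n, dtype=np.int64))
        self.cols.append(cols)
        self.vals.append(np.asarray(vals, dtype=np.float64))
        self.lb.append(lb)
        self.ub.append(ub)
        self.family.append(family)
        self.n += 1

    def add_block(self, local_rows, cols, vals, n_rows: int, lb: float, ub: float, family: str) -> None:
        """Add ``n_rows`` rows at once; ``local_rows`` are 0..n_rows-1 indices."""
        self.rows.append(np.asarray(local_rows, dtype=np.int64) + self.n)
        self.cols.append(np.asarray(cols, dtype=np.int64))
        self.vals.append(np.asarray(vals, dtype=np.float64))
        self.lb.extend([lb] * n_rows)
        self.ub.extend([ub] * n_rows)
        self.family.extend([family] * n_rows)
        self.n += n_rows

    def to_csr(self, n_vars: int) -> sparse.csr_matrix:
        if not self.rows:
            return sparse.csr_matrix((0, n_vars))
        rows = np.concatenate(self.rows)
        cols = np.concatenate(self.cols)
        vals = np.concatenate(self.vals)
        return sparse.coo_matrix((vals, (rows, cols)), shape=(self.n, n_vars)).tocsr()


def build_milp(instance: Instance, fixed_assignment: dict[str, str] | None = None) -> MILPModel:
    """Build the full model over an instance.

    ``fixed_assignment`` (patient id -> linac id), when given, tightens the
    feasible linac set of each listed new patient to that single linac.
    Ongoing patients are always pinned to the linac they are treated on.
    """
    problems = validate_instance(instance)
    if problems:
        raise BuildRefusedError(f"instance failed validation: {problems[:5]}")
    params = instance.params
    nP, nK = len(instance.patients), len(instance.linacs)
    nS, nT = params.slots_per_day, params.horizon_days
    l = params.slot_minutes
    lin_index = {k.id: j for j, k in enumerate(instance.linacs)}

    if fixed_assignment:
        for pid, kid in fixed_assignment.items():
            p = instance.patient_by_id(pid)
            if kid not in p.feasible_linacs:
                raise BuildRefusedError(
                    f"fixed assignment sends patient {pid!r} to infeasible linac {kid!r}"
                )

    def k_eff(i: int) -> tuple[int, ...]:
        p = instance.patients[i]
        if not p.is_new and p.current_linac is not None:
            return (lin_index[p.current_linac],)
        if fixed_assignment and p.id in fixed_assignment:
            return (lin_index[fixed_assignment[p.id]],)
        return tuple(sorted(lin_index[kid] for kid in p.feasible_linacs))

    effective = [k_eff(i) for i in range(nP)]
    new_ids = [i for i, p in enumerate(instance.patients) if p.is_new]
    new_rows = {i: ni for ni, i in enumerate(new_ids)}

    x_count = nP * nK * nS * nT
    dm_base = x_count
    dp_base = dm_base + nP * nT
    y_base = dp_base + nP * nT
    n_vars = y_base + len(new_ids) * nK * nT

    var_lb = np.zeros(n_vars)
    var_ub = np.ones(n_vars)
    var_ub[dm_base:y_base] = np.inf  # deviations are unbounded above (eq17: >= 0)
    integrality = np.ones(n_vars, dtype=np.int64)
    integrality[dm_base:y_base] = 0
    c = np.zeros(n_vars)
    c[dm_base:y_base] = 1.0  # objective: total under- plus over-deviation

    def xcol(i: int, k: int, s: int, t: int) -> int:
        return ((i * nK + k) * nT + (t - 1)) * nS + (s - 1)

    def xblock(i: int, k: int, t: int) -> np.ndarray:
        base = ((i * nK + k) * nT + (t - 1)) * nS
        return np.arange(base, base + nS, dtype=np.int64)

    fixed_counts: dict[str, int] = {}

    def fix_zero(cols: np.ndarray, family: str) -> None:
        cols = cols[var_ub[cols] != 0.0]
        var_ub[cols] = 0.0
        fixed_counts[family] = fixed_counts.get(family, 0) + int(cols.size)

    # eq9: linacs outside the (effective) feasible set
    for i in range(nP):
        keep = set(effective[i])
        for k in range(nK):
            if k not in keep:
                for t in range(1, nT + 1):
                    fix_zero(xblock(i, k, t), "eq9")

    # eq14: multi-slot sessions cannot start in the trailing slots of the day
    for i, p in enumerate(instance.patients):
        if p.duration_slots >= 2:
            for k in effective[i]:
                for t in range(1, nT + 1):
                    base = xcol(i, k, 1, t) - 1
                    cols = np.arange(base + nS - p.duration_slots + 2, base + nS + 1, dtype=np.int64)
                    fix_zero(cols, "eq14")

    # eq15: restricted-frame starts only inside the frame
    frame_first, frame_last = None, None
    if any(p.restricted_frame for p in instance.patients):
        frame_first, frame_last = frame_to_slot_range(params.frame_lo, params.frame_hi, l, nS)
    for i, p in enumerate(instance.patients):
        if p.restricted_frame:
            for k in effective[i]:
                for t in range(1, nT + 1):
                    base = xcol(i, k, 1, t) - 1
                    before = np.arange(base + 1, base + frame_first, dtype=np.int64)
                    after = np.arange(base + frame_last + 1, base + nS + 1, dtype=np.int64)
                    fix_zero(np.concatenate([before, after]), "eq15")

    # eq8 (fixing part): blocked slots host no session start
    for k, lin in enumerate(instance.linacs):
        for (day, slot) in lin.unavailable:
            if 1 <= day <= nT and 1 <= slot <= nS:
                cols = np.array([xcol(i, k, slot, day) for i in range(nP)], dtype=np.int64)
                fix_zero(cols, "eq8_fixed")

    acc = _RowAccumulator()

    # eq2/eq3: continuity from the first session day
    for i, p in enumerate(instance.patients):
        b, I = p.spacing_days, p.remaining_sessions
        for k in effective[i]:
            blocks = {t: xblock(i, k, t) for t in range(1, nT + 1)}
            for t in range(2, nT + 1):
                followers = range(t + b, min(nT, t + b * (I - 1)) + 1, b)
                history = np.concatenate([blocks[tp] for tp in range(1, t)])
                for n in followers:
                    cols = np.concatenate([blocks[t], history, blocks[n]])
                    vals = np.concatenate(
                        [np.ones(nS), -np.ones(history.size), -np.ones(nS)]
                    )
                    acc.add_row(cols, vals, -np.inf, 0.0, "eq2")
            for n in range(b + 1, min(nT, b * (I - 1) + 1) + 1, b):
                cols = np.concatenate([blocks[1], blocks[n]])
                vals = np.concatenate([np.ones(nS), -np.ones(nS)])
                acc.add_row(cols, vals, -np.inf, 0.0, "eq3")
            # eq4: rest days between spaced sessions
            if b >= 2:
                for t in range(1, nT - b + 1):
                    for n in range(t + 1, t + b):
                        cols = np.concatenate([blocks[t], blocks[n]])
                        acc.add_row(cols, np.ones(cols.size), -np.inf, 1.0, "eq4")

    # eq5: at most one session per patient-day; eq6: at most I_i per week; eq7: due date
    for i, p in enumerate(instance.patients):
        day_blocks = {
            t: np.concatenate([xblock(i, k, t) for k in effective[i]]) for t in range(1, nT + 1)
        }
        for t in range(1, nT + 1):
            acc.add_row(day_blocks[t], np.ones(day_blocks[t].size), -np.inf, 1.0, "eq5")
        all_cols = np.concatenate([day_blocks[t] for t in range(1, nT + 1)])
        acc.add_row(all_cols, np.ones(all_cols.size), -np.inf, float(p.remaining_sessions), "eq6")
        due_cols = np.concatenate([day_blocks[t] for t in range(1, min(p.due_day, nT) + 1)])
        acc.add_row(due_cols, np.ones(due_cols.size), 1.0, np.inf, "eq7")

    # eq8 (row part): one start per open slot
    patients_on = {k: [i for i in range(nP) if k in effective[i]] for k in range(nK)}
    for k, lin in enumerate(instance.linacs):
        cand = patients_on[k]
        if len(cand) < 2:
            continue
        for t in range(1, nT + 1):
            for s in range(1, nS + 1):
                if not lin.is_available(s, t):
                    continue
                cols = np.array([xcol(i, k, s, t) for i in cand], dtype=np.int64)
                acc.add_row(cols, np.ones(cols.size), -np.inf, 1.0, "eq8")

    # eq10/eq11: start detection for new patients; eq12: the per-day cap
    for i in new_ids:
        p = instance.patients[i]
        for k in effective[i]:
            for t in range(2, nT + 1):
                tp = max(1, t - p.spacing_days)
                cols = np.concatenate(
                    [xblock(i, k, t), xblock(i, k, tp), [_ycol(y_base, new_rows, nK, nT, i, k, t)]]
                )
                vals = np.concatenate([np.ones(nS), -np.ones(nS), [-1.0]])
                acc.add_row(cols, vals, -np.inf, 0.0, "eq10")
            cols = np.concatenate(
                [xblock(i, k, 1), [_ycol(y_base, new_rows, nK, nT, i, k, 1)]]
            )
            vals = np.concatenate([np.ones(nS), [-1.0]])
            acc.add_row(cols, vals, -np.inf, 0.0, "eq11")
    if new_ids:
        for k in range(nK):
            for t in range(1, nT + 1):
                cols = np.array(
                    [_ycol(y_base, new_rows, nK, nT, i, k, t) for i in new_ids], dtype=np.int64
                )
                acc.add_row(cols, np.ones(cols.size), -np.inf, float(params.max_new_starts), "eq12")

    # eq13: the footprint of a multi-slot session blocks other starts
    for i, p in enumerate(instance.patients):
        pdur = p.duration_slots
        if pdur < 2:
            continue
        for k in effective[i]:
            others = np.array(
                [((i2 * nK + k) * nT) * nS for i2 in patients_on[k]], dtype=np.int64
            )  # day-0 bases; shift by day below
            n_rows = nS - pdur + 1
            srange = np.arange(n_rows, dtype=np.int64)  # 0-based start offsets
            for t in range(1, nT + 1):
                day_shift = (t - 1) * nS
                self_cols = xcol(i, k, 1, t) - 1 + 1 + srange  # x_{i,k,s,t}
                block_cols = [self_cols]
                block_rows = [srange]
                for d in range(1, pdur):
                    grid = (others + day_shift)[None, :] + (srange[:, None] + d)
                    block_cols.append(grid.ravel())
                    block_rows.append(np.repeat(srange, others.size))
                cols = np.concatenate(block_cols)
                rows = np.concatenate(block_rows)
                acc.add_block(rows, cols, np.ones(cols.size), n_rows, -np.inf, 1.0, "eq13")

    # eq16 + delta_cap: deviation links
    for i, p in enumerate(instance.patients):
        starts = l * np.arange(nS)  # start minutes per 0-based slot
        under = np.maximum(0, p.window_lo - starts).astype(float)
        over = np.maximum(0, starts - p.window_hi).astype(float)
        under_slots = np.nonzero(under)[0]
        over_slots = np.nonzero(over)[0]
        for t in range(1, nT + 1):
            dm = dm_base + i * nT + (t - 1)
            dp = dp_base + i * nT + (t - 1)
            cap_cols_m, cap_vals_m = [dm], [1.0]
            cap_cols_p, cap_vals_p = [dp], [1.0]
            for k in effective[i]:
                base = xcol(i, k, 1, t) - 1
                for si in under_slots:
                    acc.add_row([base + 1 + si, dm], [under[si], -1.0], -np.inf, 0.0, "eq16")
                for si in over_slots:
                    acc.add_row([base + 1 + si, dp], [over[si], -1.0], -np.inf, 0.0, "eq16")
                cap_cols_m.extend(base + 1 + under_slots)
                cap_vals_m.extend(-under[under_slots])
                cap_cols_p.extend(base + 1 + over_slots)
                cap_vals_p.extend(-over[over_slots])
            acc.add_row(cap_cols_m, cap_vals_m, -np.inf, 0.0, "delta_cap")
            acc.add_row(cap_cols_p, cap_vals_p, -np.inf, 0.0, "delta_cap")

    return MILPModel(
        instance=instance,
        n_vars=n_vars,
        c=c,
        integrality=integrality,
        var_lb=var_lb,
        var_ub=var_ub,
        row_matrix=acc.to_csr(n_vars),
        row_lb=np.asarray(acc.lb),
        row_ub=np.asarray(acc.ub),
        row_family=acc.family,
        fixed_counts=fixed_counts,
        n_patients=nP,
        n_linacs=nK,
        n_slots=nS,
        n_days=nT,
        x_count=x_count,
        dm_base=dm_base,
        dp_base=dp_base,
        y_base=y_base,
        new_patient_rows=new_rows,
        effective_linacs=effective,
    )


def _ycol(y_base: int, new_rows: dict[int, int], nK: int, nT: int, i: int, k: int, t: int) -> int:
    return y_base + (new_rows[i] * nK + k) * nT + (t - 1)


def solve_milp(
    model: MILPModel,
    time_limit_s: float = 7200.0,
    gap_tol: float = 1e-4,
) -> tuple[SolveReport, np.ndarray | None]:
    """Solve a built model with HiGHS; returns the report and variable values."""
    from scipy.optimize import Bounds, LinearConstraint, milp

    constraints = []
    if model.row_matrix.shape[0]:
        constraints.append(LinearConstraint(model.row_matrix, model.row_lb, model.row_ub))
    t0 = time.perf_counter()
    try:
        res = milp(
            model.c,
            constraints=constraints,
            integrality=model.integrality,
            bounds=Bounds(model.var_lb, model.var_ub),
            options={"time_limit": float(time_limit_s), "mip_rel_gap": float(gap_tol), "disp": False},
        )
    except Exception as exc:  # pragma: no cover - backend failure
        raise SolverUnavailableError(f"MILP backend failed: {exc}") from exc
    wall = time.perf_counter() - t0
    gap = getattr(res, "mip_gap", None)
    if res.status == 0:
        report = SolveReport("optimal", float(res.fun), gap, wall)
    elif res.status == 1 and res.x is not None:
        report = SolveReport("feasible", float(res.fun), gap, wall)
    elif res.status == 1:
        report = SolveReport("time_limit", None, None, wall)
    elif res.status == 2:
        report = SolveReport("infeasible", None, None, wall)
    else:  # pragma: no cover - unbounded/numerical trouble
        raise SolverUnavailableError(f"solver returned status {res.status}: {res.message}")
    return report, (None if res.x is None else np.asarray(res.x))


def extract_schedule(model: MILPModel, values: np.ndarray, tol: float = 1e-6) -> Schedule:
    """Turn a solution vector into a Schedule; deviations are recomputed.

    Raises :class:`ExtractionError` when any x value is farther than ``tol``
    from {0, 1}. Deviations per session come from :func:`min_deviation`, which
    also zeroes them on sessionless patient-days.
    """
    inst = model.instance
    x = np.asarray(values[: model.x_count])
    frac = np.minimum(np.abs(x), np.abs(x - 1.0))
    bad = np.nonzero(frac > tol)[0]
    if bad.size:
        raise ExtractionError(
            f"{bad.size} x values are fractional beyond tolerance {tol} (first: {x[bad[0]]})"
        )
    sessions: list[Session] = []
    deviations: dict[tuple[str, int], tuple[float, float]] = {}
    l = inst.params.slot_minutes
    for col in np.nonzero(x > 0.5)[0]:
        rem = int(col)
        si = rem % model.n_slots
        rem //= model.n_slots
        ti = rem % model.n_days
        rem //= model.n_days
        ki = rem % model.n_linacs
        i = rem // model.n_linacs
        p = inst.patients[i]
        sessions.append(
            Session(patient=p.id, linac=inst.linacs[ki].id, day=ti + 1, start_slot=si + 1)
        )
        deviations[(p.id, ti + 1)] = tuple(
            float(v) for v in min_deviation(si + 1, l, (p.window_lo, p.window_hi))
        )
    sessions.sort(key=lambda s: (s.patient, s.day))
    return Schedule(sessions=tuple(sessions), deviations=deviations)
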