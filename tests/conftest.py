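"""Shared fixtures: hand-sized instances and a seeded tiny-instance sampler."""

from __future__ import annotations

import numpy as np
import pytest

from linacbook import Instance, Linac, Patient, PlannerParams


def make_patient(pid="p1", **kw) -> Patient:
    """A daily 1-slot new patient with an all-day window, overridable."""
    defaults = dict(
        id=pid,
        care_plan="test",
        is_new=True,
        remaining_sessions=1,
        due_day=1,
        duration_slots=1,
        feasible_linacs=("L1",),
        window_lo=0,
        window_hi=595,
    )
    defaults.update(kw)
    return Patient(**defaults)


def random_tiny_instance(seed: int) -> Instance:
    """A random instance small enough for exhaustive enumeration.

    Up to 3 patients, 2 linacs, 2 days and 8 slots, with random durations,
    spacing, windows, availability holes, frames, and new/ongoing mixes.
    """
    rng = np.random.default_rng(seed)
    nT = int(rng.integers(1, 3))
    nS = int(rng.integers(4, 9))
    nK = int(rng.integers(1, 3))
    l = 5
    span = nS * l
    params = PlannerParams(
        horizon_days=nT,
        slots_per_day=nS,
        slot_minutes=l,
        max_new_starts=int(rng.integers(1, 3)),
        frame_lo=int(rng.integers(0, 2)) * l,
        frame_hi=span - int(rng.integers(0, 2)) * l,
    )
    linacs = tuple(
        Linac(
            f"L{j + 1}",
            unavailable=frozenset(
                (int(rng.integers(1, nT + 1)), int(rng.integers(1, nS + 1)))
                for _ in range(int(rng.integers(0, 3)))
            ),
        )
        for j in range(nK)
    )
    ids = tuple(k.id for k in linacs)
    patients = []
    for i in range(int(rng.integers(1, 4))):
        feas = tuple(sorted(rng.choice(ids, size=int(rng.integers(1, nK + 1)), replace=False)))
        new = bool(rng.random() < 0.6)
        lo = int(rng.integers(0, nS)) * l
        hi = int(rng.integers(lo // l, nS)) * l
        patients.append(
            make_patient(
                pid=f"p{i + 1}",
                is_new=new,
                remaining_sessions=int(rng.integers(1, 4)),
                due_day=1 if not new else int(rng.integers(1, nT + 1)),
                duration_slots=int(rng.integers(1, 3)),
                feasible_linacs=feas,
                spacing_days=int(rng.integers(1, 3)),
                window_lo=lo,
                window_hi=hi,
                current_linac=None if new else str(rng.choice(feas)),
                restricted_frame=bool(rng.random() < 0.3),
            )
        )
    return Instance(patients=tuple(patients), linacs=linacs, params=params)


@pytest.fixture(scope="session")
def nki_sample_10k():
    """One 10,000-patient draw from the default generator, shared per session."""
    from linacbook import default_nki_config, generate_instance

    return generate_instance(default_nki_config(n_patients=10_000, n_linacs=8, seed=20260928))
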