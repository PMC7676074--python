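# Methods

## Problem and model

The package schedules the week of a radiotherapy center offline: all patient
data are known when the plan is made (deviations between planned and realized
session attributes are rare enough in practice to treat inputs as
deterministic), and the plan books every remaining irradiation session of
every patient onto a linac, day and 1-based starting slot. The planning
horizon is |T| days (default 5, Monday–Friday), each day holds |S| slots of
l minutes (defaults 120 × 5 min, a 600-minute clinical day); slot s starts
l·(s−1) minutes after opening.

The objective minimizes total preference deviation in minutes,
Σ_i Σ_t (Δ⁻_it + Δ⁺_it), where the deviations are linked to the booked start
by t_min·x − Δ⁻ ≤ l(s−1)·x ≤ t_max·x + Δ⁺ per (patient, linac, slot, day).
Because at most one session per patient-day exists, these rows are linear
without big-M constants. Two implementation choices complete the
formulation:

* **Objective scope.** Every patient's deviations are priced in the
  objective; leaving any patient out would let that patient's sessions float
  to arbitrary slots at zero cost.
* **Deviations on sessionless days.** The deviation variables are otherwise
  free to float on days without a session. We add upper-link rows
  Δ⁻_it ≤ Σ_{k,s} max(0, t_min − l(s−1))·x_iks^t (and symmetrically for Δ⁺),
  valid under the one-session-per-day rule, which pin each deviation to the
  exact minimal deviation of the booked start and to zero on sessionless
  days. The objective value is therefore well defined at every feasible
  point, not only at optimality. Deviation lower links with nonpositive
  coefficients are implied by Δ ≥ 0 and are not emitted.

Constraint families follow the formulation literally and carry audit tags
(eq2…eq16, delta_cap); per-family row counts are available from the built
model and an LP-format text export supports inspection. Three literal
readings worth knowing:

* The continuity rows subtract the booking history, so they bind only at a
  patient's first session day; from there the session days are exactly
  {t₀, t₀+b, …} truncated at the horizon or the session count.
* The rest-day family for spaced schemes quantifies its anchor day only up
  to |T|−b, so the final adjacency pair of the week (e.g. days 4 and 5 for
  b=2) is not forbidden by the formulation. We mirror this literally in both
  the model and the independent checker so that the two agree exactly; it is
  a formulation artifact that never lowers the optimum.
* Slot availability applies to session starts; the trailing slots of a
  multi-slot session are protected from other starts but not themselves
  availability-checked. With the default full-availability grids this is
  moot.

Structural restrictions (infeasible linacs, day-end starts for multi-slot
sessions, restricted-frame starts, blocked slots) are applied as variable
fixings rather than rows; ongoing patients are pinned to their current linac
at build time, which realizes the same-linac policy the center applies to
patients already under treatment.

The restricted time frame is stored in minutes (the operational unit; default
[60, 570], i.e. 08h30–17h00 of a 07h30 day start) and converted to the slot
range whose starts it admits — frame [60, 570] on the 5-minute grid admits
start slots 13…115. A session must *start* within the frame; it may end past
it. Window bounds behave the same way: a start exactly on a window bound
counts as in-window.

## Solver

Models are built as SciPy sparse matrices and solved with
`scipy.optimize.milp` (HiGHS). Defaults: relative MIP gap 1e-4, per-run time
limit 7200 s, and a 28 800 s total budget split evenly across clusters in the
sequential pipeline — generous bounds for the desk-scale problem sizes the
tests exercise. HiGHS runs single-threaded here, which makes repeated solves
reproducible; tests assert objective values and feasibility, never specific
slot choices, since ties among equal-deviation slots are broken by the
solver. Extraction rejects solutions whose binaries are farther than 1e-6
from integrality and recomputes deviations from the booked slots rather than
trusting solver values.

## Pre-assignment and clustering

`preassign` seeds per-linac workloads WL(k) with the volume of ongoing
patients, then walks new patients in input order, scanning each patient's
feasible linacs by ascending WL (ties by linac id) and assigning to the
first with WL(k) + vol(i) ≤ C_k. A patient's volume vol(i) is the number of
sessions a day-1 start fits into the horizon times the session length in
minutes; C_k is the weekly open-slot capacity (3000 min at defaults). From
equal initial loads this greedy min-load rule guarantees
max_k WL − min_k WL ≤ max_i vol(i). Input order matches how the heuristic is
stated; an LPT-style descending-volume sort would tighten balance further
but is deliberately not the default.

Clusters are a partition of the linac fleet that never mixes the main and
satellite sites (satellite placement is fixed at referral). Within a
cluster, a new patient may be rebooked onto any cluster linac still in their
feasible set; ongoing patients stay pinned. Cluster subproblems share no
patients or machines, so the merged schedule's objective is the sum of
cluster objectives and decomposition can only restrict (never improve) the
optimum — a property the tests check against the undecomposed model.

## Synthetic generator

The generator emulates the weekly intake of a large Dutch center
(~33 patients per linac per week, 8 linacs of which 2 satellite). A patient
draws a care plan first; the plan conditions session count (1–35), session
duration (10–30 min in 5-min steps), urgency, due-day distribution, the
every-other-day flag and the restricted-frame flag. Globally, 35% of
patients are new; ongoing patients get due day 1, a uniformly drawn current
linac and a remaining-session count uniform on 1..I of their plan
(mid-treatment progress is unobserved). Preference windows come from a
three-way menu — morning [0, 90], mid-day [90, 510], late [510, 600] minutes
— at 25/50/25.

Only the two largest care plans carry individually specified shares (bone
metastasis 23.3%, with 65% of its courses at ≤3 sessions; breast 16.5%);
nine further
synthetic plans absorb the remaining mass, with their distributions tuned so
the *mixture marginals* match the center-level aggregates: 15-minute share
60.5%, ≥20-minute share 19.9%, urgent share 34.0%, every-other-day share 6%
(two plans), restricted-frame share 21% (three plans). The aggregate
marginals, not the full plan-by-plan split, drive the optimization, so this
is the level at which fidelity matters. Per-plan due-day distributions are
not individually specified; the default is uniform on 1..5 for new patients
and is exposed per-plan as a calibration knob. The must-start-Monday share
defaults to 0 with a config hook rather than an invented rate.

What the generator does *not* emulate: multi-week arrival processes,
urgency-dependent intra-week arrivals, correlations between preference
window and care plan, and real pre-allocation tables (every patient is
eligible for every linac by default). Passing tests therefore demonstrate
correctness of the method under a realistic marginal mix, not performance on
any particular center's confidential case mix.

## Evaluation

`check_feasibility` re-implements every constraint family declaratively
(no solver) and returns violations as data; on every fixture suite instance
a schedule passes the checker iff it is a feasible point of the built MILP,
and the checker-recomputed cumulative deviation equals the solver objective
to 1e-6. Metrics follow planner conventions: a session is outside its window
iff its minimal deviation is strictly positive; average deviation is taken
over outside sessions only; utilization is booked minutes over weekly
capacity; empty schedules report fractions as not-applicable rather than 0.

## Test problem sizes

The exhaustive-enumeration oracle guards its search space (≤10⁷ candidates)
and is exercised on ≤3-patient/≤2-linac/≤2-day/≤8-slot instances, where the
MILP must agree exactly, including on infeasibility. The sensitivity
experiment is reproduced at 66 patients / 2 linacs (the largest size the
undecomposed model handles comfortably): with the morning and late windows
widened to 150 minutes under the 25/50/25 split, the heuristic+MILP pipeline
books 0.0% of sessions outside the windows. The full-center run
(260 patients / 8 linacs / 4 clusters) takes hours of MIP time by nature;
the suite covers its ingredients instead — the pre-assignment balance bound
at 260 patients / 8 linacs and the cluster pipeline at smaller sizes — while
the full configuration remains available through the library and CLI.

## Known limitations

* The rest-day artifact above: literal fidelity of the constraint family was
  preferred over silently repairing it.
* The pre-assignment can fail on instances whose total volume exceeds
  capacity (it assumes enough fleet capacity exists); it reports the first
  unplaceable patient.
* Weekly capacity C_k treats the 3000-minute figure as a weekly denominator
  (600 min/day × 5 days at defaults) minus explicitly blocked slots.
* Decomposed runs are near-optimal, not optimal: the pre-assignment fixes
  each new patient's cluster, and tightness of the gap is only verified at
  sizes where the undecomposed optimum is computable.
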