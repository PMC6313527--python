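# Methods

## Problem

Degraded, salinizing wetlands are restored by planting vegetation — reed
beds and mixed or pure forest stands.  Each candidate *restoration measure*
`i` has a decision variable `x_i`, its planted area in km².  Planning data
for such projects (seedling prices, planting densities, ecological water
quotas, chloride-uptake efficiencies, carbon capacities, benefit rates,
budgets and targets) are bounded but otherwise unknown, so every coefficient
is modelled as a closed interval `a± = [a⁻, a⁺]` rather than a point value.
The planner's question is: which allocation of areas minimizes total
seedling investment while meeting the project's water, salinization-control,
carbon-sink, area, labor, and benefit requirements — and how much does the
answer move as the coefficients range over their intervals?

## Model

With `Q_i±` the seedling price (10⁴ CNY/plant) and `L_i±` the planting
density (plant/km²), the program is

    min f± = Σ_i Q_i± · L_i± · x_i±

subject to (one row each, in this fixed order):

| row | form | meaning |
|---|---|---|
| water | `Σ m_i± x_i± ≤ W₀± − (Wl± + Wm± + Ws± + Wa±)` | measure quotas plus fixed lake/marsh/soil/habitat water within the budget |
| salinization | `Σ h_i± c_i± M ω_i± x_i± ≥ N₀±` | chloride uptake meets the absorption target |
| carbon | `Σ C_i± x_i± ≥ C₀±` | carbon-sink capacity meets the target |
| area | `Σ x_i± ≤ A₀±` | total project area |
| labor | `Σ 100·Lk_i± x_i± ≤ L₀±` | labor demand within supply |
| ecological benefit | `Σ (PA_i±β_i± + PW_i±δ_i± + PC_i±ε_i±) x_i± ≥ V₀±` | microclimate + purification + conservation benefits reach the floor |
| social benefit | `Σ α_i± U_i± x_i± ≥ U₀±` | product value reaches the floor |

and `x_i± ≥ 0`.  Units are canonical and enforced at the file boundary:
money 10⁴ CNY, water 10⁴ m³, areas km².  Two conversions are fixed in code:
labor is entered in man-day/ha and scaled by exactly 100 ha/km², and the
chloride product `h·c·M` is in g/m², for which 1 (g/m²)·km² = 1 tonne, so
the salinization row needs no extra factor.  The fixed water terms are
counted once and moved to the right-hand side by interval subtraction
(summing them per measure would multiply the same physical water demand by
the number of measures).  The three ecological-benefit components are folded
into a single row because their sum is linear in `x`.

## Two-step solution algorithm

The interval program is decomposed into two crisp LPs.  Objective
coefficients must be sign-definite; indices are partitioned into a
nonnegative block (`k1` entries, zero-width zeros included) and a
nonpositive block.

*Favorable step* (step 1; targets `f⁺` for a maximization, `f⁻` for a
minimization): objective uses the optimistic bound of every `c_j`;
a canonical `≤` row uses `|a_ij|⁻ sign(a_ij⁻)` on the first block and
`|a_ij|⁺ sign(a_ij⁺)` on the second, with right-hand side `b⁺`.

*Unfavorable step* (step 2): all opposite bound choices, plus **linkage
bounds** tying it to the step-1 optimum `x*`: first-block variables are
bounded above by `x*_j`, second-block variables below.  The linkage is what
makes the two crisp solutions assemble into elementwise-ordered intervals
`x_opt,j = [x_j⁻, x_j⁺]` and `f_opt = [f⁻, f⁺]`.

Sense handling: `≥` rows are negated internally so the canonical `≤` rules
apply literally; this makes the favorable step use the loosest right-hand
side (`b⁻` for `≥` rows, `b⁺` for `≤` rows) and the unfavorable step the
opposite.  Minimization is solved by negating the objective, running the
maximize path, and mirroring the bounds back — so the `f⁻` sub-model is
solved first for a minimization, as required.  A constraint coefficient
straddling zero is allowed but logged as a warning: the bound-selection rule
is heuristic there.

Numerical choices: the crisp backend is HiGHS (`scipy.optimize.linprog`)
with feasibility/optimality tolerances of 1e-9; assembled bounds inverted by
less than 1e-7 (solver noise) are clamped to a degenerate interval, larger
inversions raise.  Degenerate optima are reported as the backend's vertex;
no canonicalization is attempted, so alternate optima may differ across
platforms in `x` (never in `f`).  A step-2 infeasibility is probed once
without the linkage bounds: if that relaxation is feasible the status is
reported as `linkage_infeasible`, and the program is never silently retried.

## What the algorithm does and does not guarantee

The favorable bound is a true corner realization of the coefficient box, so
on the minimize-cost class this package targets (nonnegative costs,
nonnegative technology rows) it equals the exact minimum of crisp optima.
The *unfavorable* bound is not exact in general:

* **Linkage conservatism.**  In `max c·x` with `c₁ = [1, 2]`,
  `c₂ = [1.5, 1.6]`, `x₁ + x₂ ≤ [4, 6]`, step 1 maximizes `2x₁ + 1.6x₂`
  and returns `x = (6, 0)`; the linkage then caps `x₂ ≤ 0` in step 2, which
  yields `f⁻ = 4`, while the cheapest realization's true optimum is
  `1.5 · 4 = 6`.  The assembled interval `[4, 12]` strictly encloses the
  exact range `[6, 12]`.  (This instance is a unit test.)
* **Linkage infeasibility.**  The step-2 feasible region (tightened rows
  plus linkage) can be empty even when every realization of the program is
  feasible; this surfaces as `linkage_infeasible` on a few percent of
  generated six-measure scenarios.
* **Mixed-sign objectives.**  With objective coefficients of both signs the
  sub-model bound-selection rule is a heuristic and the assembled interval
  need not even enclose the exact range.

Consequently the test suite asserts *equality* with the
endpoint-enumeration oracle only where it is deliberately checking the
exactness statement the method is often credited with; that check fails on
roughly a tenth of small random sign-definite instances and is kept as a
known-failing record of the method's conservatism.  The properties that do
hold on the minimize-cost class — exact favorable bound, enclosure of the
brute-force range, exact agreement in the crisp limit — are asserted as
green tests, and the acceptance script reports the measured exactness rate
and maximum deviation rather than assuming them.

## Oracles

`endpoint_oracle` solves every endpoint realization (degenerate entries
contribute one choice; at most 16 non-degenerate entries, i.e. 65,536 crisp
LPs) — for an LP, whose optimum is monotone piecewise in each coefficient,
the extreme optima over the box are attained at endpoint combinations, so
this is the exact range of crisp optima.  `mc_oracle` samples coefficients
uniformly and independently inside their intervals; intervals carry no
distribution information, and uniform sampling merely explores the box —
any sampled empirical range is a subset of the true range, so it checks
enclosure, never equality.

## Synthetic scenarios

`generate_scenario` emulates the *structure* of real restoration planning
data, not any particular site: coefficient midpoints are drawn from
realistic ranges (seedling prices 1–3 CNY/plant, densities 5·10⁴–2·10⁵
plant/km², water quotas 10–50·10⁴ m³/km², carbon capacities 500–2000 t/km²,
benefit rates 10–50·10⁴ CNY/km², uptake efficiencies 0.05–0.3, etc. — all
documented in `_COEFF_RANGES`), widened by a configurable relative
half-width (default 0.1), and every budget/target is anchored so a strictly
positive reference plan keeps at least 10% slack (default 15%) in every row
under that row's own worst-case realization.  Generated scenarios are
therefore feasible for every realization by construction; they do not
reproduce spatial correlation between coefficients, economies of scale, or
inter-annual dynamics, so green tests on them certify solver and model
mechanics, not ecological realism.  The scenario's seven-row structure is
fixed by the model, so the generator exposes no extra-constraint knob.

## Calibrated case-study fixture

The case study's coefficient tables were never published — only the
original recommended scheme (five measures, 174.66 km², investment 2593.41
·10⁴ CNY), the optimal interval plan (six measures), and the optimal
investment interval [2193.14, 2416.01]·10⁴ CNY.  The bundled fixture
(`data/case_study_synthetic.yaml`, built by `calibrate_case_study_fixture`)
therefore fits **crisp per-km² unit costs** by equality-constrained least
squares: three equations (the two optimal-investment bounds on the
published area bounds, and the original investment on the original plan) in
six unknowns, regularized toward a uniform cost so the underdetermined fit
is unique and reproducible; the fit is exact to float precision and all
costs come out positive (8.2–20.2 ·10⁴ CNY/km²).  The original scheme is
mapped onto the six-measure list with 0 km² for the one mixed-forest
measure absent from it.  All remaining coefficients are generator draws
with a fixed seed, with budgets/targets anchored so both published plans are
feasible.  The fixture never claims to be the case study's data, and the
published areas are inputs the calibration never alters.  Re-solving the
fixture does *not* return the published areas — recovering an unpublished
coefficient set for which the published plan is the exact argmin is an
inverse-optimization problem that is out of scope; the fixture's contract is
plan-evaluation arithmetic only.

The published §-level benefit-increase percentages quoted alongside the
case-study benefits are mutually inconsistent with the benefit values
themselves; the package reproduces neither and reports only quantities its
own arithmetic produces.

## Problem sizes used in validation

Solver-vs-oracle checks run on 220 random sign-definite instances with
`n, m ≤ 3` and at most 8 non-degenerate interval entries (≤256 crisp LPs
each), 50 generated six-measure scenarios with 1000 Monte-Carlo samples
each, and 100 all-degenerate instances for the crisp limit; the acceptance
script uses 120/30×300/100.  These sizes give stable rates while keeping
the whole validation in the low minutes on one CPU.

## Known limitations

* Interval dependency is ignored (no affine arithmetic): the same physical
  quantity appearing in several coefficients varies independently in the
  oracles and the model rows.
* No outward rounding — containment statements hold to solver tolerance
  (1e-9), not rigorously.
* No integer/mixed-integer, stochastic, or fuzzy extensions; no
  possibility-degree constraint semantics; single planning period.
* `x_opt` non-uniqueness at ties is resolved by the backend's vertex
  choice and is not canonicalized.
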