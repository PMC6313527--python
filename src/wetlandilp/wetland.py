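"""Wetland-restoration investment model.

A restoration scenario lists vegetation-planting measures (reed beds, mixed
or pure forest stands).  The decision variable for measure *i* is its planted
area ``x_i`` in km².  The model minimizes total seedling investment

    min f = sum_i  Q_i * L_i * x_i

with ``Q_i`` the seedling price (10^4 CNY/plant) and ``L_i`` the planting
density (plant/km²), subject to interval-valued resource and target rows:

* **water**: per-measure ecological water quotas plus the fixed lake, marsh,
  soil and wildlife-habitat requirements must not exceed the water budget;
* **salinization**: total chloride uptake (soil thickness x chloride
  concentration x molar mass x absorption efficiency x area) must reach the
  project's chloride-absorption target;
* **carbon**: the planted carbon-sink capacity must reach the carbon target;
* **area** and **labor** caps;
* **ecological benefit** (microclimate + water purification + soil/water
  conservation) and **social benefit** (yield x product value) floors.

All coefficients are intervals; the resulting program is solved with the
two-step engine (minimize, so the favorable ``f-`` sub-model first) and
evaluated into a :class:`PlanReport` with investment, benefit components,
and savings relative to the scenario's original (pre-optimization) scheme.

Units are fixed: money in 10^4 CNY, water in 10^4 m³, areas in km²; the
labor coefficient is entered in man-day/ha and converted internally with the
exact factor 100 ha/km².  The chloride product h·c·M is in g/m², and
1 (g/m²)·km² = 1 tonne, so no extra factor appears in the salinization row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .engine import ILPSolution, IntervalLinearProgram, solve_ilp
from .intervals import Interval, IntervalLike

__all__ = [
    "RestorationMeasure",
    "WetlandGlobals",
    "WetlandScenario",
    "PlanReport",
    "SalinizationSummary",
    "ScenarioError",
    "InfeasibleScenarioError",
    "ROW_NAMES",
    "build_ilp",
    "evaluate_plan",
    "savings",
    "salinization_summary",
    "solve_scenario",
]

PLANTING_PATTERNS = ("none", "mixed_forest", "pure_forest")

#: Fixed constraint-row order of the assembled program.
ROW_NAMES = (
    "water",
    "salinization",
    "carbon",
    "area",
    "labor",
    "ecological_benefit",
    "social_benefit",
)

MANDAY_PER_HA_TO_KM2 = 100.0  # 1 km² = 100 ha, exact


class ScenarioError(ValueError):
    """Ill-formed restoration scenario."""


class InfeasibleScenarioError(RuntimeError):
    """Scenario admits no plan satisfying all rows; carries diagnostics."""

    def __init__(self, message: str, diagnostics: Optional[list[str]] = None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


def _iv(value: IntervalLike, what: str, nonnegative: bool = True) -> Interval:
    v = Interval.coerce(value)
    if nonnegative and v.lower < 0:
        raise ScenarioError(f"{what} must be nonnegative, got [{v.lower}, {v.upper}]")
    return v


@dataclass(frozen=True)
class RestorationMeasure:
    """One planting measure and its per-km² interval coefficients."""

    name: str
    planting_pattern: str = "none"
    seedling_price: IntervalLike = 0.0       # Q, 10^4 CNY/plant
    planting_density: IntervalLike = 0.0     # L, plant/km²
    water_quota: IntervalLike = 0.0          # m, 10^4 m³/km²
    soil_thickness: IntervalLike = 0.0       # h, m
    chloride_conc: IntervalLike = 0.0        # c, mol/m³
    chloride_uptake_eff: IntervalLike = 0.0  # ω, dimensionless in [0, 1]
    carbon_capacity: IntervalLike = 0.0      # C, tonnes/km²
    labor_per_ha: IntervalLike = 0.0         # Lk, man-day/ha
    microclimate_rate: IntervalLike = 0.0    # PA, 10^4 CNY/km²
    microclimate_corr: IntervalLike = 1.0    # β
    purification_rate: IntervalLike = 0.0    # PW, 10^4 CNY/km²
    purification_corr: IntervalLike = 1.0    # δ
    conservation_rate: IntervalLike = 0.0    # PC, 10^4 CNY/km²
    conservation_corr: IntervalLike = 1.0    # ε
    yield_per_km2: IntervalLike = 0.0        # α, tonnes/km²
    product_value: IntervalLike = 0.0        # U, 10^4 CNY/tonne

    def __post_init__(self) -> None:
        if self.planting_pattern not in PLANTING_PATTERNS:
            raise ScenarioError(
                f"measure {self.name!r}: unknown planting pattern "
                f"{self.planting_pattern!r} (expected one of {PLANTING_PATTERNS})"
            )
        for fname in _MEASURE_INTERVAL_FIELDS:
            v = _iv(getattr(self, fname), f"measure {self.name!r}: {fname}")
            object.__setattr__(self, fname, v)
        eff = getattr(self, "chloride_uptake_eff")
        if eff.upper > 1.0:
            raise ScenarioError(
                f"measure {self.name!r}: chloride_uptake_eff must lie in [0, 1], "
                f"got [{eff.lower}, {eff.upper}]"
            )

    # derived per-km² interval coefficients -----------------------------
    @property
    def unit_cost(self) -> Interval:
        """Q·L: seedling investment per km² (10^4 CNY/km²)."""
        return self.seedling_price * self.planting_density

    def chloride_uptake(self, molar_mass: float) -> Interval:
        """h·c·M·ω: chloride removed per km² planted (tonnes/km²)."""
        return (
            self.soil_thickness
            * self.chloride_conc
            * molar_mass
            * self.chloride_uptake_eff
        )

    @property
    def labor_per_km2(self) -> Interval:
        return self.labor_per_ha * MANDAY_PER_HA_TO_KM2

    @property
    def ecological_rate(self) -> Interval:
        """PA·β + PW·δ + PC·ε: total ecological benefit per km²."""
        return (
            self.microclimate_rate * self.microclimate_corr
            + self.purification_rate * self.purification_corr
            + self.conservation_rate * self.conservation_corr
        )

    @property
    def social_rate(self) -> Interval:
        """α·U: economic product value per km²."""
        return self.yield_per_km2 * self.product_value


_MEASURE_INTERVAL_FIELDS = tuple(
    f for f in RestorationMeasure.__dataclass_fields__
    if f not in ("name", "planting_pattern")
)


@dataclass(frozen=True)
class WetlandGlobals:
    """Project-wide interval budgets and targets."""

    lake_water: IntervalLike = 0.0       # Wl, 10^4 m³
    marsh_water: IntervalLike = 0.0      # Wm
    soil_water: IntervalLike = 0.0       # Ws
    habitat_water: IntervalLike = 0.0    # Wa
    max_water: IntervalLike = 0.0        # W0, total water budget
    chloride_molar_mass: float = 35.45   # M, g/mol
    chloride_target: IntervalLike = 0.0  # N0, tonnes
    carbon_target: IntervalLike = 0.0    # C0, tonnes
    total_area: IntervalLike = 0.0       # A0, km²
    labor_supply: IntervalLike = 0.0     # L0, man-day
    eco_benefit_floor: IntervalLike = 0.0   # V0, 10^4 CNY
    econ_benefit_floor: IntervalLike = 0.0  # U0, 10^4 CNY

    def __post_init__(self) -> None:
        if not self.chloride_molar_mass > 0:
            raise ScenarioError(
                f"chloride_molar_mass must be positive, got {self.chloride_molar_mass}"
            )
        for fname in _GLOBAL_INTERVAL_FIELDS:
            object.__setattr__(self, fname, _iv(getattr(self, fname), fname))

    @property
    def fixed_water(self) -> Interval:
        """Wl + Wm + Ws + Wa, counted once (10^4 m³)."""
        return self.lake_water + self.marsh_water + self.soil_water + self.habitat_water


_GLOBAL_INTERVAL_FIELDS = tuple(
    f for f in WetlandGlobals.__dataclass_fields__ if f != "chloride_molar_mass"
)


@dataclass(frozen=True)
class WetlandScenario:
    measures: tuple[RestorationMeasure, ...]
    globals: WetlandGlobals
    original_plan: tuple[float, ...] = ()       # crisp areas, km²
    original_investment: float = 0.0            # 10^4 CNY
    name: str = "scenario"

    def __post_init__(self) -> None:
        object.__setattr__(self, "measures", tuple(self.measures))
        if not self.measures:
            raise ScenarioError("scenario needs at least one measure")
        plan = tuple(float(a) for a in self.original_plan)
        if plan and len(plan) != len(self.measures):
            raise ScenarioError(
                f"original_plan has {len(plan)} areas for "
                f"{len(self.measures)} measures"
            )
        if any(a < 0 for a in plan):
            raise ScenarioError("original_plan areas must be nonnegative")
        object.__setattr__(self, "original_plan", plan)
        if self.original_investment < 0:
            raise ScenarioError("original_investment must be nonnegative")

    @property
    def n_measures(self) -> int:
        return len(self.measures)


@dataclass(frozen=True)
class PlanReport:
    """Investment, benefit components, and savings for one planting plan.

    All money in 10^4 CNY; ``savings_pct`` in percent of the original
    investment.  Savings fields are ``None`` when the scenario has no
    positive original investment to compare against.
    """

    investment: Interval
    microclimate_benefit: Interval      # VA
    purification_benefit: Interval      # VW
    conservation_benefit: Interval      # VC
    ecological_benefit: Interval        # VA + VW + VC
    social_benefit: Interval
    savings_abs: Optional[Interval] = None
    savings_pct: Optional[Interval] = None


@dataclass(frozen=True)
class SalinizationSummary:
    """Severity-class areas (km²) and their percent shares of the total."""

    class_areas: tuple[float, ...]
    total_area: float
    shares_pct: tuple[float, ...]  # rounded to two decimals


# ---------------------------------------------------------------------------
# model assembly
# ---------------------------------------------------------------------------

def build_ilp(scenario: WetlandScenario) -> IntervalLinearProgram:
    """Assemble the minimize-investment interval LP for a scenario.

    Rows appear in the fixed order of :data:`ROW_NAMES`.  The fixed water
    requirements are counted once and moved to the right-hand side by
    interval subtraction, so the water row reads
    ``sum_i m_i x_i <= W0 - (Wl + Wm + Ws + Wa)``.
    """
    g = scenario.globals
    measures = scenario.measures

    c = [mm.unit_cost for mm in measures]
    water_rhs = g.max_water - g.fixed_water
    rows = [
        [mm.water_quota for mm in measures],
        [mm.chloride_uptake(g.chloride_molar_mass) for mm in measures],
        [mm.carbon_capacity for mm in measures],
        [Interval.point(1.0) for _ in measures],
        [mm.labor_per_km2 for mm in measures],
        [mm.ecological_rate for mm in measures],
        [mm.social_rate for mm in measures],
    ]
    rhs = [
        water_rhs,
        g.chloride_target,
        g.carbon_target,
        g.total_area,
        g.labor_supply,
        g.eco_benefit_floor,
        g.econ_benefit_floor,
    ]
    senses = ["le", "ge", "ge", "le", "le", "ge", "ge"]
    return IntervalLinearProgram(
        sense="minimize",
        c=c,
        A=rows,
        b=rhs,
        row_senses=senses,
        variable_names=[mm.name for mm in measures],
        row_names=list(ROW_NAMES),
    )


# ---------------------------------------------------------------------------
# plan evaluation
# ---------------------------------------------------------------------------

def savings(original_investment: float, investment: Interval) -> tuple[Interval, Interval]:
    """Absolute and percent savings of an investment interval vs a crisp baseline.

    ``savings_abs = [orig - investment.upper, orig - investment.lower]``; the
    percent form divides elementwise by the original investment.
    """
    if not original_investment > 0:
        raise ScenarioError("original investment must be positive to compute savings")
    sav = Interval(
        original_investment - investment.upper,
        original_investment - investment.lower,
    )
    pct = Interval(
        100.0 * sav.lower / original_investment,
        100.0 * sav.upper / original_investment,
    )
    return sav, pct


def evaluate_plan(
    scenario: WetlandScenario, areas: Sequence[IntervalLike]
) -> PlanReport:
    """Evaluate investment, benefits and savings of a (possibly interval) plan."""
    if len(areas) != scenario.n_measures:
        raise ScenarioError(
            f"plan has {len(areas)} areas for {scenario.n_measures} measures"
        )
    xs = [_iv(a, f"area[{j}]") for j, a in enumerate(areas)]

    zero = Interval.point(0.0)
    invest = va = vw = vc = social = zero
    for mm, x in zip(scenario.measures, xs):
        invest = invest + mm.unit_cost * x
        va = va + mm.microclimate_rate * mm.microclimate_corr * x
        vw = vw + mm.purification_rate * mm.purification_corr * x
        vc = vc + mm.conservation_rate * mm.conservation_corr * x
        social = social + mm.social_rate * x

    sav = pct = None
    if scenario.original_investment > 0:
        sav, pct = savings(scenario.original_investment, invest)
    return PlanReport(
        investment=invest,
        microclimate_benefit=va,
        purification_benefit=vw,
        conservation_benefit=vc,
        ecological_benefit=va + vw + vc,
        social_benefit=social,
        savings_abs=sav,
        savings_pct=pct,
    )


def salinization_summary(
    class_areas: Sequence[float],
) -> SalinizationSummary:
    """Total area and two-decimal percent shares of salinization severity classes."""
    areas = tuple(float(a) for a in class_areas)
    if any(a < 0 for a in areas):
        raise ScenarioError("class areas must be nonnegative")
    total = sum(areas)
    if total <= 0:
        raise ScenarioError("at least one class area must be positive")
    shares = tuple(round(100.0 * a / total, 2) for a in areas)
    return SalinizationSummary(class_areas=areas, total_area=total, shares_pct=shares)


# ---------------------------------------------------------------------------
# end-to-end solve
# ---------------------------------------------------------------------------

def _infeasibility_diagnostics(scenario: WetlandScenario) -> list[str]:
    """Name the rows that look unsatisfiable, checked at the loosest bounds."""
    ilp = build_ilp(scenario)
    g = scenario.globals
    area_cap = Interval.coerce(g.total_area).upper
    notes: list[str] = []
    for name, row, rhs, s in zip(ROW_NAMES, ilp.A, ilp.b, ilp.row_senses):
        if s == "ge":
            # best achievable lhs under the loosest realization, spending the
            # whole area cap on the most effective measure
            best = max(a.upper for a in row) * area_cap
            if best < rhs.lower:
                notes.append(
                    f"row {name!r}: even {area_cap} km² of the most effective "
                    f"measure yields {best:.6g} < required {rhs.lower:.6g}"
                )
        else:
            if rhs.upper < 0:
                notes.append(
                    f"row {name!r}: right-hand side [{rhs.lower:.6g}, "
                    f"{rhs.upper:.6g}] is negative — budget exhausted by fixed terms"
                )
    return notes


def solve_scenario(
    scenario: WetlandScenario,
) -> tuple[ILPSolution, PlanReport]:
    """Build, solve, and evaluate a scenario's optimal planting plan."""
    ilp = build_ilp(scenario)
    solution = solve_ilp(ilp)
    if not solution.ok:
        notes = _infeasibility_diagnostics(scenario)
        raise InfeasibleScenarioError(
            f"scenario {scenario.name!r} failed: step statuses "
            f"({solution.status_first}, {solution.status_second})"
            + ("; " + "; ".join(notes) if notes else ""),
            diagnostics=notes,
        )
    report = evaluate_plan(scenario, solution.x_opt)
    return solution, report
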