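"""Synthetic scenarios, random test programs, and the calibrated case-study fixture.

Three generators live here:

* :func:`generate_scenario` draws a random but *feasible-by-construction*
  wetland-restoration scenario: every per-measure coefficient gets a
  positive midpoint from a realistic range, is widened to an interval by a
  configurable half-width, and every budget/target row is anchored to a
  strictly positive reference plan with slack under its worst-case
  realization.
* :func:`random_ilp` draws small generic interval LPs (mixed senses,
  objective coefficients of either sign, nonnegative sign-definite
  technology matrix) for solver-vs-oracle validation.
* :func:`calibrate_case_study_fixture` builds a six-measure scenario whose
  per-km² planting costs are fitted by constrained least squares so that
  evaluating the published optimal plan of the shallow basket lake wetland
  restoration case study reproduces its published investment interval, and
  evaluating the original recommended scheme reproduces its published
  investment.  The fixture is **synthetic**: the case study's coefficient
  tables were never published, so everything except the published areas and
  investments is calibrated or defaulted, and the fixture never claims to
  be the original data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .engine import IntervalLinearProgram
from .intervals import Interval
from .wetland import (
    ROW_NAMES,
    RestorationMeasure,
    WetlandGlobals,
    WetlandScenario,
    evaluate_plan,
)

__all__ = [
    "GeneratorConfig",
    "generate_scenario",
    "random_ilp",
    "calibrate_case_study_fixture",
    "CASE_STUDY_MEASURE_NAMES",
    "CASE_STUDY_OPTIMAL_AREAS",
    "CASE_STUDY_ORIGINAL_PLAN",
    "CASE_STUDY_ORIGINAL_INVESTMENT",
    "CASE_STUDY_OPTIMAL_INVESTMENT",
]


# ---------------------------------------------------------------------------
# published case-study figures (plan evaluation inputs, not model coefficients)
# ---------------------------------------------------------------------------

CASE_STUDY_MEASURE_NAMES = (
    "Reed (Phragmites karka)",
    "Populus euphratica, Dryland willow (P&D)",
    "Populus euphratica, Elaeagnus angustifolia (P&E)",
    "Dryland willow",
    "Populus bolleana",
    "Elaeagnus angustifolia",
)

CASE_STUDY_PATTERNS = (
    "none",
    "mixed_forest",
    "mixed_forest",
    "pure_forest",
    "pure_forest",
    "pure_forest",
)

#: Published optimal planting areas (km²), lower/upper bounds per measure.
CASE_STUDY_OPTIMAL_AREAS = (
    (46.75, 46.75),
    (30.54, 37.25),
    (34.71, 34.71),
    (10.16, 15.97),
    (8.64, 16.48),
    (21.36, 21.36),
)

#: Original recommended scheme (km²) mapped onto the six-measure list; the
#: P&E mixed forest does not appear in the original scheme and gets 0.
CASE_STUDY_ORIGINAL_PLAN = (50.0, 25.45, 0.0, 40.37, 34.55, 24.29)

CASE_STUDY_ORIGINAL_INVESTMENT = 2593.41   # 10^4 CNY
CASE_STUDY_OPTIMAL_INVESTMENT = (2193.14, 2416.01)  # 10^4 CNY


class CalibrationError(RuntimeError):
    """Calibrated fixture failed to reproduce the published arithmetic."""


# ---------------------------------------------------------------------------
# random feasible scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorConfig:
    """Controls for :func:`generate_scenario`.

    ``interval_half_width`` is the relative half-width applied around every
    drawn midpoint (0 gives a crisp scenario); ``feasibility_slack`` is the
    minimum relative slack every constraint row keeps at the anchor plan
    under its own worst-case realization.
    """

    n_measures: int = 6
    interval_half_width: float = 0.1
    seed: int = 0
    feasibility_slack: float = 0.15
    anchor: Optional[tuple[float, ...]] = None  # km² per measure

    def __post_init__(self) -> None:
        if self.n_measures < 1:
            raise ValueError("n_measures must be >= 1")
        if not 0.0 <= self.interval_half_width < 0.5:
            raise ValueError("interval_half_width must lie in [0, 0.5)")
        if self.feasibility_slack < 0.1:
            raise ValueError("feasibility_slack must be >= 0.1")
        if self.anchor is not None and len(self.anchor) != self.n_measures:
            raise ValueError("anchor length must equal n_measures")


# Midpoint ranges for drawn coefficients, chosen to land generated scenarios
# in the same per-km² magnitudes as the case study (costs of order 10
# (10^4 CNY)/km², benefits of order 10-100 (10^4 CNY)/km²).
_COEFF_RANGES = {
    "seedling_price": (1e-4, 3e-4),     # 1-3 CNY per seedling
    "planting_density": (5e4, 2e5),     # plant/km²
    "water_quota": (10.0, 50.0),        # 10^4 m³/km² (100-500 mm of water)
    "soil_thickness": (0.3, 1.0),       # m
    "chloride_conc": (5.0, 30.0),       # mol/m³
    "chloride_uptake_eff": (0.05, 0.3),
    "carbon_capacity": (500.0, 2000.0),  # t/km² over the project period
    "labor_per_ha": (5.0, 30.0),        # man-day/ha
    "microclimate_rate": (10.0, 50.0),  # 10^4 CNY/km²
    "microclimate_corr": (0.5, 1.2),
    "purification_rate": (10.0, 50.0),
    "purification_corr": (0.5, 1.2),
    "conservation_rate": (10.0, 50.0),
    "conservation_corr": (0.5, 1.2),
    "yield_per_km2": (100.0, 1000.0),   # t/km²
    "product_value": (0.02, 0.1),       # 10^4 CNY/t
}


def _widen(mid: float, hw: float, cap: Optional[float] = None) -> Interval:
    lo, hi = mid * (1.0 - hw), mid * (1.0 + hw)
    if cap is not None:
        hi = min(hi, cap)
        lo = min(lo, hi)
    return Interval(lo, hi)


def generate_scenario(cfg: GeneratorConfig) -> WetlandScenario:
    """Draw a feasible wetland scenario; deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    hw = cfg.interval_half_width
    n = cfg.n_measures

    measures = []
    for i in range(n):
        fields = {}
        for fname, (lo, hi) in _COEFF_RANGES.items():
            mid = rng.uniform(lo, hi)
            cap = 1.0 if fname == "chloride_uptake_eff" else None
            fields[fname] = _widen(mid, hw, cap)
        measures.append(
            RestorationMeasure(
                name=f"measure_{i + 1}",
                planting_pattern=["none", "mixed_forest", "pure_forest"][i % 3],
                **fields,
            )
        )

    anchor = (
        np.asarray(cfg.anchor, dtype=float)
        if cfg.anchor is not None
        else rng.uniform(10.0, 40.0, n)
    )
    slack = cfg.feasibility_slack
    mm_mass = 35.45

    def worst_le(coeffs: Sequence[Interval]) -> float:
        return sum(c.upper * a for c, a in zip(coeffs, anchor))

    def worst_ge(coeffs: Sequence[Interval]) -> float:
        return sum(c.lower * a for c, a in zip(coeffs, anchor))

    def le_budget(lhs_worst: float) -> Interval:
        lo = lhs_worst * (1.0 + slack)
        return Interval(lo, lo * (1.0 + 2.0 * hw))

    def ge_target(lhs_worst: float) -> Interval:
        hi = lhs_worst / (1.0 + slack)
        return Interval(hi * max(0.0, 1.0 - 2.0 * hw), hi)

    fixed_water = [_widen(rng.uniform(100.0, 500.0), hw) for _ in range(4)]
    fixed_hi = sum(w.upper for w in fixed_water)
    g = WetlandGlobals(
        lake_water=fixed_water[0],
        marsh_water=fixed_water[1],
        soil_water=fixed_water[2],
        habitat_water=fixed_water[3],
        max_water=le_budget(worst_le([m.water_quota for m in measures]) + fixed_hi),
        chloride_molar_mass=mm_mass,
        chloride_target=ge_target(worst_ge([m.chloride_uptake(mm_mass) for m in measures])),
        carbon_target=ge_target(worst_ge([m.carbon_capacity for m in measures])),
        total_area=le_budget(float(anchor.sum())),
        labor_supply=le_budget(worst_le([m.labor_per_km2 for m in measures])),
        eco_benefit_floor=ge_target(worst_ge([m.ecological_rate for m in measures])),
        econ_benefit_floor=ge_target(worst_ge([m.social_rate for m in measures])),
    )

    # the original scheme of a generated scenario is the anchor plan itself,
    # priced at the upper coefficient bound (a deliberately costly baseline)
    original_cost = sum(
        m.unit_cost.upper * a for m, a in zip(measures, anchor)
    )
    return WetlandScenario(
        measures=tuple(measures),
        globals=g,
        original_plan=tuple(float(a) for a in anchor),
        original_investment=float(original_cost),
        name=f"synthetic_seed{cfg.seed}",
    )


# ---------------------------------------------------------------------------
# random generic interval LPs for solver validation
# ---------------------------------------------------------------------------

def random_ilp(
    seed: int,
    n: Optional[int] = None,
    m: Optional[int] = None,
    half_width: float = 0.25,
    degenerate_prob: float = 0.5,
    max_interval_entries: int = 8,
    nonnegative_costs: bool = False,
) -> IntervalLinearProgram:
    """Draw a small sign-definite interval LP anchored to a feasible point.

    The instance always contains an all-ones capacity row (which keeps every
    realization bounded); remaining rows get random ``<=``/``>=`` senses with
    right-hand sides placed so a positive anchor plan is feasible for every
    realization.  Objective coefficients carry random signs unless
    ``nonnegative_costs`` (the minimize-cost structure of the restoration
    model) is requested.  At most ``max_interval_entries`` coefficients stay
    non-degenerate, which keeps endpoint enumeration cheap.
    """
    rng = np.random.default_rng(seed)
    n = int(n if n is not None else rng.integers(1, 4))
    m = int(m if m is not None else rng.integers(1, 4))
    sense = "minimize" if nonnegative_costs else str(rng.choice(["maximize", "minimize"]))

    def draw_hw() -> float:
        return 0.0 if rng.random() < degenerate_prob else float(rng.uniform(0.0, half_width))

    def iv(mid: float) -> Interval:
        h = draw_hw()
        lo, hi = mid * (1.0 - h), mid * (1.0 + h)
        return Interval(min(lo, hi), max(lo, hi))

    c = []
    for _ in range(n):
        mag = rng.uniform(0.5, 3.0)
        if not nonnegative_costs and rng.random() < 0.5:
            mag = -mag
        c.append(iv(mag))

    anchor = rng.uniform(0.3, 1.5, n)
    A = [[Interval.point(1.0)] * n]
    b = [iv(float(anchor.sum()) * 1.3)]
    senses = ["le"]
    for _ in range(m - 1):
        row = [iv(rng.uniform(0.2, 2.0)) for _ in range(n)]
        if nonnegative_costs:
            s = "ge"
        else:
            s = str(rng.choice(["le", "ge"]))
        lhs_lo = sum(r.lower * a for r, a in zip(row, anchor))
        lhs_hi = sum(r.upper * a for r, a in zip(row, anchor))
        if s == "le":
            bmid = lhs_hi * 1.3
        else:
            bmid = lhs_lo * 0.7
        A.append(row)
        b.append(iv(bmid))
        senses.append(s)

    # cap the number of non-degenerate entries for cheap enumeration
    budget = max_interval_entries

    def cap(ivl: Interval) -> Interval:
        nonlocal budget
        if ivl.is_degenerate:
            return ivl
        if budget <= 0:
            return Interval.point(ivl.midpoint)
        budget -= 1
        return ivl

    c = [cap(v) for v in c]
    A = [[cap(v) for v in row] for row in A]
    b = [cap(v) for v in b]
    return IntervalLinearProgram(sense=sense, c=c, A=A, b=b, row_senses=senses)


# ---------------------------------------------------------------------------
# calibrated case-study fixture
# ---------------------------------------------------------------------------

def _calibrated_unit_costs() -> np.ndarray:
    """Fit crisp per-km² planting costs to the published plan arithmetic.

    Solves the equality-constrained least-squares problem: find k >= 0
    minimizing the distance to a uniform cost vector subject to

        k · x_lower = published optimal investment lower bound,
        k · x_upper = published optimal investment upper bound,
        k · x_orig  = published original investment.

    The uniform-cost prior makes the (underdetermined) fit unique and
    reproducible.
    """
    x_lo = np.array([a[0] for a in CASE_STUDY_OPTIMAL_AREAS])
    x_hi = np.array([a[1] for a in CASE_STUDY_OPTIMAL_AREAS])
    x_og = np.array(CASE_STUDY_ORIGINAL_PLAN)
    M = np.vstack([x_lo, x_hi, x_og])
    v = np.array([*CASE_STUDY_OPTIMAL_INVESTMENT, CASE_STUDY_ORIGINAL_INVESTMENT])
    rows = M.sum(axis=1)
    uniform = float(rows @ v) / float(rows @ rows)
    k0 = np.full(M.shape[1], uniform)
    k = k0 + M.T @ np.linalg.solve(M @ M.T, v - M @ k0)
    if k.min() < 0:
        raise CalibrationError(f"calibrated unit costs went negative: {k}")
    resid = float(np.abs(M @ k - v).max())
    if resid > 0.5:
        raise CalibrationError(f"calibration residual {resid} exceeds 0.5 (10^4 CNY)")
    return k


#: Assumed planting densities (plant/km²) used to split the calibrated
#: per-km² cost into price x density; reed beds are planted far denser than
#: forest stands.  Synthetic bookkeeping values, not case-study data.
_FIXTURE_DENSITIES = (5e5, 1e5, 1e5, 1e5, 1e5, 1e5)

_FIXTURE_RNG_SEED = 20180  # fixed: the fixture must be bit-reproducible


def calibrate_case_study_fixture() -> WetlandScenario:
    """Six-measure synthetic scenario calibrated to the published case study.

    Unit costs reproduce the published investment arithmetic (see
    :func:`_calibrated_unit_costs`); every other coefficient is a generator
    default drawn with a fixed seed, and all budget/target rows are anchored
    so that both the published optimal plan and the original scheme are
    feasible.  The published areas are never altered by calibration.
    """
    k = _calibrated_unit_costs()
    rng = np.random.default_rng(_FIXTURE_RNG_SEED)
    hw = 0.1
    mm_mass = 35.45

    measures = []
    for i, name in enumerate(CASE_STUDY_MEASURE_NAMES):
        fields = {}
        for fname, (lo, hi) in _COEFF_RANGES.items():
            if fname in ("seedling_price", "planting_density"):
                continue
            mid = rng.uniform(lo, hi)
            cap = 1.0 if fname == "chloride_uptake_eff" else None
            fields[fname] = _widen(mid, hw, cap)
        density = _FIXTURE_DENSITIES[i]
        measures.append(
            RestorationMeasure(
                name=name,
                planting_pattern=CASE_STUDY_PATTERNS[i],
                seedling_price=Interval.point(k[i] / density),
                planting_density=Interval.point(density),
                **fields,
            )
        )

    # budgets from the elementwise max of the two published plans (so both
    # satisfy the <= rows), targets from the elementwise min (so both meet
    # the >= rows), each with worst-case slack
    x_hi = np.array([a[1] for a in CASE_STUDY_OPTIMAL_AREAS])
    x_lo = np.array([a[0] for a in CASE_STUDY_OPTIMAL_AREAS])
    x_og = np.array(CASE_STUDY_ORIGINAL_PLAN)
    hi_anchor = np.maximum(x_hi, x_og)
    lo_anchor = np.minimum(x_lo, x_og)
    slack = 0.15

    def le_budget(coeffs) -> Interval:
        worst = sum(c.upper * a for c, a in zip(coeffs, hi_anchor))
        lo = worst * (1.0 + slack)
        return Interval(lo, lo * (1.0 + 2.0 * hw))

    def ge_target(coeffs) -> Interval:
        worst = sum(c.lower * a for c, a in zip(coeffs, lo_anchor))
        hi = worst / (1.0 + slack)
        return Interval(hi * (1.0 - 2.0 * hw), hi)

    fixed_water = [_widen(rng.uniform(100.0, 500.0), hw) for _ in range(4)]
    g = WetlandGlobals(
        lake_water=fixed_water[0],
        marsh_water=fixed_water[1],
        soil_water=fixed_water[2],
        habitat_water=fixed_water[3],
        max_water=Interval(
            le_budget([m.water_quota for m in measures]).lower
            + sum(w.upper for w in fixed_water),
            le_budget([m.water_quota for m in measures]).upper
            + sum(w.upper for w in fixed_water) * (1.0 + hw),
        ),
        chloride_molar_mass=mm_mass,
        chloride_target=ge_target([m.chloride_uptake(mm_mass) for m in measures]),
        carbon_target=ge_target([m.carbon_capacity for m in measures]),
        total_area=le_budget([Interval.point(1.0)] * 6),
        labor_supply=le_budget([m.labor_per_km2 for m in measures]),
        eco_benefit_floor=ge_target([m.ecological_rate for m in measures]),
        econ_benefit_floor=ge_target([m.social_rate for m in measures]),
    )

    scenario = WetlandScenario(
        measures=tuple(measures),
        globals=g,
        original_plan=CASE_STUDY_ORIGINAL_PLAN,
        original_investment=CASE_STUDY_ORIGINAL_INVESTMENT,
        name="case_study_calibrated_synthetic",
    )

    # build-time verification of the calibration contract
    opt = evaluate_plan(
        scenario, [Interval(lo, hi) for lo, hi in CASE_STUDY_OPTIMAL_AREAS]
    ).investment
    og = evaluate_plan(scenario, list(CASE_STUDY_ORIGINAL_PLAN)).investment
    err = max(
        abs(opt.lower - CASE_STUDY_OPTIMAL_INVESTMENT[0]),
        abs(opt.upper - CASE_STUDY_OPTIMAL_INVESTMENT[1]),
        abs(og.midpoint - CASE_STUDY_ORIGINAL_INVESTMENT),
    )
    if err > 0.5:
        raise CalibrationError(
            f"fixture fails to reproduce published investments (max error {err})"
        )
    return scenario
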