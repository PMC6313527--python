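"""Scenario files, report tables, and solution dumps.

Scenarios are YAML (or JSON — every JSON document is valid YAML) with every
interval written as a two-element ``[lower, upper]`` array and a sidecar
``units`` block that must match the canonical units exactly; units are
*enforced*, never converted, at the file boundary.  Unknown keys are
rejected with the path to the offending key.

Reports are CSV: one row per measure (name, pattern, area bounds at two
decimals) followed by summary rows (investment, savings, benefit
components); written bytes are deterministic given identical inputs.
"""

from __future__ import annotations

import csv
import json
from importlib import resources
from pathlib import Path
from typing import Any, Optional, Union

import yaml

from .engine import ILPSolution
from .intervals import Interval, IntervalError
from .wetland import (
    PlanReport,
    RestorationMeasure,
    ScenarioError,
    WetlandGlobals,
    WetlandScenario,
    _GLOBAL_INTERVAL_FIELDS,
    _MEASURE_INTERVAL_FIELDS,
)

__all__ = [
    "CANONICAL_UNITS",
    "SCHEMA_VERSION",
    "ScenarioFileError",
    "load_scenario",
    "write_scenario",
    "write_report",
    "read_report",
    "solution_to_dict",
    "write_solution_json",
]

SCHEMA_VERSION = "1"


def bundled_scenario_path(name: str = "case_study_synthetic.yaml") -> Path:
    """Path of a scenario file shipped with the package.

    The default is the synthetic six-measure fixture calibrated to the
    published case-study plan arithmetic.
    """
    return Path(resources.files("wetlandilp").joinpath("data", name))

CANONICAL_UNITS: dict[str, str] = {
    # per-measure coefficients
    "seedling_price": "10^4 CNY/plant",
    "planting_density": "plant/km^2",
    "water_quota": "10^4 m^3/km^2",
    "soil_thickness": "m",
    "chloride_conc": "mol/m^3",
    "chloride_uptake_eff": "1",
    "carbon_capacity": "t/km^2",
    "labor_per_ha": "man-day/ha",
    "microclimate_rate": "10^4 CNY/km^2",
    "microclimate_corr": "1",
    "purification_rate": "10^4 CNY/km^2",
    "purification_corr": "1",
    "conservation_rate": "10^4 CNY/km^2",
    "conservation_corr": "1",
    "yield_per_km2": "t/km^2",
    "product_value": "10^4 CNY/t",
    # globals
    "lake_water": "10^4 m^3",
    "marsh_water": "10^4 m^3",
    "soil_water": "10^4 m^3",
    "habitat_water": "10^4 m^3",
    "max_water": "10^4 m^3",
    "chloride_molar_mass": "g/mol",
    "chloride_target": "t",
    "carbon_target": "t",
    "total_area": "km^2",
    "labor_supply": "man-day",
    "eco_benefit_floor": "10^4 CNY",
    "econ_benefit_floor": "10^4 CNY",
    # plan blocks
    "original_plan": "km^2",
    "original_investment": "10^4 CNY",
}

_TOP_KEYS = {
    "schema_version",
    "name",
    "units",
    "measures",
    "globals",
    "original_plan",
    "original_investment",
    "solver",
}
_MEASURE_KEYS = {"name", "planting_pattern", *_MEASURE_INTERVAL_FIELDS}
_GLOBAL_KEYS = {"chloride_molar_mass", *_GLOBAL_INTERVAL_FIELDS}
_SOLVER_KEYS = {"backend", "tolerance"}


class ScenarioFileError(ValueError):
    """Malformed scenario file; message carries the path to the key."""


def _reject_unknown(mapping: dict, allowed: set, where: str) -> None:
    unknown = sorted(set(mapping) - allowed)
    if unknown:
        raise ScenarioFileError(f"{where}: unknown key(s) {unknown}")


def _parse_interval(value: Any, where: str) -> Interval:
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return Interval.point(value)
    if isinstance(value, (list, tuple)) and len(value) == 2:
        lo, hi = value
        if all(isinstance(v, (int, float)) and not isinstance(v, bool) for v in (lo, hi)):
            try:
                return Interval(float(lo), float(hi))
            except IntervalError as exc:
                raise ScenarioFileError(f"{where}: {exc}") from None
    raise ScenarioFileError(
        f"{where}: expected a number or a two-element [lower, upper] array, "
        f"got {value!r}"
    )


def _parse_number(value: Any, where: str) -> float:
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    raise ScenarioFileError(f"{where}: expected a number, got {value!r}")


def _check_units(units: Any) -> None:
    if not isinstance(units, dict):
        raise ScenarioFileError("units: expected a mapping of field -> unit string")
    for key, unit in sorted(units.items()):
        if key not in CANONICAL_UNITS:
            raise ScenarioFileError(f"units.{key}: unknown field")
        if unit != CANONICAL_UNITS[key]:
            raise ScenarioFileError(
                f"units.{key}: expected {CANONICAL_UNITS[key]!r}, got {unit!r} "
                "(units are enforced, not converted)"
            )


def load_scenario(path: Union[str, Path]) -> WetlandScenario:
    """Load and fully validate a scenario file (YAML or JSON)."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ScenarioFileError(f"{path}: not parseable as YAML/JSON: {exc}") from None
    if not isinstance(raw, dict):
        raise ScenarioFileError(f"{path}: top level must be a mapping")
    _reject_unknown(raw, _TOP_KEYS, "top level")
    for required in ("schema_version", "units", "measures", "globals"):
        if required not in raw:
            raise ScenarioFileError(f"missing required key {required!r}")
    if str(raw["schema_version"]) != SCHEMA_VERSION:
        raise ScenarioFileError(
            f"schema_version: expected {SCHEMA_VERSION!r}, got {raw['schema_version']!r}"
        )
    _check_units(raw["units"])

    if not isinstance(raw["measures"], list) or not raw["measures"]:
        raise ScenarioFileError("measures: expected a non-empty list")
    measures = []
    for idx, block in enumerate(raw["measures"]):
        where = f"measures[{idx}]"
        if not isinstance(block, dict):
            raise ScenarioFileError(f"{where}: expected a mapping")
        _reject_unknown(block, _MEASURE_KEYS, where)
        if "name" not in block:
            raise ScenarioFileError(f"{where}: missing required key 'name'")
        fields = {
            "name": str(block["name"]),
            "planting_pattern": str(block.get("planting_pattern", "none")),
        }
        for fname in _MEASURE_INTERVAL_FIELDS:
            if fname in block:
                fields[fname] = _parse_interval(block[fname], f"{where}.{fname}")
        try:
            measures.append(RestorationMeasure(**fields))
        except ScenarioError as exc:
            raise ScenarioFileError(f"{where}: {exc}") from None

    gblock = raw["globals"]
    if not isinstance(gblock, dict):
        raise ScenarioFileError("globals: expected a mapping")
    _reject_unknown(gblock, _GLOBAL_KEYS, "globals")
    gfields: dict[str, Any] = {}
    for fname in _GLOBAL_INTERVAL_FIELDS:
        if fname in gblock:
            gfields[fname] = _parse_interval(gblock[fname], f"globals.{fname}")
    if "chloride_molar_mass" in gblock:
        gfields["chloride_molar_mass"] = _parse_number(
            gblock["chloride_molar_mass"], "globals.chloride_molar_mass"
        )
    try:
        g = WetlandGlobals(**gfields)
    except ScenarioError as exc:
        raise ScenarioFileError(f"globals: {exc}") from None

    plan = raw.get("original_plan", [])
    if plan and (
        not isinstance(plan, list)
        or not all(isinstance(a, (int, float)) and not isinstance(a, bool) for a in plan)
    ):
        raise ScenarioFileError("original_plan: expected a list of numbers")
    invest = raw.get("original_investment", 0.0)
    invest = _parse_number(invest, "original_investment")

    if "solver" in raw:
        solver = raw["solver"]
        if not isinstance(solver, dict):
            raise ScenarioFileError("solver: expected a mapping")
        _reject_unknown(solver, _SOLVER_KEYS, "solver")
        backend = solver.get("backend", "highs")
        if backend != "highs":
            raise ScenarioFileError(f"solver.backend: unsupported backend {backend!r}")

    try:
        return WetlandScenario(
            measures=tuple(measures),
            globals=g,
            original_plan=tuple(float(a) for a in plan),
            original_investment=invest,
            name=str(raw.get("name", path.stem)),
        )
    except ScenarioError as exc:
        raise ScenarioFileError(str(exc)) from None


def _iv_pair(v: Interval) -> list[float]:
    return [float(v.lower), float(v.upper)]


def scenario_to_dict(scenario: WetlandScenario) -> dict:
    doc: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "name": scenario.name,
        "units": dict(CANONICAL_UNITS),
        "measures": [],
        "globals": {},
    }
    for mm in scenario.measures:
        block: dict[str, Any] = {
            "name": mm.name,
            "planting_pattern": mm.planting_pattern,
        }
        for fname in _MEASURE_INTERVAL_FIELDS:
            block[fname] = _iv_pair(getattr(mm, fname))
        doc["measures"].append(block)
    for fname in _GLOBAL_INTERVAL_FIELDS:
        doc["globals"][fname] = _iv_pair(getattr(scenario.globals, fname))
    doc["globals"]["chloride_molar_mass"] = float(scenario.globals.chloride_molar_mass)
    if scenario.original_plan:
        doc["original_plan"] = [float(a) for a in scenario.original_plan]
    if scenario.original_investment:
        doc["original_investment"] = float(scenario.original_investment)
    return doc


def write_scenario(scenario: WetlandScenario, path: Union[str, Path]) -> None:
    """Serialize a scenario as YAML (deterministic layout)."""
    Path(path).write_text(
        yaml.safe_dump(scenario_to_dict(scenario), sort_keys=False, width=100)
    )


# ---------------------------------------------------------------------------
# report table
# ---------------------------------------------------------------------------

_REPORT_HEADER = ("name", "planting_pattern", "lower", "upper")


def _fmt(v: float) -> str:
    return f"{v:.2f}"


def write_report(
    solution: ILPSolution,
    report: PlanReport,
    path: Union[str, Path],
    scenario: Optional[WetlandScenario] = None,
) -> None:
    """Write the plan report CSV: per-measure area rows, then summary rows.

    Numeric cells are rounded to two decimals in the file; in-memory values
    keep full precision.
    """
    if solution.x_opt is None:
        raise ValueError(
            f"cannot report an unsolved program (statuses "
            f"{solution.status_first}, {solution.status_second})"
        )
    names = [f"x{j + 1}" for j in range(len(solution.x_opt))]
    patterns = ["-"] * len(names)
    if scenario is not None:
        names = [mm.name for mm in scenario.measures]
        patterns = [
            "-" if mm.planting_pattern == "none" else mm.planting_pattern
            for mm in scenario.measures
        ]
    rows: list[tuple[str, str, str, str]] = []
    for name, pattern, x in zip(names, patterns, solution.x_opt):
        rows.append((name, pattern, _fmt(x.lower), _fmt(x.upper)))

    def summary(name: str, iv: Optional[Interval]) -> None:
        if iv is not None:
            rows.append((name, "", _fmt(iv.lower), _fmt(iv.upper)))

    summary("total_investment_1e4CNY", report.investment)
    summary("savings_1e4CNY", report.savings_abs)
    summary("savings_pct", report.savings_pct)
    summary("microclimate_benefit_1e4CNY", report.microclimate_benefit)
    summary("purification_benefit_1e4CNY", report.purification_benefit)
    summary("conservation_benefit_1e4CNY", report.conservation_benefit)
    summary("ecological_benefit_1e4CNY", report.ecological_benefit)
    summary("social_benefit_1e4CNY", report.social_benefit)

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_REPORT_HEADER)
        writer.writerows(rows)


def read_report(path: Union[str, Path]) -> list[dict]:
    """Parse a report CSV back into a list of row dicts (bounds as floats)."""
    with open(path, newline="") as fh:
        out = []
        for row in csv.DictReader(fh):
            row["lower"] = float(row["lower"])
            row["upper"] = float(row["upper"])
            out.append(row)
        return out


# ---------------------------------------------------------------------------
# solution dump
# ---------------------------------------------------------------------------

def solution_to_dict(solution: ILPSolution) -> dict:
    return {
        "sense": solution.sense,
        "f": _iv_pair(solution.f_opt) if solution.f_opt is not None else None,
        "x": [_iv_pair(x) for x in solution.x_opt] if solution.x_opt else None,
        "status_first": solution.status_first,
        "status_second": solution.status_second,
    }


def write_solution_json(solution: ILPSolution, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(solution_to_dict(solution), indent=2) + "\n")
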