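"""Brute-force validation oracles for the two-step solver.

Both oracles replace every interval coefficient of a program by crisp
realizations and solve the resulting ordinary LPs, yielding an empirical
range of crisp optima that the two-step interval solution is checked
against:

* :func:`endpoint_oracle` enumerates *every* combination of interval
  endpoints (degenerate entries contribute a single choice).  For the four
  monotone-by-parts coefficient positions of an LP the extreme optima are
  attained at endpoint combinations, so on small sign-definite programs this
  is the exact range of optima.
* :func:`mc_oracle` samples realizations uniformly and independently inside
  each interval; its empirical range is always a subset of the true range,
  so it checks *enclosure* by the solver's interval, never equality.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .engine import (
    CrispSubModel,
    ILPSolution,
    IntervalLinearProgram,
    solve_lp,
)
from .intervals import Interval

__all__ = ["OracleResult", "endpoint_oracle", "mc_oracle"]

#: Hard cap on enumerated interval entries (2^16 = 65,536 crisp LPs).
MAX_ENDPOINT_ENTRIES = 16


@dataclass(frozen=True)
class OracleResult:
    """Empirical optimum range over crisp realizations of an interval LP."""

    empirical_min: Optional[float]
    empirical_max: Optional[float]
    n_realizations: int
    statuses: dict  # status -> count over realizations
    verdict: Optional[str]  # "enclosed" | "violated" | None when not comparable
    margin: Optional[float]  # min slack of the enclosure, negative if violated

    @property
    def all_optimal(self) -> bool:
        return self.statuses.get("optimal", 0) == self.n_realizations


def _crisp_lp(ilp: IntervalLinearProgram, c, A, b) -> CrispSubModel:
    n = ilp.n
    return CrispSubModel(
        sense=ilp.sense,
        c=np.asarray(c, dtype=float),
        A=np.asarray(A, dtype=float).reshape(ilp.m, n),
        b=np.asarray(b, dtype=float),
        row_senses=tuple(ilp.row_senses),
        lb=np.zeros(n),
        ub=np.full(n, np.inf),
        tag="f_plus",
    )


def _finish(
    optima: list[float],
    statuses: Counter,
    n_real: int,
    solution: Optional[ILPSolution],
    tol: float,
) -> OracleResult:
    emp_min = min(optima) if optima else None
    emp_max = max(optima) if optima else None
    verdict = margin = None
    if (
        solution is not None
        and solution.f_opt is not None
        and emp_min is not None
    ):
        f = solution.f_opt
        margin = min(emp_min - f.lower, f.upper - emp_max)
        verdict = "enclosed" if margin >= -tol else "violated"
    return OracleResult(
        empirical_min=emp_min,
        empirical_max=emp_max,
        n_realizations=n_real,
        statuses=dict(statuses),
        verdict=verdict,
        margin=margin,
    )


def _interval_entries(ilp: IntervalLinearProgram):
    """Flat list of (kind, index, Interval) for every coefficient position."""
    entries = []
    for j, cj in enumerate(ilp.c):
        entries.append(("c", j, cj))
    for i, row in enumerate(ilp.A):
        for j, a in enumerate(row):
            entries.append(("A", (i, j), a))
    for i, bi in enumerate(ilp.b):
        entries.append(("b", i, bi))
    return entries


def _realize(ilp: IntervalLinearProgram, values: dict) -> CrispSubModel:
    c = [values[("c", j)] for j in range(ilp.n)]
    A = [[values[("A", (i, j))] for j in range(ilp.n)] for i in range(ilp.m)]
    b = [values[("b", i)] for i in range(ilp.m)]
    return _crisp_lp(ilp, c, A, b)


def endpoint_oracle(
    ilp: IntervalLinearProgram,
    solution: Optional[ILPSolution] = None,
    tol: float = 1e-6,
) -> OracleResult:
    """Exhaustive endpoint enumeration of an interval LP's crisp optima.

    Refuses programs with more than :data:`MAX_ENDPOINT_ENTRIES`
    non-degenerate interval entries; use :func:`mc_oracle` for those.
    """
    entries = _interval_entries(ilp)
    nondeg = [(kind, idx, iv) for kind, idx, iv in entries if not iv.is_degenerate]
    if len(nondeg) > MAX_ENDPOINT_ENTRIES:
        raise ValueError(
            f"{len(nondeg)} non-degenerate interval entries exceed the "
            f"enumeration cap of {MAX_ENDPOINT_ENTRIES} (2^{len(nondeg)} crisp "
            "LPs); use mc_oracle for larger programs"
        )
    base = {(kind, idx): iv.lower for kind, idx, iv in entries}
    statuses: Counter = Counter()
    optima: list[float] = []
    n_real = 0
    for combo in itertools.product(
        *[(iv.lower, iv.upper) for _, _, iv in nondeg]
    ):
        values = dict(base)
        for (kind, idx, _), v in zip(nondeg, combo):
            values[(kind, idx)] = v
        res = solve_lp(_realize(ilp, values))
        statuses[res.status] += 1
        n_real += 1
        if res.status == "optimal":
            optima.append(res.objective)
    return _finish(optima, statuses, n_real, solution, tol)


def mc_oracle(
    ilp: IntervalLinearProgram,
    samples: int,
    seed: int,
    solution: Optional[ILPSolution] = None,
    tol: float = 1e-6,
) -> OracleResult:
    """Monte-Carlo realization sampling of an interval LP's crisp optima.

    Each coefficient is drawn uniformly and independently within its
    interval (the intervals carry no distribution information; uniform
    sampling merely explores the range, and range containment is
    distribution-free).  Deterministic given ``seed``.
    """
    if samples < 1:
        raise ValueError("samples must be >= 1")
    rng = np.random.default_rng(seed)
    entries = _interval_entries(ilp)
    statuses: Counter = Counter()
    optima: list[float] = []
    for _ in range(samples):
        values = {
            (kind, idx): rng.uniform(iv.lower, iv.upper) if not iv.is_degenerate
            else iv.lower
            for kind, idx, iv in entries
        }
        res = solve_lp(_realize(ilp, values))
        statuses[res.status] += 1
        if res.status == "optimal":
            optima.append(res.objective)
    return _finish(optima, statuses, samples, solution, tol)
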