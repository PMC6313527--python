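"""Interval linear programs and the two-step best/worst solution algorithm.

An interval linear program (ILP) is an ordinary LP in which the objective
coefficients, the constraint matrix, and the right-hand sides are all
interval numbers.  The solution is itself interval-valued: an objective range
``[f_opt.lower, f_opt.upper]`` and a planting/allocation range per decision
variable.

The solver decomposes the ILP into two crisp sub-models:

* a *favorable* sub-model built from the optimistic bound of every
  coefficient (largest profits / cheapest costs, loosest requirements), and
* an *unfavorable* sub-model built from the opposite bounds, with *linkage
  bounds* tying its variables to the favorable optimum so that the two crisp
  solutions assemble into a consistent interval solution.

For a maximization the favorable sub-model targets ``f+`` and is solved
first; for a minimization ``f-`` comes first.  Minimization is handled by
negating the objective, solving the maximize path, and mirroring the
resulting bounds back.  Constraint rows keep their senses; ``>=`` rows are
negated internally so that the canonical ``<=`` construction rules apply
literally, which makes the favorable sub-model use the loosest right-hand
side (``b-`` for ``>=`` rows, ``b+`` for ``<=`` rows) and the unfavorable
sub-model the opposite.

The assembled interval always *encloses* the exact range of crisp optima
over coefficient realizations on the sign-definite instances this package
targets, and its favorable bound is exact; the unfavorable bound can be
conservative when the linkage bounds bind (see docs/methods.md).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.optimize import linprog

from .intervals import Interval, interval_abs, sign

__all__ = [
    "IntervalLinearProgram",
    "SignPartition",
    "CrispSubModel",
    "LPResult",
    "ILPSolution",
    "ModelError",
    "partition_objective",
    "build_favorable_submodel",
    "build_unfavorable_submodel",
    "solve_lp",
    "solve_ilp",
]

logger = logging.getLogger(__name__)

Sense = Literal["maximize", "minimize"]
RowSense = Literal["le", "ge"]

#: LP feasibility/optimality tolerance requested of the HiGHS backend.
LP_TOLERANCE = 1e-9
#: Slack allowed when asserting interval ordering of the assembled solution;
#: inversions smaller than this are clamped to a degenerate interval.
ASSEMBLY_TOLERANCE = 1e-7


class ModelError(ValueError):
    """Ill-formed interval linear program."""


class PropagationError(RuntimeError):
    """Step-2 construction requested before step 1 was solved to optimality."""


def _as_interval_vector(values: Sequence) -> list[Interval]:
    return [Interval.coerce(v) for v in values]


@dataclass(frozen=True)
class IntervalLinearProgram:
    """Interval-coefficient LP ``opt c·x  s.t.  A x {<=,>=} b, x >= 0``.

    Parameters
    ----------
    sense:
        ``"maximize"`` or ``"minimize"``.
    c, A, b:
        Interval objective vector (length n), constraint grid (m x n) and
        right-hand side (length m).  Scalars and 2-sequences are coerced.
    row_senses:
        One of ``"le"``/``"ge"`` per row.
    allow_sign_indefinite:
        Permit objective coefficients straddling zero (partitioned by
        midpoint sign, with a logged warning).  Off by default because the
        two-step decomposition assumes sign-definite objective coefficients.
    """

    sense: Sense
    c: list[Interval]
    A: list[list[Interval]]
    b: list[Interval]
    row_senses: list[RowSense]
    allow_sign_indefinite: bool = False
    variable_names: Optional[list[str]] = None
    row_names: Optional[list[str]] = None

    def __post_init__(self) -> None:
        if self.sense not in ("maximize", "minimize"):
            raise ModelError(f"unknown sense {self.sense!r}")
        object.__setattr__(self, "c", _as_interval_vector(self.c))
        object.__setattr__(self, "A", [_as_interval_vector(row) for row in self.A])
        object.__setattr__(self, "b", _as_interval_vector(self.b))
        object.__setattr__(self, "row_senses", list(self.row_senses))
        n, m = self.n, self.m
        if n == 0:
            raise ModelError("objective has no variables")
        for i, row in enumerate(self.A):
            if len(row) != n:
                raise ModelError(f"row {i} has {len(row)} entries, expected {n}")
        if len(self.b) != m or len(self.row_senses) != m:
            raise ModelError(
                f"rhs/sense lengths ({len(self.b)}, {len(self.row_senses)}) "
                f"do not match {m} rows"
            )
        for s in self.row_senses:
            if s not in ("le", "ge"):
                raise ModelError(f"unknown row sense {s!r}")
        if self.variable_names is not None and len(self.variable_names) != n:
            raise ModelError("variable_names length mismatch")
        if self.row_names is not None and len(self.row_names) != m:
            raise ModelError("row_names length mismatch")

    @property
    def n(self) -> int:
        return len(self.c)

    @property
    def m(self) -> int:
        return len(self.A)


@dataclass(frozen=True)
class SignPartition:
    """Split of objective indices by coefficient sign.

    ``pos_idx`` holds indices with nonnegative interval coefficients (zero
    counts as nonnegative), ``neg_idx`` the strictly nonpositive rest;
    ``k1 = len(pos_idx)``.
    """

    k1: int
    pos_idx: tuple[int, ...]
    neg_idx: tuple[int, ...]


@dataclass(frozen=True)
class CrispSubModel:
    """One crisp LP of the two-step decomposition, in original orientation."""

    sense: Sense
    c: np.ndarray
    A: np.ndarray
    b: np.ndarray
    row_senses: tuple[RowSense, ...]
    lb: np.ndarray
    ub: np.ndarray  # +inf where unbounded
    tag: Literal["f_plus", "f_minus"]


@dataclass(frozen=True)
class LPResult:
    status: str  # optimal | infeasible | unbounded | error:<detail>
    objective: Optional[float]
    x: Optional[np.ndarray]


@dataclass(frozen=True)
class ILPSolution:
    """Assembled two-step solution: interval objective and variables."""

    sense: Sense
    f_opt: Optional[Interval]
    x_opt: Optional[list[Interval]]
    status_first: str
    status_second: str
    submodels: tuple[Optional[CrispSubModel], Optional[CrispSubModel]] = (None, None)

    @property
    def ok(self) -> bool:
        return self.status_first == "optimal" and self.status_second == "optimal"


# ---------------------------------------------------------------------------
# sign partition
# ---------------------------------------------------------------------------

def partition_objective(ilp: IntervalLinearProgram) -> SignPartition:
    """Split objective coefficients into nonnegative and nonpositive blocks.

    A coefficient straddling zero violates the decomposition's premise and is
    an error unless ``allow_sign_indefinite`` is set, in which case it is
    assigned by its midpoint sign with a logged warning.
    """
    pos: list[int] = []
    neg: list[int] = []
    for j, cj in enumerate(ilp.c):
        if cj.is_nonnegative:
            pos.append(j)
        elif cj.is_nonpositive:
            neg.append(j)
        elif ilp.allow_sign_indefinite:
            logger.warning(
                "objective coefficient %d = [%g, %g] straddles zero; "
                "assigning by midpoint sign — two-step bounds may be loose",
                j, cj.lower, cj.upper,
            )
            (pos if cj.midpoint >= 0 else neg).append(j)
        else:
            raise ModelError(
                f"objective coefficient {j} = [{cj.lower}, {cj.upper}] straddles "
                "zero; the two-step decomposition requires sign-definite "
                "objective coefficients (set allow_sign_indefinite to override)"
            )
    return SignPartition(k1=len(pos), pos_idx=tuple(pos), neg_idx=tuple(neg))


# ---------------------------------------------------------------------------
# internal canonical form: maximize, all rows <=
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Canonical:
    c: list[Interval]
    A: list[list[Interval]]
    b: list[Interval]
    negated_obj: bool          # True when the original sense is minimize
    negated_rows: tuple[bool, ...]  # True where an original >= row was flipped


def _canonicalize(ilp: IntervalLinearProgram) -> _Canonical:
    negated_obj = ilp.sense == "minimize"
    c = [-cj for cj in ilp.c] if negated_obj else list(ilp.c)
    A: list[list[Interval]] = []
    b: list[Interval] = []
    flipped: list[bool] = []
    for row, rhs, s in zip(ilp.A, ilp.b, ilp.row_senses):
        if s == "ge":
            A.append([-a for a in row])
            b.append(-rhs)
            flipped.append(True)
        else:
            A.append(list(row))
            b.append(rhs)
            flipped.append(False)
    for i, row in enumerate(A):
        for j, a in enumerate(row):
            if not a.is_sign_definite and not a.is_degenerate:
                logger.warning(
                    "constraint coefficient (%d, %d) = [%g, %g] straddles zero; "
                    "two-step bound selection is heuristic there",
                    i, j, a.lower, a.upper,
                )
    return _Canonical(c, A, b, negated_obj, tuple(flipped))


def _internal_partition(ilp: IntervalLinearProgram, part: SignPartition) -> tuple[set, set]:
    """Partition of the *canonical* (possibly negated) objective."""
    if ilp.sense == "minimize":
        return set(part.neg_idx), set(part.pos_idx)
    return set(part.pos_idx), set(part.neg_idx)


def _row_coefficient(a: Interval, favorable_block: bool) -> float:
    """Coefficient-bound choice of the canonical ``<=`` rows.

    The favorable block uses ``|a|- * sign(a-)``, the other ``|a|+ * sign(a+)``.
    """
    aa = interval_abs(a)
    if favorable_block:
        return aa.lower * sign(a.lower)
    return aa.upper * sign(a.upper)


def _build_step(
    ilp: IntervalLinearProgram,
    part: SignPartition,
    *,
    step: int,
    first_x: Optional[np.ndarray] = None,
) -> CrispSubModel:
    """Build the crisp sub-model for step 1 (favorable) or step 2 (unfavorable).

    The construction happens in the canonical maximize/``<=`` form and the
    result is presented back in the original orientation (sense and row
    senses of the input program).
    """
    canon = _canonicalize(ilp)
    pos, _neg = _internal_partition(ilp, part)
    n, m = ilp.n, ilp.m
    favorable = step == 1

    c_int = np.empty(n)
    for j, cj in enumerate(canon.c):
        c_int[j] = cj.upper if favorable else cj.lower

    A_int = np.empty((m, n))
    for i in range(m):
        for j in range(n):
            in_pos = j in pos
            # step 1: pos block takes the favorable bound choice; step 2 the
            # opposite.  The neg block mirrors the pos block within each step.
            A_int[i, j] = _row_coefficient(canon.A[i][j], in_pos == favorable)
    b_int = np.array([bi.upper if favorable else bi.lower for bi in canon.b])

    lb = np.zeros(n)
    ub = np.full(n, np.inf)
    if not favorable:
        if first_x is None:
            raise PropagationError("step-2 sub-model requires the step-1 solution")
        for j in range(n):
            if j in pos:
                ub[j] = first_x[j]   # linkage: bounded above by step-1 optimum
            else:
                lb[j] = first_x[j]   # linkage: bounded below by step-1 optimum

    # present in original orientation
    c_out = -c_int if canon.negated_obj else c_int
    A_out = A_int.copy()
    b_out = b_int.copy()
    for i, was_flipped in enumerate(canon.negated_rows):
        if was_flipped:
            A_out[i] = -A_out[i]
            b_out[i] = -b_out[i]

    if ilp.sense == "maximize":
        tag = "f_plus" if favorable else "f_minus"
    else:
        tag = "f_minus" if favorable else "f_plus"
    return CrispSubModel(
        sense=ilp.sense,
        c=c_out,
        A=A_out,
        b=b_out,
        row_senses=tuple(ilp.row_senses),
        lb=lb,
        ub=ub,
        tag=tag,
    )


def build_favorable_submodel(
    ilp: IntervalLinearProgram, part: SignPartition
) -> CrispSubModel:
    """Step-1 sub-model: ``f+`` for a maximization, ``f-`` for a minimization."""
    return _build_step(ilp, part, step=1)


def build_unfavorable_submodel(
    ilp: IntervalLinearProgram,
    part: SignPartition,
    first_x: Sequence[float],
) -> CrispSubModel:
    """Step-2 sub-model with linkage bounds derived from the step-1 optimum."""
    return _build_step(ilp, part, step=2, first_x=np.asarray(first_x, dtype=float))


# ---------------------------------------------------------------------------
# crisp backend
# ---------------------------------------------------------------------------

_STATUS = {0: "optimal", 1: "error:iteration limit", 2: "infeasible", 3: "unbounded"}


def solve_lp(sub: CrispSubModel) -> LPResult:
    """Solve one crisp sub-model with the HiGHS backend.

    Returns the optimum in the sub-model's own orientation (a maximization
    reports the maximum).  Backend failures surface as ``error:<detail>``.
    """
    minimize = sub.sense == "minimize"
    c = sub.c if minimize else -sub.c
    rows = []
    rhs = []
    for row, b, s in zip(sub.A, sub.b, sub.row_senses):
        if s == "le":
            rows.append(row)
            rhs.append(b)
        else:
            rows.append(-row)
            rhs.append(-b)
    bounds = [
        (lo, None if np.isinf(hi) else hi) for lo, hi in zip(sub.lb, sub.ub)
    ]
    try:
        res = linprog(
            c,
            A_ub=np.asarray(rows) if rows else None,
            b_ub=np.asarray(rhs) if rhs else None,
            bounds=bounds,
            method="highs",
            options={
                "primal_feasibility_tolerance": LP_TOLERANCE,
                "dual_feasibility_tolerance": LP_TOLERANCE,
            },
        )
    except Exception as exc:  # pragma: no cover - defensive
        return LPResult(status=f"error:{exc}", objective=None, x=None)
    status = _STATUS.get(res.status, f"error:{res.message}")
    if status != "optimal":
        return LPResult(status=status, objective=None, x=None)
    value = res.fun if minimize else -res.fun
    return LPResult(status="optimal", objective=float(value), x=np.asarray(res.x))


# ---------------------------------------------------------------------------
# two-step driver
# ---------------------------------------------------------------------------

def _ordered_interval(lo: float, hi: float, what: str) -> Interval:
    if lo > hi:
        if lo - hi > ASSEMBLY_TOLERANCE:
            raise RuntimeError(
                f"{what}: bounds inverted beyond tolerance ({lo} > {hi})"
            )
        mid = 0.5 * (lo + hi)
        lo = hi = mid
    return Interval(lo, hi)


def solve_ilp(ilp: IntervalLinearProgram) -> ILPSolution:
    """Solve an interval LP by the two-step decomposition.

    For a maximization the ``f+`` sub-model is solved first, then the linked
    ``f-`` sub-model; a minimization solves ``f-`` first.  If either crisp
    solve fails, the failing status is reported and no interval is assembled;
    a step-2 infeasibility caused purely by the linkage bounds is reported as
    ``linkage_infeasible`` (and is not retried with relaxed bounds).
    """
    part = partition_objective(ilp)
    sub1 = build_favorable_submodel(ilp, part)
    res1 = solve_lp(sub1)
    if res1.status != "optimal":
        return ILPSolution(
            sense=ilp.sense,
            f_opt=None,
            x_opt=None,
            status_first=res1.status,
            status_second="not_run",
            submodels=(sub1, None),
        )
    sub2 = build_unfavorable_submodel(ilp, part, res1.x)
    res2 = solve_lp(sub2)
    status2 = res2.status
    if status2 == "infeasible":
        # distinguish: would step 2 be feasible without the linkage bounds?
        probe = CrispSubModel(
            sense=sub2.sense,
            c=sub2.c,
            A=sub2.A,
            b=sub2.b,
            row_senses=sub2.row_senses,
            lb=np.zeros(ilp.n),
            ub=np.full(ilp.n, np.inf),
            tag=sub2.tag,
        )
        if solve_lp(probe).status == "optimal":
            status2 = "linkage_infeasible"
    if status2 != "optimal":
        return ILPSolution(
            sense=ilp.sense,
            f_opt=None,
            x_opt=None,
            status_first=res1.status,
            status_second=status2,
            submodels=(sub1, sub2),
        )

    if ilp.sense == "maximize":
        f_opt = _ordered_interval(res2.objective, res1.objective, "objective")
    else:
        f_opt = _ordered_interval(res1.objective, res2.objective, "objective")

    # Within each block, one step contributes the variable's upper bound and
    # the other its lower bound; which is which flips with the sense.
    internal_pos, _ = _internal_partition(ilp, part)
    x_opt: list[Interval] = []
    for j in range(ilp.n):
        x1, x2 = float(res1.x[j]), float(res2.x[j])
        if j in internal_pos:
            xi = _ordered_interval(x2, x1, f"x[{j}]")
        else:
            xi = _ordered_interval(x1, x2, f"x[{j}]")
        x_opt.append(xi)

    return ILPSolution(
        sense=ilp.sense,
        f_opt=f_opt,
        x_opt=x_opt,
        status_first=res1.status,
        status_second=status2,
        submodels=(sub1, sub2),
    )
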