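"""Closed-interval scalars and their arithmetic.

An :class:`Interval` ``[lo, hi]`` models a quantity whose value is bounded but
whose distribution within the bounds is unknown.  All model coefficients in
this package (prices, densities, water quotas, benefit rates, ...) are
intervals; a degenerate interval ``lo == hi`` behaves exactly like the crisp
scalar it encloses.

The binary operations return the exact range of ``x * y`` over all pairs of
points drawn from the operands; for ``+ - × ÷`` that range is attained at
endpoint combinations, so endpoint enumeration is exact.  Order relations use
the strong partial order ``x <= y  iff  x.lower <= y.lower and
x.upper <= y.upper`` — no possibility-degree semantics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Union

__all__ = [
    "Interval",
    "make_interval",
    "interval_binary",
    "interval_abs",
    "interval_order",
    "sign",
]

Scalar = Union[int, float]


class IntervalError(ValueError):
    """Invalid interval construction or operation."""


@dataclass(frozen=True)
class Interval:
    """Closed real interval ``[lower, upper]`` with ``lower <= upper``."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        lo = float(self.lower)
        hi = float(self.upper)
        if not (math.isfinite(lo) and math.isfinite(hi)):
            raise IntervalError(f"interval bounds must be finite, got [{lo}, {hi}]")
        if lo > hi:
            raise IntervalError(
                f"interval lower bound {lo} exceeds upper bound {hi}"
            )
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)

    # -- constructors -------------------------------------------------
    @classmethod
    def point(cls, value: Scalar) -> "Interval":
        """Degenerate (crisp) interval ``[value, value]``."""
        return cls(float(value), float(value))

    @classmethod
    def coerce(cls, value: "IntervalLike") -> "Interval":
        if isinstance(value, Interval):
            return value
        if isinstance(value, (int, float)):
            return cls.point(value)
        lo, hi = value  # two-element sequence
        return cls(float(lo), float(hi))

    # -- descriptive properties ---------------------------------------
    @property
    def width(self) -> float:
        return self.upper - self.lower

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lower + self.upper)

    @property
    def is_degenerate(self) -> bool:
        return self.lower == self.upper

    def contains(self, t: Scalar) -> bool:
        return self.lower <= t <= self.upper

    def contains_zero(self) -> bool:
        return self.lower <= 0.0 <= self.upper

    def issubset(self, other: "Interval") -> bool:
        return other.lower <= self.lower and self.upper <= other.upper

    # -- sign classification (nonneg/nonpos in the interval sense) ----
    @property
    def is_nonnegative(self) -> bool:
        return self.lower >= 0.0

    @property
    def is_nonpositive(self) -> bool:
        return self.upper <= 0.0

    @property
    def is_sign_definite(self) -> bool:
        return self.is_nonnegative or self.is_nonpositive

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other: "IntervalLike") -> "Interval":
        o = Interval.coerce(other)
        return Interval(self.lower + o.lower, self.upper + o.upper)

    __radd__ = __add__

    def __sub__(self, other: "IntervalLike") -> "Interval":
        o = Interval.coerce(other)
        return Interval(self.lower - o.upper, self.upper - o.lower)

    def __rsub__(self, other: "IntervalLike") -> "Interval":
        return Interval.coerce(other).__sub__(self)

    def __mul__(self, other: "IntervalLike") -> "Interval":
        o = Interval.coerce(other)
        p = (
            self.lower * o.lower,
            self.lower * o.upper,
            self.upper * o.lower,
            self.upper * o.upper,
        )
        return Interval(min(p), max(p))

    __rmul__ = __mul__

    def __truediv__(self, other: "IntervalLike") -> "Interval":
        o = Interval.coerce(other)
        if o.contains_zero():
            raise IntervalError(
                f"division by interval [{o.lower}, {o.upper}] containing zero"
            )
        p = (
            self.lower / o.lower,
            self.lower / o.upper,
            self.upper / o.lower,
            self.upper / o.upper,
        )
        return Interval(min(p), max(p))

    def __rtruediv__(self, other: "IntervalLike") -> "Interval":
        return Interval.coerce(other).__truediv__(self)

    def __neg__(self) -> "Interval":
        return Interval(-self.upper, -self.lower)

    def __abs__(self) -> "Interval":
        return interval_abs(self)

    # -- strong order --------------------------------------------------
    def __le__(self, other: "IntervalLike") -> bool:
        o = Interval.coerce(other)
        return self.lower <= o.lower and self.upper <= o.upper

    def __lt__(self, other: "IntervalLike") -> bool:
        o = Interval.coerce(other)
        return self.lower < o.lower and self.upper < o.upper

    def __ge__(self, other: "IntervalLike") -> bool:
        return Interval.coerce(other).__le__(self)

    def __gt__(self, other: "IntervalLike") -> bool:
        return Interval.coerce(other).__lt__(self)

    def __repr__(self) -> str:  # compact, round-trippable
        return f"Interval({self.lower!r}, {self.upper!r})"


IntervalLike = Union[Interval, Scalar, Iterable[Scalar]]


def make_interval(lo: Scalar, hi: Scalar) -> Interval:
    """Construct ``[lo, hi]``; raises :class:`IntervalError` if ``lo > hi``."""
    return Interval(float(lo), float(hi))


_BINARY: dict[str, Callable[[Interval, Interval], Interval]] = {
    "add": Interval.__add__,
    "sub": Interval.__sub__,
    "mul": Interval.__mul__,
    "div": Interval.__truediv__,
}


def interval_binary(op: str, x: IntervalLike, y: IntervalLike) -> Interval:
    """Apply one of ``{add, sub, mul, div}`` to two intervals.

    The result is the exact range of the operation over all point pairs;
    division by an interval containing zero raises :class:`IntervalError`.
    """
    try:
        fn = _BINARY[op]
    except KeyError:
        raise IntervalError(f"unknown interval operation {op!r}") from None
    return fn(Interval.coerce(x), Interval.coerce(y))


def interval_abs(x: IntervalLike) -> Interval:
    """Range of ``|t|`` for ``t`` in ``x``.

    Sign-definite intervals follow the usual rules ``|x| = x`` (nonnegative)
    and ``|x| = -x`` (nonpositive); an interval straddling zero maps to
    ``[0, max(-lower, upper)]``, the true range of the absolute value.
    """
    xi = Interval.coerce(x)
    if xi.is_nonnegative:
        return xi
    if xi.is_nonpositive:
        return -xi
    return Interval(0.0, max(-xi.lower, xi.upper))


_ORDER: dict[str, Callable[[Interval, Interval], bool]] = {
    "le": Interval.__le__,
    "lt": Interval.__lt__,
    "ge": Interval.__ge__,
    "gt": Interval.__gt__,
}


def interval_order(rel: str, x: IntervalLike, y: IntervalLike) -> bool:
    """Strong order relation: ``le`` holds iff both bounds are ordered."""
    try:
        fn = _ORDER[rel]
    except KeyError:
        raise IntervalError(f"unknown order relation {rel!r}") from None
    return fn(Interval.coerce(x), Interval.coerce(y))


def sign(v: Scalar) -> int:
    """Signum with ``sign(0) = 0`` (zero coefficients drop out of sub-model rows)."""
    if v > 0:
        return 1
    if v < 0:
        return -1
    return 0
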