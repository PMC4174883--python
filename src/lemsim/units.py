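"""Dimensions, units and dimensional quantities.

Every physical quantity in a model document is a pure SI magnitude tagged
with a dimension: a 7-tuple of integer exponents over the SI base
dimensions, in the fixed canonical order

    (mass, length, time, current, temperature, amount, luminous intensity)

Units bind a symbol to a dimension together with a power of ten and an
optional scale and offset, so that

    si_value = value * scale * 10**power10 + offset

Offsets exist only for affine units such as degrees Fahrenheit; they are
legal only in direct parameter assignment, never inside compound unit
definitions or expressions, because affine units break the linearity that
dimension algebra relies on.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

__all__ = [
    "Dimension",
    "Unit",
    "Quantity",
    "PhysicalConstant",
    "DIMENSIONLESS",
    "TIME",
    "dim_combine",
    "dim_power",
    "parse_quantity",
    "format_quantity",
    "UnitError",
]

#: Number of SI base dimensions; the canonical exponent order is
#: (M, L, T, I, Theta, N, J).
N_BASE_DIMENSIONS = 7

#: Attribute names accepted in documents for each base-dimension slot.
BASE_DIMENSION_ATTRS = ("m", "l", "t", "i", "k", "n", "j")


class UnitError(ValueError):
    """Raised for malformed quantities, unknown units or dimension misuse."""


@dataclass(frozen=True)
class Dimension:
    """A named 7-tuple of integer SI base-dimension exponents.

    Equality and hashing are by exponents only: two dimensions with the
    same exponents are interchangeable regardless of their names.
    """

    name: str
    exponents: tuple[int, int, int, int, int, int, int]

    def __post_init__(self) -> None:
        if len(self.exponents) != N_BASE_DIMENSIONS:
            raise UnitError(
                f"dimension {self.name!r} needs {N_BASE_DIMENSIONS} exponents, "
                f"got {len(self.exponents)}"
            )
        if not all(isinstance(e, int) for e in self.exponents):
            raise UnitError(f"dimension {self.name!r} has non-integer exponents")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dimension):
            return NotImplemented
        return self.exponents == other.exponents

    def __hash__(self) -> int:
        return hash(self.exponents)

    @property
    def is_dimensionless(self) -> bool:
        return all(e == 0 for e in self.exponents)

    def describe(self) -> str:
        """Human-readable exponent string, e.g. ``m^-1 l^-2 t^3 i^2``."""
        if self.is_dimensionless:
            return "dimensionless"
        parts = [
            f"{sym}^{e}" if e != 1 else sym
            for sym, e in zip(BASE_DIMENSION_ATTRS, self.exponents)
            if e != 0
        ]
        return " ".join(parts)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Dimension({self.name!r}, {self.describe()})"


DIMENSIONLESS = Dimension("none", (0, 0, 0, 0, 0, 0, 0))
TIME = Dimension("time", (0, 0, 1, 0, 0, 0, 0))


def dim_combine(a: Dimension, b: Dimension, op: str = "multiply") -> Dimension:
    """Combine two dimensions by exponent-wise sum (multiply) or difference
    (divide).  The result's name is synthesized; equality is by exponents."""
    if op == "multiply":
        exps = tuple(x + y for x, y in zip(a.exponents, b.exponents))
        name = f"({a.name}*{b.name})"
    elif op == "divide":
        exps = tuple(x - y for x, y in zip(a.exponents, b.exponents))
        name = f"({a.name}/{b.name})"
    else:
        raise UnitError(f"unknown dimension operation {op!r}")
    return Dimension(name, exps)  # type: ignore[arg-type]


def dim_power(a: Dimension, k: int) -> Dimension:
    """Raise a dimension to an integer power, exponent-wise."""
    if not isinstance(k, int) or isinstance(k, bool):
        raise UnitError(f"dimension exponent must be an integer, got {k!r}")
    return Dimension(f"({a.name}^{k})", tuple(e * k for e in a.exponents))  # type: ignore[arg-type]


@dataclass(frozen=True)
class Unit:
    """A unit symbol bound to a dimension with power-of-ten scaling.

    ``offset`` is expressed in SI units and may only be nonzero for units
    meant for direct assignment (e.g. Fahrenheit); such units are rejected
    wherever linearity is required.
    """

    symbol: str
    dimension: Dimension
    power10: int = 0
    scale: float = 1.0
    offset: float = 0.0

    def to_si(self, value: float) -> float:
        return value * self.scale * 10.0 ** self.power10 + self.offset

    def from_si(self, si_value: float) -> float:
        return (si_value - self.offset) / (self.scale * 10.0 ** self.power10)

    @property
    def is_affine(self) -> bool:
        return self.offset != 0.0


@dataclass(frozen=True)
class Quantity:
    """A magnitude stored in SI units plus its dimension."""

    magnitude: float
    dimension: Dimension

    def __post_init__(self) -> None:
        if not math.isfinite(self.magnitude):
            raise UnitError(f"non-finite magnitude {self.magnitude!r}")


@dataclass(frozen=True)
class PhysicalConstant:
    """A named immutable quantity, e.g. the elementary charge."""

    name: str
    quantity: Quantity


_QUANTITY_RE = re.compile(
    r"""^\s*
        (?P<num>[+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?)
        \s*
        (?P<unit>[^\s]*)
        \s*$""",
    re.VERBOSE,
)


def parse_quantity(text: str, registry: dict[str, Unit] | None = None) -> Quantity:
    """Parse ``"<number><unit symbol>"`` (or a bare number) into an SI quantity.

    Bare numbers are dimensionless.  Unit symbols are looked up
    case-sensitively in ``registry``; scale, power of ten and offset are
    applied on conversion.
    """
    m = _QUANTITY_RE.match(text)
    if m is None:
        raise UnitError(f"malformed quantity {text!r}")
    value = float(m.group("num"))
    symbol = m.group("unit")
    if not symbol:
        return Quantity(value, DIMENSIONLESS)
    if registry is None or symbol not in registry:
        raise UnitError(f"unknown unit symbol {symbol!r} in {text!r}")
    unit = registry[symbol]
    return Quantity(unit.to_si(value), unit.dimension)


def format_quantity(q: Quantity, unit: Unit | None = None) -> str:
    """Render a quantity in the given unit; inverse of :func:`parse_quantity`."""
    if unit is None:
        if not q.dimension.is_dimensionless:
            raise UnitError(
                f"cannot format dimensional quantity ({q.dimension.describe()}) "
                "without a unit"
            )
        return _fmt_num(q.magnitude)
    if unit.dimension != q.dimension:
        raise UnitError(
            f"dimension mismatch: quantity is {q.dimension.describe()}, "
            f"unit {unit.symbol!r} is {unit.dimension.describe()}"
        )
    return f"{_fmt_num(unit.from_si(q.magnitude))} {unit.symbol}"


def _fmt_num(x: float) -> str:
    """Shortest round-tripping decimal; integers rendered without a dot."""
    if x == int(x) and abs(x) < 1e16:
        return str(int(x))
    return repr(x)


def standard_dimensions() -> dict[str, Dimension]:
    """Dimension registry for the seven SI bases plus dimensionless.

    Documents declare their own compound dimensions; these are seeds any
    registry starts from.
    """
    base = {
        "none": DIMENSIONLESS,
        "mass": Dimension("mass", (1, 0, 0, 0, 0, 0, 0)),
        "length": Dimension("length", (0, 1, 0, 0, 0, 0, 0)),
        "time": TIME,
        "current": Dimension("current", (0, 0, 0, 1, 0, 0, 0)),
        "temperature": Dimension("temperature", (0, 0, 0, 0, 1, 0, 0)),
        "amount": Dimension("amount", (0, 0, 0, 0, 0, 1, 0)),
        "luminosity": Dimension("luminosity", (0, 0, 0, 0, 0, 0, 1)),
    }
    return base
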