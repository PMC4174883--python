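"""The mathematical expression grammar used inside Dynamics elements.

The grammar is C-like, except relational and logical operators are spelled
in Fortran style (``.lt.``, ``.gt.``, ``.leq.``, ``.geq.``, ``.eq.``,
``.neq.``, ``.and.``, ``.or.``) so they survive XML attribute encoding.
Precedence, loosest first::

    .or.  <  .and.  <  relational  <  + -  <  * /  <  unary -  <  ^ (right)

Boolean-valued sub-expressions are only legal where a condition is
expected; a relational operator nested inside arithmetic is a parse-time
error.  Built-in functions: exp, log, ln, sqrt, sin, cos, tan, sinh, cosh,
tanh, abs, ceil, floor and random(x), the last drawing uniformly from
[0, x) using the simulation's seeded generator.

The removable singularity of the exponential-linear rate form
``x / (1 - exp(-x))`` is guarded at parse time: the pattern is rewritten
into a dedicated node that evaluates the two-term Taylor form ``1 + x/2``
for ``|x| < 1e-7`` and the exact form elsewhere.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Callable, Mapping

from .units import DIMENSIONLESS, Dimension, dim_combine, dim_power

__all__ = [
    "parse_expression",
    "eval_expression",
    "infer_dimension",
    "to_text",
    "compile_expression",
    "free_symbols",
    "ExpressionError",
    "DimensionMismatch",
    "Literal",
    "Symbol",
    "Unary",
    "Binary",
    "Call",
    "ExpLinear",
]


class ExpressionError(ValueError):
    """Syntax or evaluation error, annotated with the offending text."""


class DimensionMismatch(ExpressionError):
    """Dimensional inconsistency found while checking an expression."""


# --------------------------------------------------------------------------
# AST


@dataclass(frozen=True)
class Node:
    pass


@dataclass(frozen=True)
class Literal(Node):
    value: float


@dataclass(frozen=True)
class Symbol(Node):
    name: str


@dataclass(frozen=True)
class Unary(Node):
    op: str  # only "-"
    operand: Node


@dataclass(frozen=True)
class Binary(Node):
    op: str  # + - * / ^ or .lt. .gt. .leq. .geq. .eq. .neq. .and. .or.
    left: Node
    right: Node


@dataclass(frozen=True)
class Call(Node):
    func: str
    args: tuple[Node, ...]


@dataclass(frozen=True)
class ExpLinear(Node):
    """Guarded ``x / (1 - exp(-x))``; continuous through x = 0."""

    operand: Node


RELATIONAL_OPS = {".lt.", ".gt.", ".leq.", ".geq.", ".eq.", ".neq."}
LOGICAL_OPS = {".and.", ".or."}
BOOLEAN_OPS = RELATIONAL_OPS | LOGICAL_OPS
#: accepted input aliases -> canonical spelling
_RELATIONAL_ALIASES = {".le.": ".leq.", ".ge.": ".geq."}

FUNCTIONS: dict[str, Callable[[float], float]] = {
    "exp": math.exp,
    "log": math.log,  # natural log, as in the reference interpreters
    "ln": math.log,
    "sqrt": math.sqrt,
    "sin": math.sin,
    "cos": math.cos,
    "tan": math.tan,
    "sinh": math.sinh,
    "cosh": math.cosh,
    "tanh": math.tanh,
    "abs": abs,
    "ceil": math.ceil,
    "floor": math.floor,
}
RANDOM_FUNC = "random"


# --------------------------------------------------------------------------
# Tokenizer

_TOKEN_RE = re.compile(
    r"""
    (?P<num>(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?)
  | (?P<dotop>\.(?:lt|gt|leq|geq|le|ge|eq|neq|and|or)\.)
  | (?P<name>[A-Za-z_][A-Za-z0-9_]*)
  | (?P<op>[-+*/^(),])
  | (?P<ws>\s+)
  | (?P<bad>.)
    """,
    re.VERBOSE,
)


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens: list[tuple[str, str, int]] = []
    for m in _TOKEN_RE.finditer(text):
        kind = m.lastgroup
        if kind == "ws":
            continue
        if kind == "bad":
            raise ExpressionError(
                f"unexpected character {m.group()!r} at position {m.start()} in {text!r}"
            )
        tok = m.group()
        if kind == "dotop":
            tok = _RELATIONAL_ALIASES.get(tok, tok)
        tokens.append((kind, tok, m.start()))
    return tokens


# --------------------------------------------------------------------------
# Recursive-descent parser


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.pos = 0

    def peek(self) -> tuple[str, str, int] | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> tuple[str, str, int]:
        tok = self.peek()
        if tok is None:
            raise ExpressionError(f"unexpected end of expression in {self.text!r}")
        self.pos += 1
        return tok

    def expect(self, value: str) -> None:
        tok = self.peek()
        if tok is None or tok[1] != value:
            where = tok[2] if tok else len(self.text)
            raise ExpressionError(
                f"expected {value!r} at position {where} in {self.text!r}"
            )
        self.pos += 1

    # precedence climbing, loosest first
    def parse_or(self) -> Node:
        node = self.parse_and()
        while (tok := self.peek()) and tok[1] == ".or.":
            self.next()
            node = Binary(".or.", node, self.parse_and())
        return node

    def parse_and(self) -> Node:
        node = self.parse_relational()
        while (tok := self.peek()) and tok[1] == ".and.":
            self.next()
            node = Binary(".and.", node, self.parse_relational())
        return node

    def parse_relational(self) -> Node:
        node = self.parse_additive()
        tok = self.peek()
        if tok and tok[1] in RELATIONAL_OPS:
            self.next()
            node = Binary(tok[1], node, self.parse_additive())
        return node

    def parse_additive(self) -> Node:
        node = self.parse_multiplicative()
        while (tok := self.peek()) and tok[1] in ("+", "-"):
            self.next()
            node = Binary(tok[1], node, self.parse_multiplicative())
        return node

    def parse_multiplicative(self) -> Node:
        node = self.parse_unary()
        while (tok := self.peek()) and tok[1] in ("*", "/"):
            self.next()
            node = _maybe_guard(Binary(tok[1], node, self.parse_unary()))
        return node

    def parse_unary(self) -> Node:
        tok = self.peek()
        if tok and tok[1] == "-":
            self.next()
            return Unary("-", self.parse_unary())
        if tok and tok[1] == "+":
            self.next()
            return self.parse_unary()
        return self.parse_power()

    def parse_power(self) -> Node:
        base = self.parse_atom()
        tok = self.peek()
        if tok and tok[1] == "^":
            self.next()
            # right-associative; exponent may carry a unary minus
            exponent = self._parse_power_operand()
            return Binary("^", base, exponent)
        return base

    def _parse_power_operand(self) -> Node:
        tok = self.peek()
        if tok and tok[1] == "-":
            self.next()
            return Unary("-", self._parse_power_operand())
        return self.parse_power()

    def parse_atom(self) -> Node:
        kind, tok, where = self.next()
        if kind == "num":
            return Literal(float(tok))
        if kind == "name":
            nxt = self.peek()
            if nxt and nxt[1] == "(":
                return self.parse_call(tok, where)
            return Symbol(tok)
        if tok == "(":
            node = self.parse_or()
            self.expect(")")
            return node
        raise ExpressionError(
            f"unexpected token {tok!r} at position {where} in {self.text!r}"
        )

    def parse_call(self, func: str, where: int) -> Node:
        if func not in FUNCTIONS and func != RANDOM_FUNC:
            raise ExpressionError(
                f"unknown function {func!r} at position {where} in {self.text!r}"
            )
        self.expect("(")
        args = [self.parse_or()]
        while (tok := self.peek()) and tok[1] == ",":
            self.next()
            args.append(self.parse_or())
        self.expect(")")
        if len(args) != 1:
            raise ExpressionError(f"function {func!r} takes exactly one argument")
        return Call(func, tuple(args))


def _strip_negation(node: Node) -> Node | None:
    """If ``node`` is a syntactic negation, return the un-negated operand."""
    if isinstance(node, Unary) and node.op == "-":
        return node.operand
    if (
        isinstance(node, Binary)
        and node.op == "-"
        and isinstance(node.left, Literal)
        and node.left.value == 0.0
    ):
        return node.right
    return None


def _maybe_guard(node: Node) -> Node:
    """Rewrite ``x / (1 - exp(-x))`` into the guarded :class:`ExpLinear` node."""
    if not (isinstance(node, Binary) and node.op == "/"):
        return node
    den = node.right
    if not (
        isinstance(den, Binary)
        and den.op == "-"
        and isinstance(den.left, Literal)
        and den.left.value == 1.0
        and isinstance(den.right, Call)
        and den.right.func == "exp"
    ):
        return node
    arg = den.right.args[0]
    inner = _strip_negation(arg)
    if inner is not None and inner == node.left:
        return ExpLinear(node.left)
    return node


def _check_boolean_placement(node: Node, boolean_context: bool, text: str) -> None:
    if isinstance(node, Binary) and node.op in BOOLEAN_OPS:
        if not boolean_context:
            raise ExpressionError(
                f"boolean operator {node.op!r} used inside arithmetic in {text!r}"
            )
        if node.op in LOGICAL_OPS:
            _check_boolean_placement(node.left, True, text)
            _check_boolean_placement(node.right, True, text)
        else:  # relational: operands are arithmetic
            _check_boolean_placement(node.left, False, text)
            _check_boolean_placement(node.right, False, text)
        return
    if isinstance(node, Binary):
        _check_boolean_placement(node.left, False, text)
        _check_boolean_placement(node.right, False, text)
    elif isinstance(node, Unary):
        _check_boolean_placement(node.operand, False, text)
    elif isinstance(node, (Call, ExpLinear)):
        children = node.args if isinstance(node, Call) else (node.operand,)
        for c in children:
            _check_boolean_placement(c, False, text)


def parse_expression(text: str, boolean: bool = False) -> Node:
    """Parse an expression attribute into an AST.

    ``boolean=True`` parses a condition (the root may be relational or
    logical); otherwise any boolean operator is rejected at parse time.
    """
    if not text or not text.strip():
        raise ExpressionError("empty expression")
    parser = _Parser(text)
    node = parser.parse_or()
    if parser.peek() is not None:
        kind, tok, where = parser.peek()  # type: ignore[misc]
        raise ExpressionError(
            f"trailing input {tok!r} at position {where} in {text!r}"
        )
    _check_boolean_placement(node, boolean, text)
    if boolean and not (isinstance(node, Binary) and node.op in BOOLEAN_OPS):
        raise ExpressionError(f"condition {text!r} is not a boolean expression")
    return node


# --------------------------------------------------------------------------
# Evaluation


def _explinear(x: float) -> float:
    if abs(x) < 1e-7:
        return 1.0 + x / 2.0
    return x / (1.0 - math.exp(-x))


def eval_expression(ast: Node, bindings: Mapping[str, float], rng=None):
    """Evaluate an AST against symbol bindings (values in SI).

    Arithmetic nodes yield floats, relational/logical nodes booleans.
    ``random(x)`` draws uniformly from [0, x) using ``rng`` (a
    ``numpy.random.Generator`` or anything with ``.random()``).
    """
    if isinstance(ast, Literal):
        return ast.value
    if isinstance(ast, Symbol):
        try:
            return bindings[ast.name]
        except KeyError:
            raise ExpressionError(f"unbound symbol {ast.name!r}") from None
    if isinstance(ast, Unary):
        return -eval_expression(ast.operand, bindings, rng)
    if isinstance(ast, ExpLinear):
        return _explinear(eval_expression(ast.operand, bindings, rng))
    if isinstance(ast, Call):
        x = eval_expression(ast.args[0], bindings, rng)
        if ast.func == RANDOM_FUNC:
            if rng is None:
                raise ExpressionError("random() used without a seeded generator")
            return rng.random() * x
        try:
            return FUNCTIONS[ast.func](x)
        except ValueError as exc:
            raise ExpressionError(f"domain error in {ast.func}({x!r}): {exc}") from None
    if isinstance(ast, Binary):
        op = ast.op
        if op == ".and.":
            return bool(eval_expression(ast.left, bindings, rng)) and bool(
                eval_expression(ast.right, bindings, rng)
            )
        if op == ".or.":
            return bool(eval_expression(ast.left, bindings, rng)) or bool(
                eval_expression(ast.right, bindings, rng)
            )
        a = eval_expression(ast.left, bindings, rng)
        b = eval_expression(ast.right, bindings, rng)
        if op == "+":
            return a + b
        if op == "-":
            return a - b
        if op == "*":
            return a * b
        if op == "/":
            if b == 0:
                raise ExpressionError(
                    f"division by zero in {to_text(ast)!r}"
                )
            return a / b
        if op == "^":
            return a ** b
        if op == ".lt.":
            return a < b
        if op == ".gt.":
            return a > b
        if op == ".leq.":
            return a <= b
        if op == ".geq.":
            return a >= b
        if op == ".eq.":
            return a == b
        if op == ".neq.":
            return a != b
    raise ExpressionError(f"cannot evaluate node {ast!r}")


# --------------------------------------------------------------------------
# Dimension inference


def infer_dimension(ast: Node, dims: Mapping[str, Dimension]) -> Dimension:
    """Infer the dimension of an arithmetic expression.

    ``+``/``-`` require equal operand dimensions; ``*``/``/`` combine them;
    ``^`` requires an integer-literal exponent unless the base is
    dimensionless; transcendental functions require and return
    dimensionless.  For a condition, use :func:`check_condition_dimensions`.
    """
    if isinstance(ast, Literal):
        return DIMENSIONLESS
    if isinstance(ast, Symbol):
        try:
            return dims[ast.name]
        except KeyError:
            raise DimensionMismatch(f"symbol {ast.name!r} has no declared dimension") from None
    if isinstance(ast, Unary):
        return infer_dimension(ast.operand, dims)
    if isinstance(ast, ExpLinear):
        d = infer_dimension(ast.operand, dims)
        if not d.is_dimensionless:
            raise DimensionMismatch(
                f"exponential-linear form requires a dimensionless argument, "
                f"got {d.describe()} in {to_text(ast)!r}"
            )
        return DIMENSIONLESS
    if isinstance(ast, Call):
        d = infer_dimension(ast.args[0], dims)
        if ast.func == RANDOM_FUNC:
            return d
        if not d.is_dimensionless:
            raise DimensionMismatch(
                f"{ast.func}() requires a dimensionless argument, got "
                f"{d.describe()} in {to_text(ast)!r}"
            )
        return DIMENSIONLESS
    if isinstance(ast, Binary):
        op = ast.op
        if op in BOOLEAN_OPS:
            raise DimensionMismatch(
                f"boolean operator {op!r} has no dimension ({to_text(ast)!r})"
            )
        a = infer_dimension(ast.left, dims)
        b = infer_dimension(ast.right, dims)
        if op in ("+", "-"):
            if a != b:
                raise DimensionMismatch(
                    f"cannot {'add' if op == '+' else 'subtract'} "
                    f"{a.describe()} and {b.describe()} in {to_text(ast)!r}"
                )
            return a
        if op == "*":
            return dim_combine(a, b, "multiply")
        if op == "/":
            return dim_combine(a, b, "divide")
        if op == "^":
            if not b.is_dimensionless:
                raise DimensionMismatch(
                    f"exponent must be dimensionless in {to_text(ast)!r}"
                )
            if a.is_dimensionless:
                return DIMENSIONLESS
            k = _integer_literal(ast.right)
            if k is None:
                raise DimensionMismatch(
                    f"dimensional base needs an integer-literal exponent in "
                    f"{to_text(ast)!r}"
                )
            return dim_power(a, k)
    raise DimensionMismatch(f"cannot infer dimension of node {ast!r}")


def _integer_literal(node: Node) -> int | None:
    if isinstance(node, Unary) and node.op == "-":
        k = _integer_literal(node.operand)
        return None if k is None else -k
    if isinstance(node, Literal) and float(node.value).is_integer():
        return int(node.value)
    return None


def check_condition_dimensions(ast: Node, dims: Mapping[str, Dimension]) -> None:
    """Check a boolean condition: each relational compares like dimensions."""
    if isinstance(ast, Binary) and ast.op in LOGICAL_OPS:
        check_condition_dimensions(ast.left, dims)
        check_condition_dimensions(ast.right, dims)
        return
    if isinstance(ast, Binary) and ast.op in RELATIONAL_OPS:
        a = infer_dimension(ast.left, dims)
        b = infer_dimension(ast.right, dims)
        if a != b:
            raise DimensionMismatch(
                f"relational {ast.op} compares {a.describe()} with "
                f"{b.describe()} in {to_text(ast)!r}"
            )
        return
    raise DimensionMismatch(f"not a condition: {to_text(ast)!r}")


# --------------------------------------------------------------------------
# Serialization and compilation

_PRECEDENCE = {
    ".or.": 1,
    ".and.": 2,
    ".lt.": 3, ".gt.": 3, ".leq.": 3, ".geq.": 3, ".eq.": 3, ".neq.": 3,
    "+": 4, "-": 4,
    "*": 5, "/": 5,
    "u-": 6,
    "^": 7,
}


def to_text(ast: Node) -> str:
    """Serialize an AST back to the attribute grammar (round-trips)."""
    return _to_text(ast, 0)


def _to_text(ast: Node, parent_prec: int) -> str:
    if isinstance(ast, Literal):
        v = ast.value
        s = str(int(v)) if v == int(v) and abs(v) < 1e16 else repr(v)
        return s
    if isinstance(ast, Symbol):
        return ast.name
    if isinstance(ast, Unary):
        inner = _to_text(ast.operand, _PRECEDENCE["u-"])
        s = f"-{inner}"
        return f"({s})" if parent_prec > _PRECEDENCE["u-"] else s
    if isinstance(ast, ExpLinear):
        x = _to_text(ast.operand, _PRECEDENCE["/"] + 1)
        s = f"{x} / (1 - exp(0 - {_to_text(ast.operand, 0)}))"
        return f"({s})" if parent_prec > _PRECEDENCE["/"] else s
    if isinstance(ast, Call):
        return f"{ast.func}({_to_text(ast.args[0], 0)})"
    if isinstance(ast, Binary):
        prec = _PRECEDENCE[ast.op]
        pad = "" if ast.op in ("^",) else " "
        left = _to_text(ast.left, prec)
        # for left-assoc ops the right child needs a strictly higher context
        right_prec = prec if ast.op == "^" else prec + 1
        right = _to_text(ast.right, right_prec)
        s = f"{left}{pad}{ast.op}{pad}{right}"
        return f"({s})" if prec < parent_prec else s
    raise ExpressionError(f"cannot serialize node {ast!r}")


def free_symbols(ast: Node) -> set[str]:
    if isinstance(ast, Symbol):
        return {ast.name}
    if isinstance(ast, Unary):
        return free_symbols(ast.operand)
    if isinstance(ast, ExpLinear):
        return free_symbols(ast.operand)
    if isinstance(ast, Binary):
        return free_symbols(ast.left) | free_symbols(ast.right)
    if isinstance(ast, Call):
        out: set[str] = set()
        for a in ast.args:
            out |= free_symbols(a)
        return out
    return set()


_PY_OPS = {
    "+": "+", "-": "-", "*": "*", "/": "/", "^": "**",
    ".lt.": "<", ".gt.": ">", ".leq.": "<=", ".geq.": ">=",
    ".eq.": "==", ".neq.": "!=", ".and.": "and", ".or.": "or",
}


def compile_expression(ast: Node) -> Callable[[Mapping[str, float]], float]:
    """Compile an AST to a fast callable ``f(bindings, rng=None)``.

    Used by the simulation engine on hot paths; semantics match
    :func:`eval_expression` except that float division by zero follows IEEE
    (inf/nan) rather than raising — the engine aborts on non-finite states
    instead.
    """
    src = _py_src(ast)
    code = compile(src, "<lemsim-expr>", "eval")
    env = {"__builtins__": {}, "math": math, "abs": abs, "_explin": _explinear}
    env.update(FUNCTIONS)

    def fn(bindings, rng=None, _code=code, _env=env):
        scope = dict(_env)
        scope.update(bindings)
        if rng is not None:
            scope["_rng"] = rng
        return eval(_code, scope)  # noqa: S307 - sandboxed, no builtins

    return fn


_COMPILE_CACHE: dict[int, tuple[Node, Callable, tuple[str, ...]]] = {}


def cached_compile(ast: Node) -> tuple[Callable, tuple[str, ...]]:
    """Compile-once cache used on simulation hot paths.

    Returns ``(callable, free symbol names)``; keyed by AST identity.
    """
    hit = _COMPILE_CACHE.get(id(ast))
    if hit is not None and hit[0] is ast:
        return hit[1], hit[2]
    fn = compile_expression(ast)
    syms = tuple(sorted(free_symbols(ast)))
    _COMPILE_CACHE[id(ast)] = (ast, fn, syms)
    return fn, syms


def _py_src(ast: Node) -> str:
    if isinstance(ast, Literal):
        return repr(ast.value)
    if isinstance(ast, Symbol):
        return ast.name
    if isinstance(ast, Unary):
        return f"(-({_py_src(ast.operand)}))"
    if isinstance(ast, ExpLinear):
        return f"_explin({_py_src(ast.operand)})"
    if isinstance(ast, Call):
        if ast.func == RANDOM_FUNC:
            return f"(_rng.random() * ({_py_src(ast.args[0])}))"
        return f"{ast.func}({_py_src(ast.args[0])})"
    if isinstance(ast, Binary):
        return f"({_py_src(ast.left)} {_PY_OPS[ast.op]} {_py_src(ast.right)})"
    raise ExpressionError(f"cannot compile node {ast!r}")
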