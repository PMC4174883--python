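"""Expression grammar: parsing, evaluation, serialization, dimensions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lemsim.expressions import (
    Binary,
    Call,
    DimensionMismatch,
    ExpLinear,
    ExpressionError,
    Literal,
    Symbol,
    Unary,
    check_condition_dimensions,
    eval_expression,
    free_symbols,
    infer_dimension,
    parse_expression,
    to_text,
)
from lemsim.units import DIMENSIONLESS, Dimension

VOLTAGE = Dimension("voltage", (1, 2, -3, -1, 0, 0, 0))
CONDUCTANCE = Dimension("conductance", (-1, -2, 3, 2, 0, 0, 0))
CURRENT = Dimension("current", (0, 0, 0, 1, 0, 0, 0))
CAPACITANCE = Dimension("capacitance", (-1, -2, 4, 2, 0, 0, 0))
TIME = Dimension("time", (0, 0, 1, 0, 0, 0, 0))


class TestParsing:
    def test_ohmic_current_tree_and_symbols(self):
        ast = parse_expression("g * (v - E)")
        assert isinstance(ast, Binary) and ast.op == "*"
        assert free_symbols(ast) == {"g", "v", "E"}

    def test_fortran_relational_conjunction(self):
        ast = parse_expression("v .gt. theta .and. t .geq. tNext", boolean=True)
        assert ast.op == ".and."
        assert ast.left.op == ".gt." and ast.right.op == ".geq."

    def test_unary_minus(self):
        ast = parse_expression("-x")
        assert isinstance(ast, Unary) and ast.operand == Symbol("x")

    def test_precedence_power_binds_tighter_than_unary_minus(self):
        # -x^2 parses as -(x^2)
        assert eval_expression(parse_expression("-x^2"), {"x": 3.0}) == -9.0

    def test_power_is_right_associative(self):
        assert eval_expression(parse_expression("2^3^2"), {}) == 512.0

    def test_multiplication_binds_tighter_than_addition(self):
        assert eval_expression(parse_expression("2 + 3 * 4"), {}) == 14.0

    def test_relational_alias_spellings_accepted(self):
        for text in ("a .le. b", "a .ge. b"):
            parse_expression(text, boolean=True)

    def test_syntax_error_reports_position(self):
        with pytest.raises(ExpressionError, match="position"):
            parse_expression("1 + * 2")

    def test_unknown_function_rejected(self):
        with pytest.raises(ExpressionError, match="mystery"):
            parse_expression("mystery(x)")

    def test_relational_inside_arithmetic_is_a_parse_error(self):
        with pytest.raises(ExpressionError):
            parse_expression("1 + (a .lt. b)")
        with pytest.raises(ExpressionError):
            parse_expression("a .lt. b")  # boolean root in arithmetic context


class TestEvaluation:
    def test_sigmoid_midpoint(self):
        assert eval_expression(
            parse_expression("1/(1 + exp(0 - x))"), {"x": 0.0}
        ) == pytest.approx(0.5)

    def test_exp_at_zero(self):
        assert eval_expression(parse_expression("exp(x)"), {"x": 0.0}) == 1.0

    def test_unbound_symbol_reported(self):
        with pytest.raises(ExpressionError, match="zzz"):
            eval_expression(parse_expression("zzz + 1"), {})

    def test_log_domain_error_reported(self):
        with pytest.raises(ExpressionError, match="domain"):
            eval_expression(parse_expression("log(x)"), {"x": -1.0})

    def test_division_by_zero_reported(self):
        with pytest.raises(ExpressionError, match="division"):
            eval_expression(parse_expression("1 / x"), {"x": 0.0})

    def test_random_is_uniform_on_zero_x_and_seeded(self):
        ast = parse_expression("random(x)")
        r1 = np.random.default_rng(42)
        r2 = np.random.default_rng(42)
        draws = [eval_expression(ast, {"x": 3.0}, r1) for _ in range(100)]
        again = [eval_expression(ast, {"x": 3.0}, r2) for _ in range(100)]
        assert draws == again
        assert all(0.0 <= d < 3.0 for d in draws)


class TestGuardedExpLinear:
    """x / (1 - exp(-x)) has a removable singularity at 0; the parser
    rewrites the pattern into a guarded node."""

    def test_pattern_is_recognized(self):
        for text in ("x / (1 - exp(0 - x))", "x / (1 - exp(-x))"):
            assert isinstance(parse_expression(text), ExpLinear)

    def test_near_zero_limit(self):
        ast = parse_expression("x / (1 - exp(0 - x))")
        assert eval_expression(ast, {"x": 1e-9}) == pytest.approx(1.0, abs=1e-6)
        assert eval_expression(ast, {"x": 0.0}) == 1.0

    def test_monotone_and_continuous_across_zero(self):
        ast = parse_expression("x / (1 - exp(0 - x))")
        xs = np.linspace(-10, 10, 4001)
        ys = np.array([eval_expression(ast, {"x": float(x)}) for x in xs])
        assert np.all(np.diff(ys) > 0)
        assert np.max(np.abs(np.diff(ys))) < 0.02  # no jump at the guard

    def test_guard_matches_exact_form_away_from_zero(self):
        ast = parse_expression("x / (1 - exp(0 - x))")
        for x in (-5.0, -0.5, 0.5, 5.0):
            exact = x / (1 - math.exp(-x))
            assert eval_expression(ast, {"x": x}) == pytest.approx(exact, rel=1e-12)


class TestDimensionInference:
    DIMS = {
        "g": CONDUCTANCE, "v": VOLTAGE, "E": VOLTAGE, "vScale": VOLTAGE,
        "i": CURRENT, "C": CAPACITANCE, "t": TIME,
    }

    def test_ohmic_expression_yields_current(self):
        assert infer_dimension(parse_expression("g * (v - E)"), self.DIMS) == CURRENT

    def test_adding_unlike_dimensions_rejected(self):
        with pytest.raises(DimensionMismatch):
            infer_dimension(parse_expression("v + g"), self.DIMS)

    def test_voltage_ratio_inside_exp_is_dimensionless(self):
        got = infer_dimension(parse_expression("exp(v / vScale)"), self.DIMS)
        assert got == DIMENSIONLESS

    def test_transcendental_requires_dimensionless_argument(self):
        with pytest.raises(DimensionMismatch):
            infer_dimension(parse_expression("exp(v)"), self.DIMS)

    def test_dimensional_base_needs_integer_literal_exponent(self):
        assert infer_dimension(parse_expression("v^2"), self.DIMS).exponents == (
            2, 4, -6, -2, 0, 0, 0)
        with pytest.raises(DimensionMismatch):
            infer_dimension(parse_expression("v^t"), self.DIMS)

    def test_condition_compares_like_dimensions_only(self):
        check_condition_dimensions(
            parse_expression("v .gt. E", boolean=True), self.DIMS
        )
        with pytest.raises(DimensionMismatch):
            check_condition_dimensions(
                parse_expression("v .gt. g", boolean=True), self.DIMS
            )

    @settings(max_examples=100, deadline=None)
    @given(data=st.data())
    def test_agreement_with_scaling_oracle(self, data):
        """Inferred dimensions agree with a brute-force homogeneity oracle:
        scaling each base unit by a random factor must scale the value by
        the factor raised to the inferred exponent."""
        dims = {"a": VOLTAGE, "b": VOLTAGE, "c": CONDUCTANCE, "k": DIMENSIONLESS}
        expr = data.draw(_arith_exprs(("a", "b", "c", "k")))
        try:
            inferred = infer_dimension(expr, dims)
        except DimensionMismatch:
            return  # oracle applies to well-dimensioned expressions only
        base = {"a": 1.3, "b": 0.7, "c": 2.1, "k": 0.9}
        try:
            v1 = eval_expression(expr, base)
        except ExpressionError:
            return
        # scale mass by 2: voltage ~ M^1, conductance ~ M^-1
        scaled = {"a": base["a"] * 2.0, "b": base["b"] * 2.0,
                  "c": base["c"] / 2.0, "k": base["k"]}
        try:
            v2 = eval_expression(expr, scaled)
        except ExpressionError:
            return
        if abs(v1) < 1e-9:
            return
        assert v2 / v1 == pytest.approx(2.0 ** inferred.exponents[0], rel=1e-6)


def _arith_exprs(symbols):
    atoms = st.one_of(
        st.sampled_from([Symbol(s) for s in symbols]),
        st.floats(min_value=0.1, max_value=4.0).map(Literal),
    )
    return st.recursive(
        atoms,
        lambda inner: st.one_of(
            st.tuples(st.sampled_from("+-*/"), inner, inner).map(
                lambda t: Binary(t[0], t[1], t[2])
            ),
            inner.map(lambda n: Unary("-", n)),
        ),
        max_leaves=8,
    )


class TestSerialization:
    @pytest.mark.parametrize(
        "text",
        [
            "g * (v - E)",
            "-x^2 + 3 * (y - 1)",
            "1/(1 + exp(0 - x))",
            "x / (1 - exp(0 - x))",
            "a / (b / c) - (a - b) * c",
            "v .gt. theta .and. t .geq. tNext",
            "abs(x) + floor(y) - random(z)",
        ],
    )
    def test_round_trip_preserves_value(self, text):
        """Serializing the AST back to text and re-parsing evaluates
        identically (seeded generator for random())."""
        boolean = ".gt." in text
        ast = parse_expression(text, boolean=boolean)
        again = parse_expression(to_text(ast), boolean=boolean)
        bindings = {s: 0.37 + 0.11 * i for i, s in enumerate(sorted(free_symbols(ast)))}
        r1, r2 = np.random.default_rng(5), np.random.default_rng(5)
        assert eval_expression(ast, bindings, r1) == eval_expression(again, bindings, r2)
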