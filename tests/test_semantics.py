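"""Inheritance resolution, component validation, dynamics checking."""

import pytest

from lemsim.document import parse_lems
from lemsim.semantics import (
    SemanticError,
    check_component,
    check_document,
    check_dynamics,
    resolve_type,
)

HEADER = """
    <Dimension name="voltage" m="1" l="2" t="-3" i="-1"/>
    <Dimension name="conductance" m="-1" l="-2" t="3" i="2"/>
    <Dimension name="capacitance" m="-1" l="-2" t="4" i="2"/>
    <Dimension name="current" i="1"/>
    <Dimension name="time" t="1"/>
    <Unit symbol="mV" dimension="voltage" power="-3"/>
    <Unit symbol="mS" dimension="conductance" power="-3"/>
    <Unit symbol="uF" dimension="capacitance" power="-6"/>
    <Unit symbol="ms" dimension="time" power="-3"/>
"""


def _doc(body: str):
    return parse_lems(f"<Lems>{HEADER}{body}</Lems>")


class TestTypeResolution:
    def test_extension_inherits_requirements_and_exposures(self, fixture_docs):
        doc = fixture_docs["hh_cell"]
        rt = resolve_type("ionChannelHH", doc)
        assert "baseIonChannel" in rt.lineage
        assert rt.requirements["v"].name == "voltage"
        assert "g" in rt.exposures

    def test_rate_subtypes_fill_base_typed_child_slots(self, fixture_docs):
        doc = fixture_docs["hh_cell"]
        rt = resolve_type("expOneRate", doc)
        assert rt.is_subtype_of("baseVoltageDepRate")

    def test_self_extension_is_a_cycle_error(self):
        doc = _doc('<ComponentType name="loop" extends="loop"/>')
        with pytest.raises(SemanticError, match="cycl"):
            resolve_type("loop", doc)

    def test_resolution_is_idempotent_and_order_independent(self, fixture_docs):
        doc = fixture_docs["hh_cell"]
        a = resolve_type("gateHHrates", doc)
        b = resolve_type("gateHHrates", doc)
        assert a is b  # cached, single merged view
        assert list(a.parameters) == ["instances"]

    def test_conflicting_dimension_redeclaration_rejected(self):
        doc = _doc(
            '<ComponentType name="base"><Parameter name="p" dimension="voltage"/>'
            "</ComponentType>"
            '<ComponentType name="derived" extends="base">'
            '<Parameter name="p" dimension="time"/></ComponentType>'
        )
        with pytest.raises(SemanticError, match="conflicting"):
            resolve_type("derived", doc)

    def test_derived_type_may_override_derived_variable(self):
        doc = _doc(
            '<ComponentType name="base"><Exposure name="y" dimension="none"/>'
            '<Dynamics><DerivedVariable name="y" dimension="none" exposure="y" '
            'value="1 + 1"/></Dynamics></ComponentType>'
            '<ComponentType name="derived" extends="base">'
            '<Dynamics><DerivedVariable name="y" dimension="none" exposure="y" '
            'value="2 + 2"/></Dynamics></ComponentType>'
        )
        from lemsim.expressions import eval_expression

        rt = resolve_type("derived", doc)
        assert eval_expression(rt.dynamics.derived_variables["y"].expr, {}) == 4.0


PASSIVE_TYPES = """
    <ComponentType name="passiveChannel">
        <Parameter name="conductance" dimension="conductance"/>
        <Parameter name="erev" dimension="voltage"/>
        <Requirement name="v" dimension="voltage"/>
        <Exposure name="i" dimension="current"/>
        <Dynamics>
            <DerivedVariable name="i" dimension="current" exposure="i"
                             value="conductance * (erev - v)"/>
        </Dynamics>
    </ComponentType>
"""


class TestComponentChecking:
    def test_valid_component_converts_to_si(self):
        doc = _doc(
            PASSIVE_TYPES
            + '<passiveChannel id="c" conductance="10 mS" erev="-65 mV"/>'
        )
        tc = check_component(doc.components[0], doc)
        assert tc.parameters["conductance"].magnitude == pytest.approx(0.01)
        assert tc.parameters["erev"].magnitude == pytest.approx(-0.065)

    def test_wrong_unit_dimension_reported_with_both_dimensions(self):
        doc = _doc(
            PASSIVE_TYPES
            + '<passiveChannel id="c" conductance="10 mS" erev="-65 ms"/>'
        )
        with pytest.raises(SemanticError, match="erev"):
            check_component(doc.components[0], doc)

    def test_missing_parameter_named_in_error(self):
        doc = _doc(PASSIVE_TYPES + '<passiveChannel id="c" conductance="10 mS"/>')
        with pytest.raises(SemanticError, match="erev"):
            check_component(doc.components[0], doc)

    def test_unknown_attribute_rejected(self):
        doc = _doc(
            PASSIVE_TYPES
            + '<passiveChannel id="c" conductance="10 mS" erev="-65 mV" bogus="1"/>'
        )
        with pytest.raises(SemanticError, match="bogus"):
            check_component(doc.components[0], doc)

    def test_exactly_one_child_slot_enforced(self, fixture_docs):
        doc = parse_lems(
            "<Lems>" + HEADER + PASSIVE_TYPES + """
            <ComponentType name="holder">
                <Child name="channel" type="passiveChannel"/>
            </ComponentType>
            <holder id="h"/>
            </Lems>"""
        )
        with pytest.raises(SemanticError, match="exactly one"):
            check_component(doc.components[0], doc)

    def test_component_stays_valid_against_ancestor_members(self, fixture_docs):
        """A component valid for a derived type supplies values for every
        member the base type declares (restriction property)."""
        doc = fixture_docs["hh_cell"]
        raw = next(c for c in doc.components if c.id == "hhcell")
        tc = check_component(raw, doc)
        base = resolve_type("baseCellMembPotCap", doc)
        for pname in base.parameters:
            assert pname in tc.parameters


class TestDynamicsChecking:
    def test_current_over_capacitance_is_a_valid_voltage_derivative(self):
        doc = _doc(
            """
            <ComponentType name="cell">
                <Parameter name="C" dimension="capacitance"/>
                <Parameter name="i0" dimension="current"/>
                <Dynamics>
                    <StateVariable name="v" dimension="voltage"/>
                    <TimeDerivative variable="v" value="i0 / C"/>
                </Dynamics>
            </ComponentType>
            """
        )
        assert check_dynamics(resolve_type("cell", doc), doc) == []

    def test_conductance_times_voltage_is_not_a_voltage_derivative(self):
        doc = _doc(
            """
            <ComponentType name="cell">
                <Parameter name="g" dimension="conductance"/>
                <Dynamics>
                    <StateVariable name="v" dimension="voltage"/>
                    <TimeDerivative variable="v" value="g * v"/>
                </Dynamics>
            </ComponentType>
            """
        )
        report = check_dynamics(resolve_type("cell", doc), doc)
        assert len(report) == 1 and "dv/dt" in report[0]

    def test_empty_dynamics_gives_empty_report(self):
        doc = _doc('<ComponentType name="nothing"/>')
        assert check_dynamics(resolve_type("nothing", doc), doc) == []

    def test_report_collects_all_violations_not_just_first(self):
        doc = _doc(
            """
            <ComponentType name="cell">
                <Parameter name="g" dimension="conductance"/>
                <Dynamics>
                    <StateVariable name="v" dimension="voltage"/>
                    <StateVariable name="u" dimension="voltage"/>
                    <TimeDerivative variable="v" value="g * v"/>
                    <TimeDerivative variable="u" value="g * u"/>
                </Dynamics>
            </ComponentType>
            """
        )
        assert len(check_dynamics(resolve_type("cell", doc), doc)) == 2

    def test_regimes_require_exactly_one_initial(self):
        doc = _doc(
            """
            <ComponentType name="cell">
                <Dynamics>
                    <StateVariable name="v" dimension="voltage"/>
                    <Regime name="one"/>
                    <Regime name="two"/>
                </Dynamics>
            </ComponentType>
            """
        )
        report = check_dynamics(resolve_type("cell", doc), doc)
        assert any("initial" in r for r in report)

    def test_every_fixture_dimension_checks_clean(self, fixture_docs):
        for name, doc in fixture_docs.items():
            assert check_document(doc) == [], f"fixture {name} has violations"
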