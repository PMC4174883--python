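"""Integration schemes, hybrid stepping, flattening, trace output."""

import math
import os

import numpy as np
import pytest

import lemsim
from lemsim import componentlib as cl
from lemsim.document import parse_lems
from lemsim.engine import EngineError, flatten, simulate, write_traces
from lemsim.runtime import build_instance_tree


def _order_of_accuracy(method):
    dts = [0.1, 0.05, 0.025, 0.0125]
    errs = []
    for dt in dts:
        doc = parse_lems(cl.decay_model_xml(dt_s=dt))
        tr = simulate(doc, method=method)
        errs.append(abs(tr.records["cell/v"][-1] - math.exp(-1.0)))
    return np.polyfit(np.log2(dts), np.log2(errs), 1)[0]


class TestIntegrators:
    def test_single_euler_step_matches_scheme_definition(self):
        # dv/dt = -v/tau, one step: v' = v (1 - dt/tau)
        doc = parse_lems(cl.decay_model_xml(tau_s=2.0, v0=1.0, dt_s=0.5, length_s=0.5))
        tr = simulate(doc, method="euler")
        assert tr.records["cell/v"][-1] == pytest.approx(1.0 * (1 - 0.5 / 2.0))

    def test_euler_convergence_order_is_one(self):
        assert _order_of_accuracy("euler") == pytest.approx(1.0, abs=0.2)

    def test_rk4_convergence_order_is_four(self):
        assert _order_of_accuracy("rk4") == pytest.approx(4.0, abs=0.2)

    def test_passive_membrane_matches_exponential_relaxation(self, fixture_traces):
        """C dv/dt = g (E - v) from v(0) = E + 10 mV decays with tau = C/g;
        the fixture runs at dt = tau/1000."""
        tr = fixture_traces["passive_channel"]
        E, v0, tau = -0.065, -0.055, 0.1
        exact = E + (v0 - E) * np.exp(-tr.times / tau)
        rel = np.abs(tr.records["cell/v"] - exact) / np.abs(exact)
        assert np.max(rel) < 1e-3

    def test_non_finite_state_aborts_with_variable_path(self):
        doc = parse_lems(
            """<Lems>
            <Dimension name="time" t="1"/>
            <Unit symbol="s" dimension="time" power="0"/>
            <ComponentType name="blowup">
                <Parameter name="tau" dimension="time"/>
                <Dynamics>
                    <StateVariable name="v" dimension="none"/>
                    <OnStart><StateAssignment variable="v" value="1"/></OnStart>
                    <TimeDerivative variable="v" value="v * v * v / tau"/>
                </Dynamics>
            </ComponentType>
            <blowup id="b" tau="0.001 s"/>
            </Lems>"""
        )
        with pytest.raises(EngineError, match="v"):
            simulate(doc, target="b", dt=0.01, length=5.0, method="euler")


class TestFlattening:
    def test_flat_state_layout_uses_path_prefixed_names(self, fixture_docs):
        root = build_instance_tree(fixture_docs["passive_channel"], "cell")
        system = flatten(root)
        assert "v" in system.names  # root state carries no prefix

    def test_single_state_flatten_is_identity_layout(self):
        doc = parse_lems(cl.decay_model_xml())
        root = build_instance_tree(doc, "cell")
        system = flatten(root)
        assert system.names == ["v"]

    def test_derived_variable_cycles_rejected(self):
        doc = parse_lems(
            """<Lems>
            <ComponentType name="cyclic">
                <Dynamics>
                    <DerivedVariable name="a" dimension="none" value="b + 1"/>
                    <DerivedVariable name="b" dimension="none" value="a + 1"/>
                </Dynamics>
            </ComponentType>
            <cyclic id="c"/>
            </Lems>"""
        )
        root = build_instance_tree(doc, "c")
        with pytest.raises(EngineError, match="cycle"):
            flatten(root)

    @pytest.mark.parametrize("name", sorted(cl.FIXTURE_NAMES))
    def test_flattened_and_tree_walk_euler_agree(self, name):
        """Same dt, same seed: the vectorized flattened update and the
        per-node tree walk stay within 1e-9 relative at every step."""
        tr_flat = simulate(cl.load_fixture(name), seed=3, method="euler",
                           dt=5e-5, length=0.04)
        tr_tree = simulate(cl.load_fixture(name), seed=3, method="euler-tree",
                           dt=5e-5, length=0.04)
        for key in tr_flat.records:
            a, b = tr_flat.records[key], tr_tree.records[key]
            denom = np.maximum(np.abs(a), 1e-12)
            assert np.max(np.abs(a - b) / denom) < 1e-9, key


class TestHybridSemantics:
    def test_condition_already_true_at_start_does_not_fire(self):
        doc = parse_lems(
            """<Lems>
            <ComponentType name="latch">
                <EventPort name="out" direction="out"/>
                <Dynamics>
                    <StateVariable name="x" dimension="none"/>
                    <OnStart><StateAssignment variable="x" value="2"/></OnStart>
                    <OnCondition test="x .gt. 1"><EventOut port="out"/></OnCondition>
                </Dynamics>
            </ComponentType>
            <latch id="l"/>
            </Lems>"""
        )
        tr = simulate(doc, target="l", dt=0.001, length=0.01)
        assert tr.events == []

    def test_refractory_regime_ignores_integrating_derivative(self, fixture_traces):
        """While refractory, v is frozen at the reset value."""
        tr = fixture_traces["adex_cell"]
        spikes = [t for t, _, port in tr.events if port == "spike"]
        assert spikes, "the driven cell must spike"
        t, v = tr.times, tr.records["adex/v"]
        dt = t[1] - t[0]
        t0 = spikes[0]
        inside = (t > t0 + dt) & (t < t0 + 0.002 - dt)
        assert np.allclose(v[inside], -0.0706, atol=1e-12)

    def test_interspike_intervals_respect_refractory_period(self, fixture_traces):
        tr = fixture_traces["adex_cell"]
        spikes = np.array([t for t, _, port in tr.events if port == "spike"])
        assert len(spikes) >= 2
        assert np.min(np.diff(spikes)) >= 0.002

    def test_kinetic_occupancies_conserved_every_step(self, fixture_traces):
        tr = fixture_traces["two_state_kinetic_gate"]
        total = tr.records["gate/c/occupancy"] + tr.records["gate/o/occupancy"]
        assert np.max(np.abs(total - 1.0)) < 1e-9

    def test_two_state_steady_state_is_alpha_over_alpha_plus_beta(self, fixture_traces):
        tr = fixture_traces["two_state_kinetic_gate"]
        assert tr.records["gate/o/occupancy"][-1] == pytest.approx(2.0 / 3.0, abs=1e-6)

    def test_delayed_event_arrives_in_first_step_at_or_after_delivery(self):
        doc = cl.load_fixture("small_network")
        tr = simulate(doc, seed=1)
        spikes = [(t, who) for t, who, port in tr.events]
        assert spikes, "ring cells must spike"
        # synapse state of the downstream cell must react only after delay
        tr2 = simulate(
            cl.load_fixture("small_network"), seed=1,
            records=["pop/cell[1]/synapses[0]/A"],
        )
        a = tr2.records["pop/cell[1]/synapses[0]/A"]
        first_upstream = min(t for t, who, _ in tr2.events if who == "pop/cell[0]")
        t = tr2.times
        assert np.all(a[t < first_upstream + 0.005] == 0.0)
        assert np.any(a[t >= first_upstream + 0.005] > 0.0)


class TestRecording:
    def test_trace_file_shape_and_time_column(self, tmp_path, fixture_traces):
        tr = fixture_traces["two_state_kinetic_gate"]
        paths = write_traces(tr, str(tmp_path))
        data = [l.split("\t") for l in open(paths[0]).read().splitlines()]
        assert data[0][0] == "time"
        assert len(data) - 1 == len(tr.times)
        assert float(data[1][0]) == 0.0

    def test_zero_length_run_writes_single_row(self, tmp_path):
        doc = parse_lems(cl.decay_model_xml(length_s=0.0))
        tr = simulate(doc)
        paths = write_traces(tr, str(tmp_path))
        lines = open(paths[0]).read().splitlines()
        assert len(lines) == 2  # header + t=0

    def test_same_seed_reproduces_files_byte_for_byte(self, tmp_path):
        for sub in ("a", "b"):
            tr = simulate(cl.load_fixture("adex_cell"), seed=7)
            write_traces(tr, str(tmp_path / sub))
        fa = (tmp_path / "a" / "adex_cell.tsv").read_bytes()
        fb = (tmp_path / "b" / "adex_cell.tsv").read_bytes()
        assert fa == fb
        ea = (tmp_path / "a" / "events.tsv").read_bytes()
        assert ea == (tmp_path / "b" / "events.tsv").read_bytes()
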