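"""Catalog of runnable example models plus a seeded network generator.

Every fixture is a complete document (dimensions, units, component types,
components, a Simulation element and a Target) and collectively the
catalog exercises parameters, derived parameters/variables, requirements,
child/children slots, component references, attachments, event ports,
regimes, kinetic schemes, population expansion and event connections with
delays and weights.
"""

from __future__ import annotations

import os

import numpy as np

from ..document import LemsDocument, parse_lems

__all__ = [
    "FIXTURE_DIR",
    "FIXTURE_NAMES",
    "fixture_path",
    "get_fixture",
    "load_fixture",
    "generate_random_network",
    "decay_model_xml",
]

FIXTURE_DIR = os.path.join(os.path.dirname(__file__), "fixtures")

#: fixture name -> one-line description
FIXTURE_NAMES = {
    "passive_channel": "ohmic channel on a holder cell; exponential relaxation",
    "hh_cell": "classic sodium/potassium/leak conductances with gating particles",
    "adex_cell": "adaptive exponential integrate-and-fire cell with two regimes",
    "blocking_plastic_synapse": "voltage-block + short-term-plasticity synapse",
    "two_state_kinetic_gate": "closed/open kinetic scheme with constant rates",
    "small_network": "three-cell inhibitory ring with delayed event connections",
}


def fixture_path(name: str) -> str:
    if name not in FIXTURE_NAMES:
        raise KeyError(
            f"unknown fixture {name!r}; catalog: {sorted(FIXTURE_NAMES)}"
        )
    return os.path.join(FIXTURE_DIR, f"{name}.xml")


def get_fixture(name: str) -> str:
    """Return the fixture's XML text (includes unresolved; parse with the
    fixture directory on the include path, as :func:`load_fixture` does)."""
    with open(fixture_path(name)) as fh:
        return fh.read()


def load_fixture(name: str) -> LemsDocument:
    """Parse a catalog fixture into a merged document."""
    return parse_lems(fixture_path(name), include_dirs=[FIXTURE_DIR])


def generate_random_network(
    n_cells: int,
    connection_probability: float,
    delay_range: tuple[float, float] = (1e-3, 5e-3),
    weight_range: tuple[float, float] = (0.5, 1.5),
    seed: int = 0,
) -> str:
    """Build a random network document: one population of ``n_cells``
    integrate-and-fire-style cells with Bernoulli(p) directed connections
    (no self-connections), each realized as an event connection attaching
    the shared synapse component with a uniformly drawn delay and weight.

    Delay range is in seconds.  Output is deterministic per argument set
    (byte-identical for identical arguments).  Parse the result with
    ``include_dirs=[FIXTURE_DIR]``.
    """
    if not 0.0 <= connection_probability <= 1.0:
        raise ValueError(
            f"connection probability must be in [0, 1], got {connection_probability}"
        )
    if n_cells <= 0:
        raise ValueError(f"need a positive number of cells, got {n_cells}")
    rng = np.random.default_rng(seed)
    lines = [
        "<Lems>",
        '    <Include file="defs.xml"/>',
        '    <Include file="basetypes.xml"/>',
        '    <Include file="adextypes.xml"/>',
        '    <Include file="synapsetypes.xml"/>',
        '    <Include file="networktypes.xml"/>',
        '    <adExCell id="cell" C="281 pF" gL="30 nS" EL="-70.6 mV"',
        '              VT="-50.4 mV" delT="2 mV" Vr="-70.6 mV" a="4 nS"',
        '              b="80.5 pA" tauw="144 ms" refract="2 ms" threshold="-40 mV">',
        '        <input type="pulseGenerator" delay="10 ms" duration="80 ms"',
        '               amplitude="0.8 nA"/>',
        "    </adExCell>",
        '    <blockingPlasticSynapse id="syn" gbase="2 nS" erev="-80 mV"',
        '                            tauRise="1 ms" tauDecay="8 ms">',
        '        <blockMechanism type="voltageConcDepBlockMechanism"',
        '                        blockConcentration="0 mM" scalingConc="3.57 mM"',
        '                        scalingVolt="16.13 mV"/>',
        '        <plasticityMechanism type="tsodyksMarkramDepFacMechanism"',
        '                             initReleaseProb="0.5" tauRec="120 ms"',
        '                             tauFac="10 ms"/>',
        "    </blockingPlasticSynapse>",
        '    <network id="net">',
        f'        <population id="pop" size="{n_cells}" component="cell"/>',
    ]
    d_lo, d_hi = delay_range
    w_lo, w_hi = weight_range
    for src in range(n_cells):
        for dst in range(n_cells):
            if src == dst:
                continue
            if rng.random() >= connection_probability:
                continue
            delay_ms = (d_lo + (d_hi - d_lo) * rng.random()) * 1e3
            weight = w_lo + (w_hi - w_lo) * rng.random()
            lines.append(
                f'        <synapticConnection id="c_{src}_{dst}" '
                f'from="pop/cell[{src}]" to="pop/cell[{dst}]" '
                f'delay="{delay_ms!r} ms" weight="{weight!r}" synapse="syn"/>'
            )
    lines += [
        "    </network>",
        '    <Simulation id="sim" length="100 ms" step="0.05 ms" target="net">',
        '        <OutputFile id="of0" fileName="random_network.tsv">',
        '            <OutputColumn quantity="pop/cell[0]/v"/>',
        "        </OutputFile>",
        "    </Simulation>",
        '    <Target component="sim"/>',
        "</Lems>",
    ]
    return "\n".join(lines) + "\n"


def decay_model_xml(tau_s: float = 1.0, v0: float = 1.0,
                    dt_s: float = 0.1, length_s: float = 1.0) -> str:
    """Minimal linear test model dv/dt = -v/tau with v(0) = v0 (v is kept
    dimensionless); used for integrator order-of-accuracy measurements."""
    return f"""<Lems>
    <Dimension name="time" t="1"/>
    <Dimension name="per_time" t="-1"/>
    <Unit symbol="s" dimension="time" power="0"/>
    <Unit symbol="per_s" dimension="per_time" power="0"/>
    <ComponentType name="decay">
        <Parameter name="tau" dimension="time"/>
        <Parameter name="v0" dimension="none"/>
        <Exposure name="v" dimension="none"/>
        <Dynamics>
            <StateVariable name="v" dimension="none" exposure="v"/>
            <TimeDerivative variable="v" value="(0 - v) / tau"/>
            <OnStart>
                <StateAssignment variable="v" value="v0"/>
            </OnStart>
        </Dynamics>
    </ComponentType>
    <decay id="cell" tau="{tau_s!r} s" v0="{v0!r}"/>
    <Simulation id="sim" length="{length_s!r} s" step="{dt_s!r} s" target="cell">
        <OutputFile id="of0" fileName="decay.tsv">
            <OutputColumn quantity="cell/v"/>
        </OutputFile>
    </Simulation>
    <Target component="sim"/>
</Lems>
"""
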