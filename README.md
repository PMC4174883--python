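# lemsim

An interpreter and fixed-step simulator for **LEMS** (Low Entropy Model
Specification) documents — the declarative XML language for hierarchical
physio-chemical models that underpins NeuroML 2 style model descriptions.

`lemsim` is for modelers and tool builders who want to parse, validate and
execute LEMS models without a domain-specific simulator: ion channels,
synapses, point neurons and event-driven networks are all expressed in the
language itself, and the numerical core knows nothing about neuroscience —
only dimensional quantities, ODEs, events, regimes and kinetic schemes.

## What the language expresses

* **Dimensional quantities.** Every dimension is a 7-tuple of integer
  exponents over the SI bases (M, L, T, I, Θ, N, J); units bind symbols to a
  dimension with a power of ten (plus optional scale/offset).  A relation
  like the ohmic current *I* = *g*·(*v* − *E*) is as much a statement about
  dimensions as magnitudes, so every time derivative, assignment and
  condition in a model is dimension-checked before it may run.
* **ComponentType / Component separation.** A *ComponentType* declares
  parameters, exposures, requirements, child slots, event ports and
  dynamics — equations without values.  A *Component* binds values with
  units.  Types extend one another, inheriting structure and dynamics.
* **Containment scoping.**  A gate inside a channel on a cell reads the
  membrane potential of *that* cell through a declared Requirement resolved
  nearest-ancestor-first — and of no other cell.
* **Hybrid dynamics.**  First-order ODEs (`TimeDerivative`), discrete
  events (`OnEvent`/`EventOut` with delays and weights), edge-triggered
  conditions (`OnCondition`), mutually exclusive `Regime`s with entry
  actions, and `KineticScheme`s integrated as conserved mean-field
  occupancy ODEs.
* **Structure.**  Populations (`MultiInstantiate`), event connections that
  attach synapse instances to target cells, and parent-to-child event
  relays.

Integration is forward Euler on the instance tree or — the default —
classic 4th-order Runge-Kutta on the flattened, path-prefixed state
vector; both paths are required to agree and are tested against each other.

## Worked example

```python
import lemsim
from lemsim import componentlib

doc = componentlib.load_fixture("adex_cell")   # complete runnable document
print(lemsim.check_document(doc))              # -> []  (dimension-clean)

traces = lemsim.simulate(doc, seed=1)
spikes = [t for t, _, port in traces.events if port == "spike"]
print([round(t * 1e3, 2) for t in spikes])
```

Output:

```
[]
[67.67, 92.3, 124.6, 168.25, 224.57]
```

The fixture is an adaptive exponential integrate-and-fire cell (C = 281 pF,
g_L = 30 nS, E_L = −70.6 mV, Δ_T = 2 mV, τ_w = 144 ms, b = 80.5 pA) driven
by a 0.8 nA step from 50 ms.  The five spike times (ms) stretch out because
each spike increments the adaptation current *w* by *b*; every interval is
at least the 2 ms refractory period enforced by the refractory regime.

The same models run from the shell:

```
lemsim validate --fixture hh_cell      # parse + type/dimension check
lemsim run --fixture hh_cell -seed 1 -o out/   # TSV traces + event log
lemsim info --fixture hh_cell          # document summary + type lineages
```

`examples/` contains one short script per capability: fixture simulation,
unit checking, mutation detection, convergence measurement, random network
generation and kinetic schemes.

## Fixture catalog

| name | exercises |
|---|---|
| `passive_channel` | requirements, derived variables, closed-form relaxation |
| `hh_cell` | channel/gate/rate inheritance, the three rate forms, product reduction |
| `adex_cell` | two regimes, spike events, refractory reset |
| `blocking_plastic_synapse` | block + plasticity children, parent-to-child relay |
| `two_state_kinetic_gate` | kinetic scheme, occupancy conservation |
| `small_network` | populations, attachments, delayed weighted connections |

`componentlib.generate_random_network(n, p, seed=...)` produces seeded
random network documents for stress testing.

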