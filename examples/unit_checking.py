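"""Dimensional quantities and automatic equation checking.

Builds the ohmic current relation I = g (v - E) symbolically and shows how
dimension inference validates it from the declared dimensions alone —
the same machinery that vets every fixture before simulation.
"""

from lemsim import infer_dimension, parse_expression, parse_quantity
from lemsim.componentlib import load_fixture
from lemsim.expressions import DimensionMismatch

doc = load_fixture("passive_channel")  # brings dimensions + units

q = parse_quantity("-65 mV", doc.units)
print(f"'-65 mV' -> {q.magnitude} V, dimension {q.dimension.describe()}")

dims = {
    "g": doc.dimensions["conductance"],
    "v": doc.dimensions["voltage"],
    "E": doc.dimensions["voltage"],
}
current = infer_dimension(parse_expression("g * (v - E)"), dims)
print(f"g * (v - E) has dimension {current.describe()} "
      f"(== current: {current == doc.dimensions['current']})")

try:
    infer_dimension(parse_expression("v + g"), dims)
except DimensionMismatch as exc:
    print(f"v + g rejected: {exc}")
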