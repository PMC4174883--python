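"""Generate and run a seeded random spiking network.

Builds a document with one population of adaptive exponential cells and
Bernoulli-random delayed inhibitory connections, validates it, simulates
30 ms and prints the event traffic.  The same arguments always produce a
byte-identical document.
"""

import lemsim
from lemsim import componentlib

xml = componentlib.generate_random_network(
    n_cells=8, connection_probability=0.3, seed=11
)
n_conn = xml.count("<synapticConnection")
print(f"8 cells, p = 0.3, seed 11 -> {n_conn} directed connections")

doc = lemsim.parse_lems(xml, include_dirs=[componentlib.FIXTURE_DIR])
print("validation issues:", len(lemsim.check_document(doc)))

traces = lemsim.simulate(doc, seed=11, length=0.03)
by_cell = {}
for t, who, _ in traces.events:
    by_cell.setdefault(who, []).append(t)
print(f"{len(traces.events)} spikes in 30 ms across {len(by_cell)} cells")
for who, ts in sorted(by_cell.items()):
    print(f"  {who}: {['%.1f ms' % (t * 1e3) for t in ts]}")
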