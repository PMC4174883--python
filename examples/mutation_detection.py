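"""Unit-consistency checking catches a single flipped unit.

Takes the valid sodium-channel fixture, swaps one parameter's unit from
millivolts to milliseconds, and shows the validation report pinpointing
the inconsistent quantity.
"""

import lemsim
from lemsim import componentlib

good = componentlib.get_fixture("hh_cell")
doc = lemsim.parse_lems(good, include_dirs=[componentlib.FIXTURE_DIR])
print("valid fixture:", len(lemsim.check_document(doc)), "issues")

mutated = good.replace('midpoint="-40 mV"', 'midpoint="-40 ms"', 1)
doc = lemsim.parse_lems(mutated, include_dirs=[componentlib.FIXTURE_DIR])
report = lemsim.check_document(doc)
print("after flipping one mV to ms:", len(report), "issue(s):")
for issue in report:
    print(" -", issue)
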