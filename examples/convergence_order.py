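"""Empirical order of accuracy of the two fixed-step schemes.

Integrates dv/dt = -v over [0, 1] s at a sequence of halved step sizes and
fits the slope of log2(global error at t = 1) against log2(dt).  Forward
Euler is first order; the default scheme on the flattened system is
classic fourth-order Runge-Kutta.
"""

import math

import numpy as np

import lemsim
from lemsim.componentlib import decay_model_xml

dts = [0.1, 0.05, 0.025, 0.0125]
for method in ("euler", "rk4"):
    errors = []
    for dt in dts:
        doc = lemsim.parse_lems(decay_model_xml(dt_s=dt))
        traces = lemsim.simulate(doc, method=method)
        errors.append(abs(traces.records["cell/v"][-1] - math.exp(-1.0)))
    slope = np.polyfit(np.log2(dts), np.log2(errors), 1)[0]
    print(f"{method:5s}: errors {['%.2e' % e for e in errors]} "
          f"-> observed order {slope:.2f}")
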