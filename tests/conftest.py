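import pytest
from hypothesis import settings

import lemsim
from lemsim import componentlib as cl

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def fixture_docs():
    """All catalog fixtures, parsed once."""
    return {name: cl.load_fixture(name) for name in cl.FIXTURE_NAMES}


@pytest.fixture(scope="session")
def fixture_traces(fixture_docs):
    """One full simulation of every catalog fixture (shared, read-only)."""
    return {
        name: lemsim.simulate(doc, seed=1) for name, doc in fixture_docs.items()
    }


@pytest.fixture()
def si_units():
    """A small unit registry covering the dimensions the tests touch."""
    from lemsim.units import Dimension, Unit, standard_dimensions

    dims = standard_dimensions()
    dims["voltage"] = Dimension("voltage", (1, 2, -3, -1, 0, 0, 0))
    dims["conductance"] = Dimension("conductance", (-1, -2, 3, 2, 0, 0, 0))
    dims["current"] = Dimension("current", (0, 0, 0, 1, 0, 0, 0))
    dims["capacitance"] = Dimension("capacitance", (-1, -2, 4, 2, 0, 0, 0))
    units = {
        "V": Unit("V", dims["voltage"]),
        "mV": Unit("mV", dims["voltage"], power10=-3),
        "MV": Unit("MV", dims["voltage"], power10=6),
        "s": Unit("s", dims["time"]),
        "ms": Unit("ms", dims["time"], power10=-3),
        "S": Unit("S", dims["conductance"]),
        "mS": Unit("mS", dims["conductance"], power10=-3),
        "nS": Unit("nS", dims["conductance"], power10=-9),
        "A": Unit("A", dims["current"]),
        "F": Unit("F", dims["capacitance"]),
        "K": Unit("K", dims["temperature"]),
        "degF": Unit("degF", dims["temperature"], scale=5.0 / 9.0,
                     offset=255.3722222222222),
    }
    return dims, units
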