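import numpy as np
import pytest

from wormtaxis import evolution


def _set_slot(genes, pmap, name, value):
    names = [s.name for s in pmap.slots]
    i = names.index(name)
    genes[i] = pmap.slots[i].to_gene(value)


@pytest.fixture(scope="session")
def handmade_circuit():
    """A hand-wired klinotaxis circuit used where evolved parameters are
    not required: ON cell excites AIY, OFF cell inhibits it, AIZ relays
    with lateral coupling, and left/right motor pairs receive
    opposite-sign drive so concentration steps modulate turning."""
    pm = evolution.default_parameter_map()
    g = np.zeros(len(pm))
    for name, value in [
        ("N", 1.0), ("M", 1.0),
        ("w_ASEL_AIYL", 15.0), ("w_ASEL_AIYR", 15.0),
        ("w_ASER_AIYL", -15.0), ("w_ASER_AIYR", -15.0),
        ("theta_AIYL", 0.0), ("theta_AIYR", 0.0),
        ("g_AIY", 0.5),
        ("w_AIYL_AIZL", 10.0), ("w_AIYR_AIZR", 10.0),
        ("theta_AIZL", -5.0), ("theta_AIZR", -5.0),
        ("g_AIZ", 2.0),
        ("w_AIZL_SMBL", -10.0), ("w_AIZR_SMBR", 10.0),
        ("theta_SMBL", 2.0), ("theta_SMBR", -7.0),
        ("wself_SMBL", 0.0), ("wself_SMBR", 0.0),
    ]:
        _set_slot(g, pm, name, value)
    return evolution.decode(g, pm)


@pytest.fixture(scope="session")
def random_circuit():
    """An arbitrary (non-functional) circuit with every parameter type
    populated, for dynamics and serialization tests."""
    rng = np.random.default_rng(42)
    return evolution.decode(rng.uniform(-1.0, 1.0, 20))


@pytest.fixture(scope="session")
def fixture_ensemble():
    """Packaged evolved circuits (the high-performance subpopulation)."""
    from wormtaxis import fixtures

    ens = fixtures.packaged_ensemble()
    assert ens, "packaged ensemble is empty"
    return ens


@pytest.fixture(scope="session")
def best_circuit(fixture_ensemble):
    from wormtaxis import fixtures

    return fixtures.best_fixture_circuit()
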