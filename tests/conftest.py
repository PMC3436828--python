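import pytest

from fluxmodes import enumerate_ems, layered_network, toy_network


@pytest.fixture(scope="session")
def chain():
    return toy_network("chain")


@pytest.fixture(scope="session")
def diamond():
    return toy_network("diamond")


@pytest.fixture(scope="session")
def rev_cycle():
    return toy_network("rev_cycle")


@pytest.fixture(scope="session")
def deadend():
    return toy_network("deadend")


@pytest.fixture(scope="session")
def branched():
    return toy_network("branched")


@pytest.fixture(scope="session")
def parallel20():
    """Symmetric two-layer cascade with 4 x 5 = 20 elementary modes."""
    return layered_network([4, 5], name="parallel20")


@pytest.fixture(scope="session")
def parallel20_full(parallel20):
    return enumerate_ems(parallel20.model)


@pytest.fixture(scope="session")
def layered_mid():
    """Four layers of four isozymes with skip bridges: 305 modes."""
    return layered_network([4] * 4, skips=True, name="layered_mid")


@pytest.fixture(scope="session")
def layered_mid_full(layered_mid):
    return enumerate_ems(layered_mid.model)


@pytest.fixture(scope="session")
def layered_big():
    """Six layers of four isozymes with skip bridges: 5473 modes of
    varying length; full enumeration is deliberately avoided in tests —
    the exact count and length histogram come from path counting."""
    return layered_network([4] * 6, skips=True, name="layered_big")
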