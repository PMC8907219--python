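import numpy as np
import pytest

from chondronet.dynamics import SolverConfig
from chondronet.network import Edge, Node, RegulatoryNetwork, Sign
from chondronet.synthetic import fixture_chondrocyte_network


@pytest.fixture(scope="session")
def fixture_net():
    return fixture_chondrocyte_network()


@pytest.fixture(scope="session")
def fast_solver():
    """Coarser step than the default; steady states are unbiased by the step
    size (fixed points of the RK4 map coincide with ODE fixed points)."""
    return SolverConfig(step=0.05, t_max=60.0, excursion_tol=1e-4)


@pytest.fixture()
def chain_net():
    """A -> B (activation), A is a source node."""
    net = RegulatoryNetwork()
    net.add_edge(Edge("A", "B", Sign.ACTIVATION))
    return net


@pytest.fixture()
def toggle_net():
    """Mutual inhibition with self-activation: the classic bistable toggle."""
    net = RegulatoryNetwork()
    net.add_edge(Edge("A", "B", Sign.INHIBITION))
    net.add_edge(Edge("B", "A", Sign.INHIBITION))
    net.add_edge(Edge("A", "A", Sign.ACTIVATION))
    net.add_edge(Edge("B", "B", Sign.ACTIVATION))
    return net
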